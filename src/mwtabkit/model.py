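"""In-memory document model for mwTab files.

An mwTab file is a sequence of ``#``-prefixed text blocks (sections).  Most
sections are flat key → value mappings; the ``SUBJECT_SAMPLE_FACTORS``
section is a table mapping each sample to its subject and experimental
factor values, and the results sections (``MS_METABOLITE_DATA``,
``NMR_BINNED_DATA``, ``METABOLITES``) hold a feature-by-sample matrix with a
stated units field.  :class:`MwTabDocument` mirrors that structure exactly
and is the single source of truth for both the mwTab-text and JSON
serializations: section order, key order and verbatim text values are
preserved, and all cell values stay strings (numeric interpretation is the
consumer's job, which keeps round trips lossless).

Bracket-style access works in the usual pythonic way::

    doc["PROJECT"]["PROJECT_SUMMARY"]            # read
    doc["PROJECT"]["PROJECT_SUMMARY"] = "text"   # modify

The first ``#METABOLOMICS WORKBENCH`` line of a file carries VERSION,
CREATED_ON, STUDY_ID and ANALYSIS_ID; those live in :class:`HeaderInfo` and
are also reachable through the pseudo-section name
``"METABOLOMICS WORKBENCH"`` for uniform access.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import UnknownKeyError, UnknownSectionError

#: Pseudo-section name under which the file-header fields are exposed.
HEADER_SECTION = "METABOLOMICS WORKBENCH"

#: Keys stored on :class:`HeaderInfo`, in canonical order.
HEADER_KEYS = ("VERSION", "CREATED_ON", "STUDY_ID", "ANALYSIS_ID")

#: Section name -> key prefix regenerated at write time.  Two-letter codes
#: for the metadata blocks; the data blocks prefix items with their own name
#: (e.g. ``MS_METABOLITE_DATA:UNITS``).
SECTION_PREFIXES = {
    "PROJECT": "PR",
    "STUDY": "ST",
    "SUBJECT": "SU",
    "COLLECTION": "CO",
    "TREATMENT": "TR",
    "SAMPLEPREP": "SP",
    "CHROMATOGRAPHY": "CH",
    "ANALYSIS": "AN",
    "MS": "MS",
    "NMR": "NM",
    "MS_METABOLITE_DATA": "MS_METABOLITE_DATA",
    "NMR_BINNED_DATA": "NMR_BINNED_DATA",
    "METABOLITES": "METABOLITES",
    "EXTENDED_MS_METABOLITE_DATA": "EXTENDED_MS_METABOLITE_DATA",
}

SSF_SECTION = "SUBJECT_SAMPLE_FACTORS"

#: Data-table kinds.  ``MS_METABOLITE_DATA`` and ``NMR_BINNED_DATA`` are the
#: results matrices (mandatory units); ``METABOLITES`` is the metabolite
#: annotation table; ``EXTENDED`` covers extended/unknown tabular blocks.
RESULTS_KINDS = ("MS_METABOLITE_DATA", "NMR_BINNED_DATA")
TABLE_KINDS = ("MS_METABOLITE_DATA", "NMR_BINNED_DATA", "METABOLITES", "EXTENDED")

STUDY_ID_RE = re.compile(r"^ST\d+$")
ANALYSIS_ID_RE = re.compile(r"^AN\d+$")

_SECTION_NAME_RE = re.compile(r"^[A-Z][A-Z0-9_ ]*$")


@dataclass
class HeaderInfo:
    """Fields of the ``#METABOLOMICS WORKBENCH`` file header."""

    version: str = ""
    created_on: str = ""
    study_id: str = ""
    analysis_id: str = ""

    _FIELD_BY_KEY = {
        "VERSION": "version",
        "CREATED_ON": "created_on",
        "STUDY_ID": "study_id",
        "ANALYSIS_ID": "analysis_id",
    }

    def get(self, key: str) -> str:
        try:
            return getattr(self, self._FIELD_BY_KEY[key])
        except KeyError:
            raise UnknownKeyError(
                f"header section {HEADER_SECTION!r} has no key {key!r}"
            ) from None

    def set(self, key: str, value: str) -> None:
        if key not in self._FIELD_BY_KEY:
            raise UnknownKeyError(
                f"header section {HEADER_SECTION!r} cannot hold key {key!r}; "
                f"allowed keys: {', '.join(HEADER_KEYS)}"
            )
        setattr(self, self._FIELD_BY_KEY[key], value)

    def as_items(self) -> dict[str, str]:
        """Ordered mapping view used for pseudo-section access/validation."""
        return {k: self.get(k) for k in HEADER_KEYS}


@dataclass
class SubjectSampleFactorRecord:
    """One row of the SUBJECT_SAMPLE_FACTORS block.

    ``factors`` maps factor name to factor value (e.g. ``Treatment -> drug``);
    ``additional_data`` holds free-form ``key=value`` annotations such as raw
    file names.
    """

    subject_type: str = ""
    local_sample_id: str = ""
    factors: dict[str, str] = field(default_factory=dict)
    additional_data: dict[str, str] = field(default_factory=dict)

    def __eq__(self, other):
        if not isinstance(other, SubjectSampleFactorRecord):
            return NotImplemented
        return (
            self.subject_type == other.subject_type
            and self.local_sample_id == other.local_sample_id
            and list(self.factors.items()) == list(other.factors.items())
            and list(self.additional_data.items()) == list(other.additional_data.items())
        )


@dataclass(eq=False)
class DataTable:
    """Feature-by-sample matrix of verbatim text values.

    ``rows`` is an ordered list of ``(feature_id, values)`` where ``values``
    is aligned to ``column_names``.  ``units`` is the mandatory units string
    of results tables; the empty string means it was missing in the file.
    ``factor_row`` is the optional ``Factors`` header row aligned to the
    sample columns.
    """

    kind: str
    units: str = ""
    column_names: list[str] = field(default_factory=list)
    factor_row: list[str] | None = None
    rows: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in TABLE_KINDS:
            raise ValueError(f"unknown data-table kind {self.kind!r}")
        width = len(self.column_names)
        if self.factor_row is not None and len(self.factor_row) != width:
            raise ValueError(
                f"factor row has {len(self.factor_row)} cells, expected {width}"
            )
        for feature_id, values in self.rows:
            if len(values) != width:
                raise ValueError(
                    f"row {feature_id!r} has {len(values)} values, expected {width}"
                )

    def __eq__(self, other):
        if not isinstance(other, DataTable):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.units == other.units
            and self.column_names == other.column_names
            and self.factor_row == other.factor_row
            and self.rows == other.rows
        )


@dataclass(eq=False)
class Section:
    """One ``#NAME`` text block.

    Exactly one of three shapes: plain items, SUBJECT_SAMPLE_FACTORS records,
    or a data table (a data section may additionally carry plain items, e.g.
    results-file names).  Item keys are stored without their two-letter
    prefix; repeated keys in the file are continuation lines merged at parse
    time, so keys are unique here.
    """

    name: str
    prefix: str = ""
    items: dict[str, str] = field(default_factory=dict)
    ssf_records: list[SubjectSampleFactorRecord] = field(default_factory=list)
    data_table: DataTable | None = None

    def __post_init__(self):
        if not self.name or not _SECTION_NAME_RE.match(self.name):
            raise ValueError(f"invalid section name {self.name!r}")
        if self.ssf_records and self.name != SSF_SECTION:
            raise ValueError(
                f"section {self.name!r} cannot hold subject/sample factor records"
            )
        if self.ssf_records and self.data_table is not None:
            raise ValueError("a section cannot hold both factor records and a data table")

    # -- pythonic access -------------------------------------------------
    def __getitem__(self, key: str) -> str:
        if self.data_table is not None and key == "UNITS" and key not in self.items:
            return self.data_table.units
        try:
            return self.items[key]
        except KeyError:
            raise UnknownKeyError(
                f"section {self.name!r} has no key {key!r}"
            ) from None

    def __setitem__(self, key: str, value: str) -> None:
        self.items[key] = value

    def __contains__(self, key: str) -> bool:
        return key in self.items

    def keys(self):
        return self.items.keys()

    def __eq__(self, other):
        if not isinstance(other, Section):
            return NotImplemented
        return (
            self.name == other.name
            and list(self.items.items()) == list(other.items.items())
            and self.ssf_records == other.ssf_records
            and self.data_table == other.data_table
        )


@dataclass(eq=False)
class MwTabDocument:
    """Ordered, nested representation of one mwTab analysis file.

    ``sections`` preserves file order; serialization emits sections in
    stored order.  ``source_id`` records provenance (path, URL or analysis
    identifier) and is excluded from equality, as are the recoverable
    ``parse_findings`` collected while reading a defective file.
    """

    header: HeaderInfo = field(default_factory=HeaderInfo)
    sections: dict[str, Section] = field(default_factory=dict)
    source_id: str = ""
    parse_findings: list = field(default_factory=list)
    end_marker_seen: bool = True

    # -- pythonic access -------------------------------------------------
    def __getitem__(self, name: str) -> Section | HeaderInfo:
        if name == HEADER_SECTION:
            return _HeaderView(self.header)
        try:
            return self.sections[name]
        except KeyError:
            raise UnknownSectionError(f"document has no section {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name == HEADER_SECTION or name in self.sections

    def __iter__(self):
        return iter(self.sections)

    def add_section(self, section: Section) -> Section:
        self.sections[section.name] = section
        return section

    @property
    def data_table(self) -> DataTable | None:
        """The results data table (MS or NMR), if any."""
        for sec in self.sections.values():
            if sec.data_table is not None and sec.data_table.kind in RESULTS_KINDS:
                return sec.data_table
        return None

    def __eq__(self, other):
        if not isinstance(other, MwTabDocument):
            return NotImplemented
        return (
            self.header == other.header
            and list(self.sections) == list(other.sections)
            and all(self.sections[n] == other.sections[n] for n in self.sections)
        )


class _HeaderView:
    """Mapping facade exposing HeaderInfo as the pseudo-section."""

    def __init__(self, header: HeaderInfo):
        self._header = header

    def __getitem__(self, key: str) -> str:
        return self._header.get(key)

    def __setitem__(self, key: str, value: str) -> None:
        self._header.set(key, value)

    def __contains__(self, key: str) -> bool:
        return key in HEADER_KEYS

    def keys(self):
        return list(HEADER_KEYS)


# -- operation-style accessors ------------------------------------------


def get_value(doc: MwTabDocument, section: str, key: str) -> str:
    """Return the stored (continuation-merged) value of ``key`` in ``section``.

    Raises :class:`UnknownSectionError` / :class:`UnknownKeyError` naming the
    missing element.  The header pseudo-section ``"METABOLOMICS WORKBENCH"``
    resolves VERSION, CREATED_ON, STUDY_ID and ANALYSIS_ID.
    """
    return doc[section][key]


def set_value(doc: MwTabDocument, section: str, key: str, value: str) -> MwTabDocument:
    """Set ``key`` in ``section`` to ``value``; new keys append at the tail.

    Existing keys keep their position.  Raises UnknownSectionError for a
    missing section.
    """
    doc[section][key] = value
    return doc


def list_sample_columns(doc: MwTabDocument) -> list[str]:
    """Sample/column labels of the results data table, in order.

    Returns an empty list when the document has no results table.
    """
    table = doc.data_table
    return list(table.column_names) if table is not None else []
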