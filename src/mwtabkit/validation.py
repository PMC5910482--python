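"""Schema-based validation and consistency checking.

Each text block has a :class:`SchemaDefinition` listing its required and
optional keys and per-key value rules (regular expressions or enumerations).
The bundled default schema follows the official mwTab format specification
(e.g. the PROJECT block requires PROJECT_TITLE, PROJECT_SUMMARY, INSTITUTE,
LAST_NAME, FIRST_NAME, ADDRESS, EMAIL and PHONE) and can be replaced by a
user schema file in the same JSON dialect.

Findings are collected as :class:`ValidationIssue` objects, never thrown:
real repository files frequently violate the specification yet remain
usable, so structural breaches and missing required metadata are reported
as errors while advisory conditions (unknown keys, sample-count mismatches,
content after ``#END``) are warnings.  Validating the same document twice
yields identical ordered findings.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .errors import SchemaLoadError
from .model import (
    HEADER_SECTION,
    RESULTS_KINDS,
    MwTabDocument,
    Section,
)
from .validation_types import ISSUE_CODES, ValidationIssue  # noqa: F401 (re-export)

_ANALYSIS_IN_NAME_RE = re.compile(r"(AN\d{6,})")


@dataclass
class SchemaDefinition:
    """Field rules for one text block."""

    section: str
    required_keys: list[str] = field(default_factory=list)
    optional_keys: list[str] = field(default_factory=list)
    value_rules: dict[str, dict] = field(default_factory=dict)
    structural_rules: dict = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.required_keys) & set(self.optional_keys)
        if overlap:
            raise SchemaLoadError(
                f"schema for {self.section!r}: keys cannot be both required "
                f"and optional: {sorted(overlap)}"
            )
        for key, rule in self.value_rules.items():
            if "pattern" in rule:
                try:
                    re.compile(rule["pattern"])
                except re.error as exc:
                    raise SchemaLoadError(
                        f"schema for {self.section!r}: bad pattern for "
                        f"{key!r}: {exc}"
                    ) from exc
            elif "enum" not in rule:
                raise SchemaLoadError(
                    f"schema for {self.section!r}: rule for {key!r} must have "
                    "'pattern' or 'enum'"
                )

    @property
    def known_keys(self) -> set[str]:
        return set(self.required_keys) | set(self.optional_keys)


def load_schemas(path: str | None = None) -> dict[str, SchemaDefinition]:
    """Load schema definitions from a JSON file (bundled default if None).

    The file maps section name to ``{"required": [...], "optional": [...],
    "value_rules": {key: {"pattern": ...} | {"enum": [...]}},
    "structural_rules": {...}}``.  Raises :class:`SchemaLoadError` with the
    offending location for malformed input.
    """
    if path is None:
        text = (
            resources.files("mwtabkit") / "schemas" / "mwtab_schema.json"
        ).read_text(encoding="utf-8")
        origin = "<bundled schema>"
    else:
        try:
            with open(path, encoding="utf-8") as fh:
                text = fh.read()
        except OSError as exc:
            raise SchemaLoadError(f"cannot read schema file {path!r}: {exc}") from exc
        origin = path
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaLoadError(
            f"{origin}: not valid JSON (line {exc.lineno}, column {exc.colno})"
        ) from exc
    if not isinstance(raw, dict):
        raise SchemaLoadError(f"{origin}: top level must be an object")
    schemas: dict[str, SchemaDefinition] = {}
    for name, spec in raw.items():
        if not isinstance(spec, dict):
            raise SchemaLoadError(f"{origin}: entry {name!r} must be an object")
        schemas[name] = SchemaDefinition(
            section=name,
            required_keys=list(spec.get("required", [])),
            optional_keys=list(spec.get("optional", [])),
            value_rules=dict(spec.get("value_rules", {})),
            structural_rules=dict(spec.get("structural_rules", {})),
        )
    return schemas


def default_schemas() -> dict[str, SchemaDefinition]:
    """The bundled schema definitions for every standard text block."""
    return load_schemas(None)


def validate_section(sec: Section | Mapping[str, str],
                     schema: SchemaDefinition) -> list[ValidationIssue]:
    """Validate one section's items against its schema.

    Reports one MISSING_REQUIRED_FIELD error per absent required key (in
    schema order), then per-key findings in file order: a
    CONSTRAINT_VIOLATION for each value failing its rule and an UNKNOWN_KEY
    warning for each key in neither set.  Never fail-fast.
    """
    if isinstance(sec, Section):
        name, items = sec.name, sec.items
    else:
        name, items = schema.section, dict(sec)
    issues: list[ValidationIssue] = []
    for key in schema.required_keys:
        if not items.get(key, ""):
            issues.append(
                ValidationIssue(
                    severity="error",
                    code="MISSING_REQUIRED_FIELD",
                    section=name,
                    key=key,
                    message=f"section {name!r} is missing the required "
                            f"{key!r} field",
                )
            )
    known = schema.known_keys
    for key, value in items.items():
        rule = schema.value_rules.get(key)
        if rule and value:
            if "pattern" in rule and not re.search(rule["pattern"], value):
                issues.append(
                    ValidationIssue(
                        severity="error",
                        code="CONSTRAINT_VIOLATION",
                        section=name,
                        key=key,
                        message=f"value {value!r} of {name}.{key} does not "
                                f"match required pattern {rule['pattern']!r}",
                    )
                )
            elif "enum" in rule and value not in rule["enum"]:
                issues.append(
                    ValidationIssue(
                        severity="error",
                        code="CONSTRAINT_VIOLATION",
                        section=name,
                        key=key,
                        message=f"value {value!r} of {name}.{key} is not one "
                                f"of {rule['enum']}",
                    )
                )
        if known and key not in known:
            issues.append(
                ValidationIssue(
                    severity="warning",
                    code="UNKNOWN_KEY",
                    section=name,
                    key=key,
                    message=f"key {key!r} is not in the {name!r} schema",
                )
            )
    return issues


def validate_document(doc: MwTabDocument,
                      schemas: dict[str, SchemaDefinition] | None = None,
                      ) -> list[ValidationIssue]:
    """Validate a parsed document: file-level + per-section + consistency.

    File-level checks re-report the recoverable parse findings (leading
    content, orphan items, unterminated tables, malformed factor records),
    add MISSING_END when no ``#END`` marker was seen and EMPTY_UNITS for
    each results table whose mandatory units value is empty, then apply the
    per-block schemas and the cross-block consistency checks.
    """
    schemas = schemas if schemas is not None else default_schemas()
    issues: list[ValidationIssue] = []

    # parse findings, except ROW_ARITY which check_consistency re-reports
    issues.extend(f for f in doc.parse_findings if f.code != "ROW_ARITY")

    if not doc.end_marker_seen:
        issues.append(
            ValidationIssue(
                severity="error",
                code="MISSING_END",
                section="",
                message="file is missing the '#END' statement that signals "
                        "the end of the file",
            )
        )

    header_schema = schemas.get(HEADER_SECTION)
    if header_schema is not None:
        issues.extend(validate_section(doc.header.as_items(), header_schema))

    for sec in doc.sections.values():
        if sec.name == "UNATTRIBUTED":
            continue  # already reported as ORPHAN_ITEM findings
        schema = schemas.get(sec.name)
        if schema is None:
            issues.append(
                ValidationIssue(
                    severity="warning",
                    code="UNKNOWN_SECTION",
                    section=sec.name,
                    message=f"section {sec.name!r} has no schema definition",
                )
            )
            continue
        issues.extend(validate_section(sec, schema))
        table = sec.data_table
        if (
            table is not None
            and table.kind in RESULTS_KINDS
            and not table.units
        ):
            issues.append(
                ValidationIssue(
                    severity="error",
                    code="EMPTY_UNITS",
                    section=sec.name,
                    key="UNITS",
                    message=f"mandatory units field of the {sec.name} table "
                            "is empty",
                )
            )

    issues.extend(check_consistency(doc))
    return issues


def check_consistency(doc: MwTabDocument) -> list[ValidationIssue]:
    """Cross-block consistency findings.

    * COLUMN_MISMATCH (warning): results-table sample-column count differs
      from the SUBJECT_SAMPLE_FACTORS record count.
    * ROW_ARITY (error): table rows whose cell count differed from the
      header (detected at parse, re-reported here).
    * ID_MISMATCH (warning): header analysis id conflicts with an AN
      identifier embedded in the document's source path/address.
    """
    issues: list[ValidationIssue] = []
    issues.extend(f for f in doc.parse_findings if f.code == "ROW_ARITY")

    table = doc.data_table
    ssf = doc.sections.get("SUBJECT_SAMPLE_FACTORS")
    if table is not None and ssf is not None and ssf.ssf_records:
        n_cols = len(table.column_names)
        n_recs = len(ssf.ssf_records)
        if n_cols != n_recs:
            issues.append(
                ValidationIssue(
                    severity="warning",
                    code="COLUMN_MISMATCH",
                    section="SUBJECT_SAMPLE_FACTORS",
                    message=f"data table has {n_cols} sample columns but "
                            f"{n_recs} subject/sample factor records",
                )
            )

    if doc.header.analysis_id and doc.source_id:
        m = _ANALYSIS_IN_NAME_RE.search(doc.source_id)
        if m and m.group(1) != doc.header.analysis_id:
            issues.append(
                ValidationIssue(
                    severity="warning",
                    code="ID_MISMATCH",
                    section=HEADER_SECTION,
                    key="ANALYSIS_ID",
                    message=f"header analysis id {doc.header.analysis_id!r} "
                            f"differs from {m.group(1)!r} in the source "
                            f"address {doc.source_id!r}",
                )
            )
    return issues


@dataclass
class UnitsSurvey:
    """Tally of the mandatory units field across results tables.

    ``missing_count`` counts tables whose units value is empty; the sum of
    ``tally`` counts plus ``missing_count`` equals the number of surveyed
    tables.  With case-folded normalization, variants such as
    "Peak height" and "peak height" merge into one tally entry (keyed by
    the case-folded form).
    """

    tally: dict[str, int] = field(default_factory=dict)
    missing_count: int = 0
    normalization: str = "verbatim"

    @property
    def total(self) -> int:
        return sum(self.tally.values()) + self.missing_count


def survey_units(docs: Iterable[MwTabDocument],
                 normalization: str = "verbatim") -> UnitsSurvey:
    """Survey the units value of every results data table in ``docs``.

    ``normalization`` is ``"verbatim"`` or ``"case-folded"``.
    """
    if normalization not in ("verbatim", "case-folded"):
        raise ValueError(f"unknown normalization {normalization!r}")
    survey = UnitsSurvey(normalization=normalization)
    for doc in docs:
        table = doc.data_table
        if table is None:
            continue
        units = table.units
        if not units:
            survey.missing_count += 1
            continue
        if normalization == "case-folded":
            units = units.casefold()
        survey.tally[units] = survey.tally.get(units, 0) + 1
    return survey
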