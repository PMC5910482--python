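"""Deterministic synthetic mwTab files with known ground truth.

:func:`generate_document` emits a complete, schema-valid analysis document
— header with synthetic ST/AN identifiers, all required metadata blocks,
``n_samples`` subject/sample factor records and a platform-appropriate
results matrix (``n_metabolites`` features by ``n_samples`` samples, plus a
METABOLITES annotation table for MS) — together with a
:class:`GroundTruth` recording every generated item, record and cell.  All
randomness flows from ``FixtureSpec.seed`` through one stated generator
(:class:`random.Random`), so the same spec renders byte-identical text.

:func:`inject_corruption` introduces exactly one defect of a named class
into rendered text, returning the issue codes the validator is expected to
report — the single-fault test bed for the defect classes observed in real
repository files (leading blank lines, missing ``#END``, empty mandatory
units, dropped required fields, malformed factor rows, row-arity breaks,
case-variant units strings).
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .codec import write_mwtab
from .errors import CorruptionInapplicableError
from .model import (
    DataTable,
    HeaderInfo,
    MwTabDocument,
    Section,
    SubjectSampleFactorRecord,
)
from .tokenizer import LayoutPolicy
from .validation import default_schemas

#: Small list of real metabolite names for realism; longer tables append a
#: numeric suffix.
METABOLITE_NAMES = [
    "alanine", "arginine", "asparagine", "aspartate", "citrate", "creatinine",
    "cysteine", "fumarate", "glucose", "glutamate", "glutamine", "glycine",
    "histidine", "isoleucine", "lactate", "leucine", "lysine", "malate",
    "methionine", "phenylalanine", "proline", "pyruvate", "serine",
    "succinate", "threonine", "tryptophan", "tyrosine", "valine",
]

_FACTOR_NAMES = ["Treatment", "Time point", "Diet", "Genotype", "Dose"]
_FACTOR_VALUES = {
    "Treatment": ["control", "drug"],
    "Time point": ["0 h", "4 h", "24 h"],
    "Diet": ["chow", "high fat"],
    "Genotype": ["WT", "KO"],
    "Dose": ["low", "high"],
}

MAX_SAMPLES = 10_000
MAX_METABOLITES = 100_000


class CorruptionClass(str, Enum):
    LEADING_BLANK_LINES = "LEADING_BLANK_LINES"
    MISSING_END = "MISSING_END"
    EMPTY_UNITS = "EMPTY_UNITS"
    DROP_REQUIRED_KEY = "DROP_REQUIRED_KEY"
    SSF_MALFORMED = "SSF_MALFORMED"
    ROW_ARITY = "ROW_ARITY"
    UNITS_CASE_VARIANT = "UNITS_CASE_VARIANT"


#: Issue codes the validator must report for a single injected fault.
#: UNITS_CASE_VARIANT is not detectable within a single file (it only
#: surfaces when surveying units across files), hence the empty set.
EXPECTED_ISSUE_CODES: dict[CorruptionClass, frozenset[str]] = {
    CorruptionClass.LEADING_BLANK_LINES: frozenset({"LEADING_CONTENT"}),
    CorruptionClass.MISSING_END: frozenset({"MISSING_END"}),
    CorruptionClass.EMPTY_UNITS: frozenset({"EMPTY_UNITS"}),
    CorruptionClass.DROP_REQUIRED_KEY: frozenset({"MISSING_REQUIRED_FIELD"}),
    CorruptionClass.SSF_MALFORMED: frozenset({"SSF_MALFORMED"}),
    CorruptionClass.ROW_ARITY: frozenset({"ROW_ARITY"}),
    CorruptionClass.UNITS_CASE_VARIANT: frozenset(),
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic analysis file."""

    seed: int = 0
    n_samples: int = 6
    n_metabolites: int = 40
    platform: str = "MS"  # MS | NMR
    n_factors: int = 2
    include_optional_keys: bool = False
    units: str | None = None  # default: platform-appropriate string

    def __post_init__(self):
        if not (1 <= self.n_samples <= MAX_SAMPLES):
            raise ValueError(f"n_samples must be in [1, {MAX_SAMPLES}]")
        if not (1 <= self.n_metabolites <= MAX_METABOLITES):
            raise ValueError(f"n_metabolites must be in [1, {MAX_METABOLITES}]")
        if self.platform not in ("MS", "NMR"):
            raise ValueError("platform must be 'MS' or 'NMR'")
        if self.n_factors < 0 or self.n_factors > len(_FACTOR_NAMES):
            raise ValueError(f"n_factors must be in [0, {len(_FACTOR_NAMES)}]")


@dataclass
class GroundTruth:
    """Everything the generator emitted, for oracle-style assertions."""

    items: list[tuple[str, str, str]] = field(default_factory=list)
    ssf_records: list[SubjectSampleFactorRecord] = field(default_factory=list)
    sample_names: list[str] = field(default_factory=list)
    table_rows: list[tuple[str, list[str]]] = field(default_factory=list)
    units: str = ""
    n_sections: int = 0
    study_id: str = ""
    analysis_id: str = ""


_WORDS = (
    "metabolite profiling of plasma samples across treatment groups using "
    "targeted and untargeted approaches to characterize pathway level "
    "responses under controlled dietary and pharmacological interventions "
    "with replicate measurements and quality control pooling"
).split()


def _sentence(rng: random.Random, n_words: int) -> str:
    words = [rng.choice(_WORDS) for _ in range(n_words)]
    return " ".join(words)


def generate_document(spec: FixtureSpec) -> tuple[MwTabDocument, GroundTruth]:
    """Build a valid document and its ground truth, deterministic under seed."""
    rng = random.Random(spec.seed)
    truth = GroundTruth()

    study_id = f"ST{rng.randrange(1, 999999):06d}"
    analysis_id = f"AN{rng.randrange(1, 999999):06d}"
    truth.study_id, truth.analysis_id = study_id, analysis_id
    doc = MwTabDocument(
        header=HeaderInfo(
            version="1",
            created_on=f"2017-{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}",
            study_id=study_id,
            analysis_id=analysis_id,
        ),
        source_id=f"{analysis_id}.txt",
    )

    last = rng.choice(["Smith", "Jones", "Garcia", "Chen", "Patel", "Kim"])
    first = rng.choice(["Alex", "Sam", "Jordan", "Taylor", "Morgan", "Casey"])
    contact = {
        "INSTITUTE": "University of Example",
        "LAST_NAME": last,
        "FIRST_NAME": first,
        "ADDRESS": f"{rng.randrange(1, 999)} College Way, Example City, EX 40000",
        "EMAIL": f"{first.lower()}.{last.lower()}@example.edu",
        "PHONE": f"555-{rng.randrange(100, 999)}-{rng.randrange(1000, 9999)}",
    }

    def add(name: str, items: dict[str, str]) -> Section:
        sec = doc.add_section(Section(name=name, prefix=_prefix(name)))
        for key, value in items.items():
            sec.items[key] = value
            truth.items.append((name, key, value))
        return sec

    project_items = {
        "PROJECT_TITLE": f"Synthetic metabolomics project {study_id}",
        "PROJECT_SUMMARY": _sentence(rng, 40),
        **contact,
    }
    if spec.include_optional_keys:
        project_items.update({
            "PROJECT_TYPE": "Basic research",
            "DEPARTMENT": "Biochemistry",
            "FUNDING_SOURCE": "Example Foundation",
            "DOI": f"10.0000/synthetic.{spec.seed}",
        })
    add("PROJECT", project_items)

    add("STUDY", {
        "STUDY_TITLE": f"Synthetic study {study_id} ({spec.platform})",
        **contact,
        **({"STUDY_SUMMARY": _sentence(rng, 30)} if spec.include_optional_keys else {}),
    })

    add("SUBJECT", {
        "SUBJECT_TYPE": "Mammal",
        "SUBJECT_SPECIES": "Mus musculus",
        **({"TAXONOMY_ID": "10090"} if spec.include_optional_keys else {}),
    })

    # subject/sample factors: one record per sample
    ssf = doc.add_section(Section(name="SUBJECT_SAMPLE_FACTORS"))
    factor_names = _FACTOR_NAMES[: spec.n_factors]
    sample_names = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    truth.sample_names = sample_names
    for i, sample in enumerate(sample_names):
        factors = {
            name: rng.choice(_FACTOR_VALUES[name]) for name in factor_names
        }
        rec = SubjectSampleFactorRecord(
            subject_type="Mouse",
            local_sample_id=sample,
            factors=factors,
            additional_data={"RAW_FILE": f"{analysis_id}_{i + 1:03d}.raw"},
        )
        ssf.ssf_records.append(rec)
        truth.ssf_records.append(rec)

    add("COLLECTION", {"COLLECTION_SUMMARY": _sentence(rng, 15),
                       **({"SAMPLE_TYPE": "Blood (plasma)"}
                          if spec.include_optional_keys else {})})
    add("TREATMENT", {"TREATMENT_SUMMARY": _sentence(rng, 15)})
    add("SAMPLEPREP", {"SAMPLEPREP_SUMMARY": _sentence(rng, 15)})

    if spec.platform == "MS":
        add("CHROMATOGRAPHY", {
            "CHROMATOGRAPHY_TYPE": "Reversed phase",
            "INSTRUMENT_NAME": "Agilent 1290 Infinity",
            "COLUMN_NAME": "Waters Acquity BEH C18 (100 x 2.1mm, 1.7um)",
        })
    add("ANALYSIS", {"ANALYSIS_TYPE": spec.platform})

    if spec.platform == "MS":
        add("MS", {
            "INSTRUMENT_NAME": "Thermo Q Exactive Orbitrap",
            "INSTRUMENT_TYPE": "Orbitrap",
            "MS_TYPE": "ESI",
            "ION_MODE": rng.choice(["POSITIVE", "NEGATIVE"]),
        })
        units = spec.units if spec.units is not None else "peak area"
        feature_names = _metabolite_names(spec.n_metabolites)
        data_name = "MS_METABOLITE_DATA"
    else:
        add("NMR", {
            "INSTRUMENT_NAME": "Bruker Avance III 600",
            "INSTRUMENT_TYPE": "FT-NMR",
            "NMR_EXPERIMENT_TYPE": "1D 1H",
            "SPECTROMETER_FREQUENCY": "600 MHz",
        })
        units = spec.units if spec.units is not None else "Intensity"
        feature_names = _bin_ranges(spec.n_metabolites)
        data_name = "NMR_BINNED_DATA"

    truth.units = units
    data_sec = doc.add_section(Section(name=data_name, prefix=_prefix(data_name)))
    factor_row = (
        [" | ".join(f"{k}:{v}" for k, v in rec.factors.items())
         for rec in truth.ssf_records]
        if factor_names else None
    )
    rows = []
    for name in feature_names:
        values = [f"{rng.uniform(0, 100000):.1f}" for _ in sample_names]
        rows.append((name, values))
    truth.table_rows = rows
    data_sec.data_table = DataTable(
        kind=data_name,
        units=units,
        column_names=list(sample_names),
        factor_row=factor_row,
        rows=rows,
    )

    if spec.platform == "MS":
        met = doc.add_section(Section(name="METABOLITES", prefix=_prefix("METABOLITES")))
        met.data_table = DataTable(
            kind="METABOLITES",
            units="",
            column_names=["moverz_quant", "ri"],
            rows=[
                (name, [f"{rng.uniform(50, 1000):.4f}", f"{rng.uniform(100, 4000):.1f}"])
                for name in feature_names
            ],
        )

    truth.n_sections = len(doc.sections)
    return doc, truth


def _prefix(name: str) -> str:
    from .model import SECTION_PREFIXES

    return SECTION_PREFIXES.get(name, "")


def _metabolite_names(n: int) -> list[str]:
    names = []
    for i in range(n):
        base = METABOLITE_NAMES[i % len(METABOLITE_NAMES)]
        names.append(base if i < len(METABOLITE_NAMES)
                     else f"{base}_{i // len(METABOLITE_NAMES)}")
    return names


def _bin_ranges(n: int, start: float = 0.50, step: float = 0.04) -> list[str]:
    return [f"{start + i * step:.2f}-{start + (i + 1) * step:.2f}" for i in range(n)]


def generate_mwtab_text(spec: FixtureSpec,
                        layout: LayoutPolicy | None = None) -> tuple[str, GroundTruth]:
    """Render a generated document to mwTab text."""
    doc, truth = generate_document(spec)
    return write_mwtab(doc, layout), truth


# -- corruption injector -------------------------------------------------

_UNITS_LINE_RE = re.compile(r"^(\w+:UNITS\s+)(\S.*)$")
_SSF_LINE_RE = re.compile(r"^SUBJECT_SAMPLE_FACTORS\s")


def inject_corruption(text: str, cls: CorruptionClass | str,
                      seed: int = 0) -> tuple[str, frozenset[str]]:
    """Introduce exactly one defect of class ``cls`` into mwTab text.

    Returns the corrupted text and the set of issue codes
    ``validate_document`` is expected to report.  Raises
    :class:`CorruptionInapplicableError` when the class does not apply to
    this document (e.g. EMPTY_UNITS with no results table).
    """
    cls = CorruptionClass(cls)
    rng = random.Random(seed)
    lines = text.splitlines()
    expected = EXPECTED_ISSUE_CODES[cls]

    if cls is CorruptionClass.LEADING_BLANK_LINES:
        lines = [""] * rng.randrange(1, 4) + lines
    elif cls is CorruptionClass.MISSING_END:
        if "#END" not in lines:
            raise CorruptionInapplicableError("text has no '#END' line to remove")
        lines.remove("#END")
    elif cls is CorruptionClass.EMPTY_UNITS:
        idx = _find_units_line(lines)
        m = _UNITS_LINE_RE.match(lines[idx])
        lines[idx] = m.group(1).split()[0]  # keep the key, drop the value
    elif cls is CorruptionClass.UNITS_CASE_VARIANT:
        idx = _find_units_line(lines)
        m = _UNITS_LINE_RE.match(lines[idx])
        value = m.group(2)
        lines[idx] = m.group(1) + value.swapcase()
    elif cls is CorruptionClass.DROP_REQUIRED_KEY:
        lines = _drop_required_key(lines, rng)
    elif cls is CorruptionClass.SSF_MALFORMED:
        idx_all = [i for i, l in enumerate(lines) if _SSF_LINE_RE.match(l)]
        if not idx_all:
            raise CorruptionInapplicableError("no SUBJECT_SAMPLE_FACTORS rows")
        idx = rng.choice(idx_all)
        cells = lines[idx].split("\t")
        # blank the local sample id (second data cell after the key field)
        if len(cells) < 3:
            raise CorruptionInapplicableError("factor row too short to corrupt")
        cells[2] = ""
        lines[idx] = "\t".join(cells)
    elif cls is CorruptionClass.ROW_ARITY:
        idx = _pick_data_row(lines, rng)
        cells = lines[idx].split("\t")
        lines[idx] = "\t".join(cells[:-1])  # drop the last value cell
    return "\n".join(lines) + "\n", expected


def _find_units_line(lines: list[str]) -> int:
    for i, line in enumerate(lines):
        if _UNITS_LINE_RE.match(line):
            return i
    raise CorruptionInapplicableError("no units line (document has no results table)")


def _pick_data_row(lines: list[str], rng: random.Random) -> int:
    in_table = False
    header_seen = False
    candidates = []
    for i, line in enumerate(lines):
        if re.match(r"^(MS_METABOLITE_DATA|NMR_BINNED_DATA)_START$", line):
            in_table = True
            header_seen = False
            continue
        if re.match(r"^(MS_METABOLITE_DATA|NMR_BINNED_DATA)_END$", line):
            in_table = False
            continue
        if in_table:
            if not header_seen:
                header_seen = True  # skip the Samples/Bin-range header row
                continue
            if line.split("\t")[0] == "Factors":
                continue
            if len(line.split("\t")) > 1:
                candidates.append(i)
    if not candidates:
        raise CorruptionInapplicableError(
            "no multi-cell data rows to corrupt (need >= 1 sample column)"
        )
    return rng.choice(candidates)


def _drop_required_key(lines: list[str], rng: random.Random) -> list[str]:
    """Remove all lines of one seeded-drawn required key present in the text."""
    schemas = default_schemas()
    present: list[tuple[str, str]] = []   # (prefixed key field, code-bearing key)
    section = None
    seen = set()
    for line in lines:
        if line.startswith("#") and not line.startswith("#METABOLOMICS"):
            section = line[1:].strip()
            continue
        if section in schemas and not line.startswith("#") and line:
            key_field = line.split()[0]
            schema = schemas[section]
            prefix = f"{_prefix(section)}:" if _prefix(section) else ""
            bare = key_field[len(prefix):] if key_field.startswith(prefix) else key_field
            if bare in schema.required_keys and key_field not in seen:
                present.append((key_field, bare))
                seen.add(key_field)
    # header-block requireds (VERSION / CREATED_ON) are eligible too
    for key in ("VERSION", "CREATED_ON"):
        if any(l.split() and l.split()[0] == key for l in lines):
            present.append((key, key))
    if not present:
        raise CorruptionInapplicableError("no required keys present to drop")
    key_field, _ = rng.choice(sorted(present))
    return [l for l in lines if not (l.split() and l.split()[0] == key_field)]


def write_corpus(outdir: str | Path, count: int = 10, seed: int = 0,
                 corrupt: dict[CorruptionClass, int] | None = None,
                 platform_mix: bool = True) -> list[Path]:
    """Write a directory of fixture files; returns the written paths.

    ``corrupt`` maps corruption classes to how many of the files receive
    that (single) fault; corrupted files keep their class in the filename.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    faults: list[CorruptionClass | None] = []
    for cls, n in (corrupt or {}).items():
        faults.extend([CorruptionClass(cls)] * n)
    if len(faults) > count:
        raise ValueError("more corrupted files requested than total count")
    faults.extend([None] * (count - len(faults)))
    for i in range(count):
        spec = FixtureSpec(
            seed=seed + i,
            n_samples=3 + (i % 4),
            n_metabolites=5 + 3 * (i % 5),
            platform="NMR" if platform_mix and i % 3 == 2 else "MS",
        )
        text, truth = generate_mwtab_text(spec)
        cls = faults[i]
        stem = truth.analysis_id
        if cls is not None:
            text, _ = inject_corruption(text, cls, seed=seed + i)
            stem += f"_{cls.value.lower()}"
        path = outdir / f"{stem}.txt"
        path.write_text(text, encoding="utf-8")
        paths.append(path)
    return paths
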