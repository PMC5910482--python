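"""Syntactic analysis and serialization.

``tokenize -> build_document`` turns a token stream into an
:class:`~mwtabkit.model.MwTabDocument`; ``write_mwtab`` / ``write_json`` /
``parse_json`` provide the bidirectional mwTab <-> JSON conversion.  Both
serializations are lossless projections of the same document model, so the
set of (section, key, value) triples and all table cells are identical
across them.

Canonical JSON mapping
----------------------
* Top level: one object; keys are section names in document order, plus
  ``"METABOLOMICS WORKBENCH"`` holding the header fields.
* Ordinary sections: object of key -> string.
* SUBJECT_SAMPLE_FACTORS: array of objects with "Subject type", "Sample ID",
  "Factors" (object) and "Additional sample data" (object).
* Results sections: {"Units", "Samples", optional "Factors", "Data"} where
  "Data" is an array of row objects keyed "Metabolite" (or "Bin range" for
  NMR binned data) followed by sample -> value pairs in column order.
  METABOLITES annotation tables use {"Fields", "Data"} (no units concept).
* All scalars are strings; JSON numbers are never emitted (lossless).
"""

from __future__ import annotations

import json
import re
from typing import Iterable

from .errors import MappingError, ParseError
from .model import (
    ANALYSIS_ID_RE,
    HEADER_SECTION,
    RESULTS_KINDS,
    SECTION_PREFIXES,
    SSF_SECTION,
    STUDY_ID_RE,
    DataTable,
    HeaderInfo,
    MwTabDocument,
    Section,
    SubjectSampleFactorRecord,
)
from .tokenizer import LayoutPolicy, Token, TokenKind, tokenize
from .validation_types import ValidationIssue

#: Sentinel/section name -> model table kind.
_TABLE_KIND_BY_NAME = {
    "MS_METABOLITE_DATA": "MS_METABOLITE_DATA",
    "NMR_BINNED_DATA": "NMR_BINNED_DATA",
    "METABOLITES": "METABOLITES",
    "EXTENDED_MS_METABOLITE_DATA": "EXTENDED",
}

#: Canonical first cell of the table header row, per table kind.
_HEADER_LABEL = {
    "MS_METABOLITE_DATA": "Samples",
    "NMR_BINNED_DATA": "Bin range(ppm)",
    "METABOLITES": "metabolite_name",
    "EXTENDED": "Samples",
}

#: Canonical JSON row-object key for the feature column, per table kind.
_FEATURE_JSON_KEY = {
    "MS_METABOLITE_DATA": "Metabolite",
    "NMR_BINNED_DATA": "Bin range",
    "METABOLITES": "Metabolite",
    "EXTENDED": "Metabolite",
}

_HEADER_ID_RE = re.compile(r"(STUDY_ID|ANALYSIS_ID|VERSION|CREATED_ON):(\S+)")


def _finding(severity, code, section, message, key=None, line=None):
    return ValidationIssue(
        severity=severity, code=code, section=section, key=key, line=line,
        message=message,
    )


class _TableBuilder:
    """Accumulates table rows between *_START/*_END sentinels."""

    def __init__(self, name: str, line: int):
        self.name = name
        self.line = line
        self.kind = _TABLE_KIND_BY_NAME.get(name, "EXTENDED")
        self.column_names: list[str] = []
        self.factor_row: list[str] | None = None
        self.rows: list[tuple[str, list[str]]] = []
        self.arity_findings: list[ValidationIssue] = []
        self._saw_header = False

    def header_row(self, cells: list[str]) -> None:
        self.column_names = cells[1:]
        self._saw_header = True

    def data_row(self, cells: list[str], line: int) -> None:
        if not self._saw_header:
            self.header_row(cells)
            return
        feature, values = cells[0], cells[1:]
        if feature == "Factors" and self.factor_row is None and not self.rows:
            self.factor_row = self._align(values, feature, line)
            return
        self.rows.append((feature, self._align(values, feature, line)))

    def _align(self, values: list[str], feature: str, line: int) -> list[str]:
        width = len(self.column_names)
        if len(values) != width:
            self.arity_findings.append(
                _finding(
                    "error", "ROW_ARITY", self.name,
                    f"table row {feature!r} has {len(values)} value cells, "
                    f"expected {width}",
                    key=feature, line=line,
                )
            )
            values = (values + [""] * width)[:width]
        return values

    def build(self, units: str) -> DataTable:
        return DataTable(
            kind=self.kind,
            units=units,
            column_names=self.column_names,
            factor_row=self.factor_row,
            rows=self.rows,
        )


def build_document(tokens: Iterable[Token], source_id: str = "",
                   layout: LayoutPolicy | None = None) -> MwTabDocument:
    """Assemble a document from a token stream (syntactic analysis).

    Repeated item keys within a section are continuation lines, merged into
    one value with the layout's merge separator.  Recoverable defects
    (orphan items, unterminated tables, malformed factor records, row-arity
    mismatches) are attached to the document as parse findings; the only
    fatal condition is the absence of the ``#METABOLOMICS WORKBENCH`` file
    header.
    """
    layout = layout or LayoutPolicy()
    sep = layout.merge_separator
    doc = MwTabDocument(source_id=source_id)
    findings: list[ValidationIssue] = []

    seen_file_header = False
    seen_end = False
    leading_content = False
    current: Section | None = None
    in_header_block = False   # between FILE_HEADER and first section header
    table: _TableBuilder | None = None
    pending_units: dict[str, str] = {}   # section name -> units value

    def close_table(flag_missing_end: bool, line: int) -> None:
        nonlocal table
        if table is None:
            return
        if flag_missing_end:
            findings.append(
                _finding(
                    "error", "TABLE_WITHOUT_END", table.name,
                    f"table {table.name!r} not terminated by {table.name}_END; "
                    "closed at next section boundary",
                    line=line,
                )
            )
        findings.extend(table.arity_findings)
        sec = current
        if sec is None or sec.data_table is not None or sec.ssf_records:
            findings.append(
                _finding(
                    "warning", "UNKNOWN_BLOCK", table.name,
                    f"extra or misplaced table block {table.name!r} discarded",
                    line=table.line,
                )
            )
        else:
            units = pending_units.get(sec.name, "")
            sec.data_table = table.build(units)
        table = None

    def unattributed() -> Section:
        if "UNATTRIBUTED" not in doc.sections:
            doc.add_section(Section(name="UNATTRIBUTED"))
        return doc.sections["UNATTRIBUTED"]

    for tok in tokens:
        if tok.diagnostic == "LEADING_CONTENT":
            leading_content = True
        kind = tok.kind

        if kind is TokenKind.BLANK:
            continue

        if kind is TokenKind.FILE_HEADER:
            seen_file_header = True
            in_header_block = True
            for m in _HEADER_ID_RE.finditer(tok.value or ""):
                doc.header.set(m.group(1), m.group(2))
            continue

        if kind is TokenKind.END_MARKER:
            close_table(flag_missing_end=True, line=tok.line)
            seen_end = True
            current = None
            in_header_block = False
            continue

        if seen_end:
            findings.append(
                _finding(
                    "warning", "TRAILING_CONTENT", current.name if current else "",
                    f"content after #END at line {tok.line}",
                    line=tok.line,
                )
            )
            # fall through: still parse it so nothing is silently lost

        if kind is TokenKind.SECTION_HEADER:
            close_table(flag_missing_end=True, line=tok.line)
            in_header_block = False
            name = tok.key or ""
            if name in doc.sections:
                current = doc.sections[name]
                continue
            try:
                current = doc.add_section(
                    Section(name=name, prefix=SECTION_PREFIXES.get(name, ""))
                )
            except ValueError:
                findings.append(
                    _finding(
                        "warning", "UNKNOWN_SECTION", name or "<empty>",
                        f"malformed section header {('#' + name)!r}; following "
                        "items treated as unattributed",
                        line=tok.line,
                    )
                )
                current = None
            continue

        if kind is TokenKind.ITEM:
            key, value = tok.key or "", tok.value or ""
            if in_header_block and key in ("VERSION", "CREATED_ON",
                                           "STUDY_ID", "ANALYSIS_ID"):
                doc.header.set(key, value)
                continue
            if current is None:
                findings.append(
                    _finding(
                        "error", "ORPHAN_ITEM", "UNATTRIBUTED",
                        f"item {key!r} appears before any section header",
                        key=key, line=tok.line,
                    )
                )
                sec = unattributed()
                _merge_item(sec, key, value, sep)
                continue
            if current.name == SSF_SECTION and key == SSF_SECTION:
                rec, rec_findings = _parse_ssf_value(value, tok.line)
                current.ssf_records.append(rec)
                findings.extend(rec_findings)
                continue
            prefix = current.prefix
            if prefix and key.startswith(prefix + ":"):
                key = key[len(prefix) + 1:]
            if current.data_table is None and key == "UNITS" and table is None:
                pending_units[current.name] = value
                continue
            _merge_item(current, key, value, sep)
            continue

        if kind is TokenKind.TABLE_START:
            close_table(flag_missing_end=True, line=tok.line)
            table = _TableBuilder(tok.key or "", tok.line)
            continue

        if kind is TokenKind.TABLE_HEADER_ROW:
            if table is not None:
                table.header_row(tok.cells or [])
            continue

        if kind is TokenKind.TABLE_DATA_ROW:
            if table is not None:
                table.data_row(tok.cells or [], tok.line)
            continue

        if kind is TokenKind.TABLE_END:
            if table is None:
                findings.append(
                    _finding(
                        "warning", "UNKNOWN_BLOCK",
                        current.name if current else "",
                        f"stray table end sentinel {tok.key}_END",
                        line=tok.line,
                    )
                )
            else:
                close_table(flag_missing_end=False, line=tok.line)
            continue

    close_table(flag_missing_end=True, line=0)

    if not seen_file_header:
        raise ParseError(
            "no '#METABOLOMICS WORKBENCH' file header found", code="NO_FILE_HEADER"
        )
    if leading_content:
        findings.insert(
            0,
            _finding(
                "error", "LEADING_CONTENT", "",
                "content (blank lines or text) precedes the "
                "'#METABOLOMICS WORKBENCH' header",
                line=1,
            ),
        )
    doc.end_marker_seen = seen_end
    doc.parse_findings = findings
    return doc


def _merge_item(sec: Section, key: str, value: str, sep: str) -> None:
    if key in sec.items:
        existing = sec.items[key]
        sec.items[key] = existing + sep + value if value else existing
    else:
        sec.items[key] = value


def _parse_ssf_value(value: str, line: int):
    """Parse one tab-separated SUBJECT_SAMPLE_FACTORS row value.

    Cells: subject type, local sample id, factors ("Name:Value | ..."),
    optional additional data ("key=value; ...").  "-" stands for an empty
    subject/factor cell.
    """
    findings: list[ValidationIssue] = []
    cells = value.split("\t")

    def malformed(msg):
        findings.append(
            _finding("error", "SSF_MALFORMED", SSF_SECTION, msg, line=line)
        )

    subject = cells[0] if cells else ""
    sample = cells[1] if len(cells) > 1 else ""
    factors_cell = cells[2] if len(cells) > 2 else "-"
    extra_cell = cells[3] if len(cells) > 3 else ""
    if len(cells) < 2:
        malformed(f"factor record has {len(cells)} cell(s); expected at least "
                  "subject and sample id")
    if len(cells) > 4:
        malformed(f"factor record has {len(cells)} cells; expected at most 4")
    if not sample:
        malformed("factor record has an empty local sample id")

    factors: dict[str, str] = {}
    if factors_cell not in ("", "-"):
        for part in factors_cell.split(" | "):
            name, colon, val = part.partition(":")
            if not colon or not name.strip():
                malformed(f"factor entry {part!r} is not in 'Name:Value' form")
                continue
            name = name.strip()
            if name in factors:
                malformed(f"duplicate factor name {name!r} in one record")
                continue
            factors[name] = val.strip()

    additional: dict[str, str] = {}
    if extra_cell not in ("", "-"):
        for part in extra_cell.split("; "):
            k, eq, v = part.partition("=")
            if not eq or not k.strip():
                malformed(f"additional-data entry {part!r} is not in 'key=value' form")
                continue
            additional[k.strip()] = v.strip()

    rec = SubjectSampleFactorRecord(
        subject_type="" if subject == "-" else subject,
        local_sample_id=sample,
        factors=factors,
        additional_data=additional,
    )
    return rec, findings


def parse_mwtab(text: str, source_id: str = "",
                layout: LayoutPolicy | None = None) -> MwTabDocument:
    """Parse mwTab text into a document (tokenize + build)."""
    return build_document(tokenize(text), source_id=source_id, layout=layout)


# -- mwTab writer --------------------------------------------------------


def _wrap_value(value: str, width: int | None) -> list[str]:
    """Split a long value at single-space boundaries for continuation lines.

    Only values whose whitespace consists of single spaces are wrapped, so
    that re-merging fragments with a single space is an exact inverse; any
    other value is emitted on one line regardless of width.
    """
    if width is None or len(value) <= width:
        return [value]
    if "\t" in value or "  " in value:
        return [value]
    lines: list[str] = []
    cur: list[str] = []
    cur_len = 0
    for word in value.split(" "):
        add = len(word) if not cur else cur_len + 1 + len(word)
        if cur and add > width:
            lines.append(" ".join(cur))
            cur, cur_len = [word], len(word)
        else:
            cur.append(word)
            cur_len = add
    if cur:
        lines.append(" ".join(cur))
    return lines


def write_mwtab(doc: MwTabDocument, layout: LayoutPolicy | None = None) -> str:
    """Serialize a document to mwTab text (inverse of :func:`parse_mwtab`).

    Sections are emitted in stored order with their key prefixes
    regenerated, long values re-wrapped into repeated-key continuation
    lines, table sentinels restored, and a final ``#END``.
    """
    layout = layout or LayoutPolicy()
    out: list[str] = []

    header_parts = []
    if doc.header.study_id:
        header_parts.append(f"STUDY_ID:{doc.header.study_id}")
    if doc.header.analysis_id:
        header_parts.append(f"ANALYSIS_ID:{doc.header.analysis_id}")
    out.append("#METABOLOMICS WORKBENCH" + (" " + " ".join(header_parts)
                                            if header_parts else ""))
    if doc.header.version:
        out.append(_item_line("VERSION", doc.header.version, layout))
    if doc.header.created_on:
        out.append(_item_line("CREATED_ON", doc.header.created_on, layout))

    for sec in doc.sections.values():
        out.append(f"#{sec.name}")
        prefix = sec.prefix or SECTION_PREFIXES.get(sec.name, "")
        for key, value in sec.items.items():
            full_key = f"{prefix}:{key}" if prefix else key
            for frag in _wrap_value(value, layout.wrap_width):
                out.append(_item_line(full_key, frag, layout))
        for rec in sec.ssf_records:
            out.append(_ssf_line(rec, layout))
        if sec.data_table is not None:
            out.extend(_table_lines(sec, layout))
    out.append("#END")
    return "\n".join(out) + "\n"


def _item_line(key: str, value: str, layout: LayoutPolicy) -> str:
    if not value:
        return key
    if layout.key_width and len(key) < layout.key_width:
        return key.ljust(layout.key_width) + "\t" + value
    return key + "\t" + value


def _ssf_line(rec: SubjectSampleFactorRecord, layout: LayoutPolicy) -> str:
    factors = " | ".join(f"{k}:{v}" for k, v in rec.factors.items()) or "-"
    cells = [rec.subject_type or "-", rec.local_sample_id, factors]
    if rec.additional_data:
        cells.append("; ".join(f"{k}={v}" for k, v in rec.additional_data.items()))
    return _item_line(SSF_SECTION, "\t".join(cells), layout)


def _table_lines(sec: Section, layout: LayoutPolicy) -> list[str]:
    table = sec.data_table
    assert table is not None
    sentinel = sec.name if sec.name in _TABLE_KIND_BY_NAME else table.kind
    lines = []
    if table.kind in RESULTS_KINDS:
        units_key = f"{sec.prefix}:UNITS" if sec.prefix else "UNITS"
        lines.append(_item_line(units_key, table.units, layout))
    lines.append(f"{sentinel}_START")
    lines.append("\t".join([_HEADER_LABEL[table.kind]] + table.column_names))
    if table.factor_row is not None:
        lines.append("\t".join(["Factors"] + table.factor_row))
    for feature, values in table.rows:
        lines.append("\t".join([feature] + values))
    lines.append(f"{sentinel}_END")
    return lines


# -- JSON codec ----------------------------------------------------------


def write_json(doc: MwTabDocument, indent: int | None = 1) -> str:
    """Serialize a document to its canonical JSON representation."""
    top: dict[str, object] = {HEADER_SECTION: doc.header.as_items()}
    for sec in doc.sections.values():
        if sec.name == SSF_SECTION:
            top[sec.name] = [
                {
                    "Subject type": r.subject_type,
                    "Sample ID": r.local_sample_id,
                    "Factors": dict(r.factors),
                    "Additional sample data": dict(r.additional_data),
                }
                for r in sec.ssf_records
            ]
        elif sec.data_table is not None:
            top[sec.name] = _table_to_json(sec)
        else:
            top[sec.name] = dict(sec.items)
    return json.dumps(top, indent=indent, ensure_ascii=False)


def _table_to_json(sec: Section) -> dict[str, object]:
    table = sec.data_table
    assert table is not None
    obj: dict[str, object] = {}
    for key, value in sec.items.items():
        obj[key] = value
    if table.kind in RESULTS_KINDS:
        obj["Units"] = table.units
        obj["Samples"] = list(table.column_names)
        if table.factor_row is not None:
            obj["Factors"] = list(table.factor_row)
    else:
        obj["Fields"] = list(table.column_names)
    fkey = _FEATURE_JSON_KEY[table.kind]
    data = []
    for feature, values in table.rows:
        row: dict[str, str] = {fkey: feature}
        for col, val in zip(table.column_names, values):
            row[col] = val
        data.append(row)
    obj["Data"] = data
    return obj


def parse_json(text: str, source_id: str = "") -> MwTabDocument:
    """Parse canonical-mapping JSON back into a document.

    Raises :class:`json.JSONDecodeError` (with position) for malformed JSON
    and :class:`MappingError` naming the offending key for structurally
    foreign JSON.
    """
    top = json.loads(text)
    if not isinstance(top, dict):
        raise MappingError("top-level JSON value must be an object",
                           code="MAPPING_ERROR")
    doc = MwTabDocument(source_id=source_id)
    for name, payload in top.items():
        if name == HEADER_SECTION:
            if not isinstance(payload, dict):
                raise MappingError(
                    f"{HEADER_SECTION!r} must be an object", code="MAPPING_ERROR"
                )
            for key, value in payload.items():
                doc.header.set(key, _expect_str(name, key, value))
            continue
        if name == SSF_SECTION:
            if not isinstance(payload, list):
                raise MappingError(
                    f"{SSF_SECTION!r} must be an array of factor records",
                    code="MAPPING_ERROR",
                )
            sec = Section(name=name)
            for i, rec in enumerate(payload):
                if not isinstance(rec, dict):
                    raise MappingError(
                        f"{SSF_SECTION}[{i}] must be an object", code="MAPPING_ERROR"
                    )
                sec.ssf_records.append(
                    SubjectSampleFactorRecord(
                        subject_type=str(rec.get("Subject type", "")),
                        local_sample_id=str(rec.get("Sample ID", "")),
                        factors={str(k): str(v)
                                 for k, v in (rec.get("Factors") or {}).items()},
                        additional_data={
                            str(k): str(v)
                            for k, v in (rec.get("Additional sample data") or {}).items()
                        },
                    )
                )
            doc.add_section(sec)
            continue
        if not isinstance(payload, dict):
            raise MappingError(
                f"section {name!r} must be a JSON object", code="MAPPING_ERROR"
            )
        sec = Section(name=name, prefix=SECTION_PREFIXES.get(name, ""))
        if "Data" in payload:
            _table_from_json(sec, name, payload)
        else:
            for key, value in payload.items():
                sec.items[key] = _expect_str(name, key, value)
        doc.add_section(sec)
    return doc


def _expect_str(section: str, key: str, value) -> str:
    if not isinstance(value, str):
        raise MappingError(
            f"value of {section}.{key} must be a JSON string, "
            f"got {type(value).__name__}",
            code="MAPPING_ERROR",
        )
    return value


def _table_from_json(sec: Section, name: str, payload: dict) -> None:
    kind = _TABLE_KIND_BY_NAME.get(name, "EXTENDED")
    columns = payload.get("Samples", payload.get("Fields"))
    if not isinstance(columns, list):
        raise MappingError(
            f"section {name!r} with 'Data' needs a 'Samples' or 'Fields' array",
            code="MAPPING_ERROR",
        )
    columns = [str(c) for c in columns]
    factor_row = payload.get("Factors")
    if factor_row is not None:
        factor_row = [str(c) for c in factor_row]
    data = payload.get("Data")
    if not isinstance(data, list):
        raise MappingError(f"{name}.Data must be an array", code="MAPPING_ERROR")
    fkey = _FEATURE_JSON_KEY[kind]
    rows: list[tuple[str, list[str]]] = []
    for i, row in enumerate(data):
        if not isinstance(row, dict):
            raise MappingError(f"{name}.Data[{i}] must be an object",
                               code="MAPPING_ERROR")
        feature = str(row.get(fkey, ""))
        rows.append((feature, [str(row.get(col, "")) for col in columns]))
    for key, value in payload.items():
        if key in ("Units", "Samples", "Fields", "Factors", "Data"):
            continue
        sec.items[key] = _expect_str(name, key, value)
    sec.data_table = DataTable(
        kind=kind,
        units=str(payload.get("Units", "")),
        column_names=columns,
        factor_row=factor_row,
        rows=rows,
    )
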