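"""Batch conversion between mwTab text and its JSON representation.

A single resolved source converts to a single output file; a directory or
archive converts to a directory or archive with member names preserved and
extensions swapped (``.txt``/``.mwtab`` <-> ``.json``).  Output compression
is inferred from the output address extension (``.zip``, ``.tar.gz``,
``.tar.bz2``).  Per-file failures are recorded in the report, not raised.
"""

from __future__ import annotations

import io
import tarfile
import time
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from .codec import parse_json, parse_mwtab, write_json, write_mwtab
from .errors import MwTabError, SourceError
from .fileio import ARCHIVE_SUFFIXES, FetchConfig, SourceSpec, open_text, resolve_source
from .model import MwTabDocument
from .validation_types import ValidationIssue

FORMATS = ("mwtab", "json")
_EXT = {"mwtab": ".txt", "json": ".json"}


@dataclass
class ConversionReport:
    files_converted: int = 0
    failures: list[tuple[str, Exception]] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)


def _parse(text: str, fmt: str | None, source_id: str) -> MwTabDocument:
    if fmt == "json":
        return parse_json(text, source_id=source_id)
    if fmt == "mwtab":
        return parse_mwtab(text, source_id=source_id)
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return parse_json(text, source_id=source_id)
    return parse_mwtab(text, source_id=source_id)


def _render(doc: MwTabDocument, fmt: str) -> str:
    return write_json(doc) if fmt == "json" else write_mwtab(doc)


def _member_name(spec: SourceSpec, to_format: str) -> str:
    name = Path(spec.member if spec.member else spec.address).name
    stem = name
    for ext in (".txt", ".mwtab", ".json"):
        if name.lower().endswith(ext):
            stem = name[: -len(ext)]
            break
    return stem + _EXT[to_format]


def _archive_kind(address: str) -> str | None:
    lower = address.lower()
    for suffix, comp in ARCHIVE_SUFFIXES.items():
        if lower.endswith(suffix):
            return comp
    return None


def convert(in_address: str, out_address: str,
            from_format: str | None = None, to_format: str = "json",
            overwrite: bool = False,
            config: FetchConfig | None = None) -> ConversionReport:
    """Convert every file resolved from ``in_address`` into ``to_format``.

    ``from_format`` may be omitted (auto-detected per file from the first
    non-blank character); explicit formats are enforced, so a format
    mismatch becomes a per-file failure.  Raises :class:`SourceError` with
    code OUTPUT_EXISTS when the target exists and ``overwrite`` is unset,
    or UNRESOLVABLE_INPUT when the input address resolves to nothing.
    """
    if from_format is not None and from_format not in FORMATS:
        raise ValueError(f"from_format must be one of {FORMATS}")
    if to_format not in FORMATS:
        raise ValueError(f"to_format must be one of {FORMATS}")
    config = config or FetchConfig()

    try:
        specs = resolve_source(in_address, config)
    except SourceError as exc:
        raise SourceError(
            f"cannot resolve input {in_address!r}: {exc}", code="UNRESOLVABLE_INPUT"
        ) from exc
    if not specs:
        raise SourceError(
            f"input {in_address!r} resolved to no files", code="UNRESOLVABLE_INPUT"
        )

    out_path = Path(out_address)
    out_comp = _archive_kind(out_address)
    single = len(specs) == 1 and out_comp is None and not out_path.is_dir()
    if (single or out_comp is not None) and out_path.exists() and not overwrite:
        raise SourceError(
            f"output {out_address!r} exists (use overwrite)", code="OUTPUT_EXISTS"
        )

    report = ConversionReport()
    converted: list[tuple[str, str]] = []  # (member name, rendered text)
    study_ids: list[str] = []

    for spec in specs:
        try:
            text = open_text(spec, config)
            doc = _parse(text, from_format, spec.display)
            rendered = _render(doc, to_format)
        except (MwTabError, ValueError) as exc:
            report.failures.append((spec.display, exc))
            continue
        converted.append((_member_name(spec, to_format), rendered))
        study_ids.append(doc.header.study_id)
        report.files_converted += 1

    # batch STUDY_ID coherence: when a dominant study id exists (shared by
    # more than half the batch), flag each disagreeing member
    non_empty = [s for s in study_ids if s]
    if len(set(non_empty)) > 1:
        majority = max(set(non_empty), key=non_empty.count)
        if non_empty.count(majority) * 2 > len(non_empty):
            for (name, _), sid in zip(converted, study_ids):
                if sid and sid != majority:
                    report.warnings.append(
                        ValidationIssue(
                            severity="warning",
                            code="ID_MISMATCH",
                            section="METABOLOMICS WORKBENCH",
                            key="STUDY_ID",
                            message=f"batch member {name!r} has STUDY_ID {sid!r}; "
                                    f"the rest of the batch uses {majority!r}",
                        )
                    )

    if single:
        name, rendered = converted[0] if converted else (None, None)
        if rendered is not None:
            out_path.parent.mkdir(parents=True, exist_ok=True)
            out_path.write_text(rendered, encoding="utf-8")
            report.outputs.append(str(out_path))
        return report

    if out_comp is None:
        out_path.mkdir(parents=True, exist_ok=True)
        for name, rendered in converted:
            target = out_path / name
            if target.exists() and not overwrite:
                report.failures.append(
                    (str(target), SourceError(f"output member {name!r} exists",
                                              code="OUTPUT_EXISTS"))
                )
                report.files_converted -= 1
                continue
            target.write_text(rendered, encoding="utf-8")
            report.outputs.append(str(target))
        return report

    out_path.parent.mkdir(parents=True, exist_ok=True)
    if out_comp == "zip":
        with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name, rendered in converted:
                zf.writestr(name, rendered)
    else:
        mode = "w:gz" if out_comp == "gzip-tar" else "w:bz2"
        with tarfile.open(out_path, mode) as tf:
            for name, rendered in converted:
                data = rendered.encode("utf-8")
                info = tarfile.TarInfo(name=name)
                info.size = len(data)
                info.mtime = int(time.time())
                tf.addfile(info, io.BytesIO(data))
    report.outputs.append(str(out_path))
    return report
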