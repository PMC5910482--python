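"""Multi-source streaming I/O.

:func:`resolve_source` turns a heterogeneous address — local file,
directory, zip/tar.gz/tar.bz2 archive, http(s) URL, or a bare repository
identifier such as ``AN000001`` — into an ordered list of
:class:`SourceSpec` records.  :func:`read_files` then streams parsed
documents one at a time (at most one file's text is materialized
concurrently), auto-detecting the mwTab vs JSON format from the first
non-blank character.

Network access is off by default; repository identifiers expand to REST
URLs through configurable templates so tests never touch the network.
"""

from __future__ import annotations

import io
import re
import tarfile
import urllib.error
import urllib.request
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .codec import parse_json, parse_mwtab
from .errors import MwTabError, SourceError
from .model import MwTabDocument

_ANALYSIS_ID_RE = re.compile(r"^AN\d+$")
_STUDY_ID_RE = re.compile(r"^ST\d+$")
_ID_LIKE_RE = re.compile(r"^(AN|ST)[\w-]*$")

ARCHIVE_SUFFIXES = {
    ".zip": "zip",
    ".tar.gz": "gzip-tar",
    ".tgz": "gzip-tar",
    ".tar.bz2": "bzip2-tar",
}
_SUSPECT_ARCHIVE_SUFFIXES = (".tar.xz", ".txz", ".7z", ".rar", ".tar", ".gz", ".bz2", ".xz")


@dataclass
class FetchConfig:
    """I/O configuration.

    ``allow_network`` gates URL and identifier sources (off by default).
    ``analysis_url_template`` / ``study_url_template`` expand bare AN/ST
    identifiers to Metabolomics Workbench REST addresses.  ``extensions``
    are the file suffixes accepted when scanning directories and archives.
    """

    allow_network: bool = False
    analysis_url_template: str = (
        "https://www.metabolomicsworkbench.org/rest/study/analysis_id/"
        "{analysis_id}/mwtab/txt"
    )
    study_url_template: str = (
        "https://www.metabolomicsworkbench.org/rest/study/study_id/"
        "{study_id}/mwtab/txt"
    )
    fail_fast: bool = False
    extensions: tuple[str, ...] = (".txt", ".mwtab", ".json")
    encoding: str = "utf-8"
    timeout: float = 30.0


@dataclass
class SourceSpec:
    """Resolved description of where one file comes from."""

    kind: str  # local_file | directory | archive_member | url | analysis_id
    address: str
    member: str | None = None
    compression: str = "none"  # none | zip | gzip-tar | bzip2-tar

    def __post_init__(self):
        if self.kind == "archive_member" and self.member is None:
            raise ValueError("archive_member spec requires a member name")
        if self.kind != "archive_member" and self.member is not None:
            raise ValueError(f"{self.kind} spec cannot carry a member name")

    @property
    def display(self) -> str:
        return f"{self.address}#{self.member}" if self.member else self.address


@dataclass
class ErrorRecord:
    """Per-file failure yielded (not raised) by :func:`read_files`."""

    address: str
    error: Exception


def _archive_compression(name: str) -> str | None:
    lower = name.lower()
    for suffix, comp in ARCHIVE_SUFFIXES.items():
        if lower.endswith(suffix):
            return comp
    return None


def _accepted(name: str, config: FetchConfig) -> bool:
    return name.lower().endswith(tuple(e.lower() for e in config.extensions))


def resolve_source(address: str, config: FetchConfig | None = None) -> list[SourceSpec]:
    """Resolve one address into an ordered list of source specs.

    A directory expands to one spec per contained file with an accepted
    extension (lexicographic order); an archive to one spec per member in
    archive order; bare ``AN...``/``ST...`` identifiers to one analysis_id
    spec.  Raises :class:`SourceError` (NOT_FOUND, UNSUPPORTED_ARCHIVE,
    UNRECOGNIZED_ADDRESS) on failure.
    """
    config = config or FetchConfig()
    if not address:
        raise SourceError("empty source address", code="UNRECOGNIZED_ADDRESS")

    if address.startswith(("http://", "https://")):
        return [SourceSpec(kind="url", address=address)]

    path = Path(address)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.is_file() and _accepted(p.name, config)
        )
        return [SourceSpec(kind="local_file", address=str(p)) for p in files]

    if path.is_file():
        comp = _archive_compression(path.name)
        if comp == "zip":
            with zipfile.ZipFile(path) as zf:
                members = [
                    n for n in zf.namelist()
                    if not n.endswith("/") and _accepted(n, config)
                ]
            return [
                SourceSpec(kind="archive_member", address=str(path), member=m,
                           compression="zip")
                for m in members
            ]
        if comp in ("gzip-tar", "bzip2-tar"):
            mode = "r:gz" if comp == "gzip-tar" else "r:bz2"
            with tarfile.open(path, mode) as tf:
                members = [
                    m.name for m in tf.getmembers()
                    if m.isfile() and _accepted(m.name, config)
                ]
            return [
                SourceSpec(kind="archive_member", address=str(path), member=m,
                           compression=comp)
                for m in members
            ]
        if path.name.lower().endswith(_SUSPECT_ARCHIVE_SUFFIXES):
            raise SourceError(
                f"unsupported archive format: {address!r} (supported: "
                ".zip, .tar.gz, .tar.bz2)",
                code="UNSUPPORTED_ARCHIVE",
            )
        return [SourceSpec(kind="local_file", address=str(path))]

    if _ANALYSIS_ID_RE.match(address) or _STUDY_ID_RE.match(address):
        return [SourceSpec(kind="analysis_id", address=address)]
    if _ID_LIKE_RE.match(address):
        raise SourceError(
            f"malformed repository identifier {address!r} (expected AN or ST "
            "followed by digits)",
            code="UNRECOGNIZED_ADDRESS",
        )
    raise SourceError(f"no such file or directory: {address!r}", code="NOT_FOUND")


def open_text(spec: SourceSpec, config: FetchConfig | None = None) -> str:
    """Return the decoded text of one resolved source.

    Raises :class:`SourceError` with source context for I/O failures, HTTP
    errors (with status) and NETWORK_DISABLED when a url/analysis_id source
    is opened without ``config.allow_network``.
    """
    config = config or FetchConfig()
    try:
        if spec.kind == "local_file":
            return Path(spec.address).read_text(encoding=config.encoding)
        if spec.kind == "archive_member":
            return _read_archive_member(spec, config)
        if spec.kind in ("url", "analysis_id"):
            url = _expand_url(spec, config)
            if not config.allow_network:
                raise SourceError(
                    f"network access is disabled; cannot fetch {url!r} "
                    "(set FetchConfig.allow_network=True to enable)",
                    code="NETWORK_DISABLED",
                )
            return _fetch_url(url, config)
    except SourceError:
        raise
    except UnicodeDecodeError as exc:
        raise SourceError(
            f"cannot decode {spec.display!r} as {config.encoding}: {exc}",
            code="DECODE_ERROR",
        ) from exc
    except OSError as exc:
        raise SourceError(
            f"I/O error reading {spec.display!r}: {exc}", code="IO_ERROR"
        ) from exc
    raise SourceError(f"unknown source kind {spec.kind!r}",
                      code="UNRECOGNIZED_ADDRESS")


def _read_archive_member(spec: SourceSpec, config: FetchConfig) -> str:
    if spec.compression == "zip":
        with zipfile.ZipFile(spec.address) as zf:
            data = zf.read(spec.member)
    else:
        mode = "r:gz" if spec.compression == "gzip-tar" else "r:bz2"
        with tarfile.open(spec.address, mode) as tf:
            fh = tf.extractfile(spec.member)
            if fh is None:
                raise SourceError(
                    f"member {spec.member!r} not found in {spec.address!r}",
                    code="NOT_FOUND",
                )
            data = fh.read()
    return data.decode(config.encoding)


def _expand_url(spec: SourceSpec, config: FetchConfig) -> str:
    if spec.kind == "url":
        return spec.address
    if _STUDY_ID_RE.match(spec.address):
        return config.study_url_template.format(study_id=spec.address)
    return config.analysis_url_template.format(analysis_id=spec.address)


def _fetch_url(url: str, config: FetchConfig) -> str:
    try:
        with urllib.request.urlopen(url, timeout=config.timeout) as resp:
            data = resp.read()
    except urllib.error.HTTPError as exc:
        raise SourceError(
            f"HTTP {exc.code} fetching {url!r}: {exc.reason}", code="HTTP_ERROR"
        ) from exc
    except urllib.error.URLError as exc:
        raise SourceError(f"cannot fetch {url!r}: {exc.reason}",
                          code="IO_ERROR") from exc
    if isinstance(data, bytes):
        return data.decode(config.encoding)
    return data


def _detect_format(text: str) -> str:
    for ch in text:
        if not ch.isspace():
            return "json" if ch == "{" else "mwtab"
    return "mwtab"


def parse_text(text: str, source_id: str = "", fmt: str | None = None) -> MwTabDocument:
    """Parse text in either format; auto-detect from the first non-blank char."""
    fmt = fmt or _detect_format(text)
    if fmt == "json":
        return parse_json(text, source_id=source_id)
    return parse_mwtab(text, source_id=source_id)


def read_files(*addresses: str,
               config: FetchConfig | None = None,
               fail_fast: bool | None = None,
               ) -> Iterator[MwTabDocument | ErrorRecord]:
    """Lazily yield one parsed document per resolved source.

    Per-file parse or access failures are yielded as :class:`ErrorRecord`
    entries rather than raised mid-stream, unless ``fail_fast`` is set
    (argument overrides ``config.fail_fast``).
    """
    config = config or FetchConfig()
    strict = config.fail_fast if fail_fast is None else fail_fast
    for address in addresses:
        try:
            specs = resolve_source(address, config)
        except MwTabError as exc:
            if strict:
                raise
            yield ErrorRecord(address=address, error=exc)
            continue
        for spec in specs:
            try:
                text = open_text(spec, config)
                doc = parse_text(text, source_id=spec.display)
            except (MwTabError, ValueError) as exc:
                if strict:
                    raise
                yield ErrorRecord(address=spec.display, error=exc)
                continue
            yield doc
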