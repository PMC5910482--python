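"""Shared validation datatypes (kept import-light: used by codec and validation)."""

from __future__ import annotations

from dataclasses import dataclass

#: Closed set of machine-readable issue codes.
ISSUE_CODES = frozenset({
    "MISSING_REQUIRED_FIELD",
    "CONSTRAINT_VIOLATION",
    "UNKNOWN_KEY",
    "UNKNOWN_SECTION",
    "UNKNOWN_BLOCK",
    "MISSING_END",
    "LEADING_CONTENT",
    "TRAILING_CONTENT",
    "EMPTY_UNITS",
    "SSF_MALFORMED",
    "COLUMN_MISMATCH",
    "ROW_ARITY",
    "ID_MISMATCH",
    "ORPHAN_ITEM",
    "TABLE_WITHOUT_END",
})

SEVERITIES = ("error", "warning")


@dataclass
class ValidationIssue:
    """One structured validation finding.

    Findings are collected, never thrown; ``severity`` is ``"error"`` for
    structural format breaches and missing required metadata, ``"warning"``
    for recoverable or advisory conditions.
    """

    severity: str
    code: str
    section: str
    message: str
    key: str | None = None
    line: int | None = None

    def __post_init__(self):
        if self.severity not in SEVERITIES:
            raise ValueError(f"invalid severity {self.severity!r}")
        if self.code not in ISSUE_CODES:
            raise ValueError(f"unknown issue code {self.code!r}")
        if not self.message:
            raise ValueError("issue message must be non-empty")

    def as_dict(self) -> dict:
        return {
            "severity": self.severity,
            "code": self.code,
            "section": self.section,
            "key": self.key,
            "line": self.line,
            "message": self.message,
        }

    def __str__(self) -> str:
        loc = self.section or "<file>"
        if self.key:
            loc += f".{self.key}"
        if self.line:
            loc += f" (line {self.line})"
        return f"{self.severity.upper()} {self.code} {loc}: {self.message}"
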