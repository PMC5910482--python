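"""Exception hierarchy.

Every exception carries a stable machine ``code`` so callers (and the CLI)
can branch on failure class without string matching.
"""

from __future__ import annotations


class MwTabError(Exception):
    """Base class for all mwtabkit errors."""

    code: str = "ERROR"

    def __init__(self, message: str, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class ParseError(MwTabError):
    """Fatal syntactic failure (e.g. no ``#METABOLOMICS WORKBENCH`` header)."""

    code = "PARSE_ERROR"


class MappingError(MwTabError):
    """JSON that does not follow the canonical mwTab mapping."""

    code = "MAPPING_ERROR"


class SourceError(MwTabError):
    """File/URL/archive resolution or access failure."""

    code = "SOURCE_ERROR"


class SchemaLoadError(MwTabError):
    """A user-supplied schema file that cannot be interpreted."""

    code = "SCHEMA_LOAD_ERROR"


class UnknownSectionError(MwTabError, KeyError):
    code = "UNKNOWN_SECTION"


class UnknownKeyError(MwTabError, KeyError):
    code = "UNKNOWN_KEY"


class CorruptionInapplicableError(MwTabError):
    """Requested corruption class cannot be applied to this document."""

    code = "INAPPLICABLE"
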