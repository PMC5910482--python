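"""Lexical analysis of mwTab text.

:func:`tokenize` splits raw text into a flat stream of typed tokens with
1-based line numbers, without building any cross-line structure (that is the
codec's job).  Tokenization is total: every decodable line becomes exactly
one token, and irregular lines carry a diagnostic instead of raising, so
that the validator — not the lexer — decides severity.

:func:`detoken_line` is the inverse used by the writer: for any well-formed
token, ``tokenize(detoken_line(tok))`` reproduces a token with the same
kind, key, value and cells.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator


class TokenKind(str, Enum):
    FILE_HEADER = "FILE_HEADER"
    SECTION_HEADER = "SECTION_HEADER"
    ITEM = "ITEM"
    TABLE_START = "TABLE_START"
    TABLE_HEADER_ROW = "TABLE_HEADER_ROW"
    TABLE_DATA_ROW = "TABLE_DATA_ROW"
    TABLE_END = "TABLE_END"
    END_MARKER = "END_MARKER"
    BLANK = "BLANK"


@dataclass
class Token:
    """Typed lexical unit with line provenance.

    ``key``/``value`` are set for ITEM, SECTION_HEADER (key = section name),
    TABLE_START/END (key = table name) and FILE_HEADER (value = text after
    the header string).  ``cells`` is set for table rows.  ``diagnostic``
    flags recoverable irregularities (currently ``LEADING_CONTENT`` for any
    line before the file header).
    """

    kind: TokenKind
    line: int
    key: str | None = None
    value: str | None = None
    cells: list[str] | None = None
    diagnostic: str | None = None


@dataclass
class LayoutPolicy:
    """Text-layout dialect for the writer.

    ``key_width``: pad the key field with spaces to this width before the
    separating tab (the aligned-column layout of deposited files); ``None``
    means pure single-tab separation.  ``wrap_width``: re-wrap item values
    longer than this many characters into repeated-key continuation lines
    (``None`` disables wrapping).  ``merge_separator`` joins continuation
    fragments at parse time and must therefore match between reader and
    writer for stable round trips.
    """

    key_width: int | None = 33
    wrap_width: int | None = 80
    merge_separator: str = " "


FILE_HEADER_PREFIX = "#METABOLOMICS WORKBENCH"
END_LINE = "#END"

_SENTINEL_RE = re.compile(r"^([A-Z][A-Z0-9_]*)_(START|END)$")
_ITEM_RE = re.compile(r"^(\S+)(?:\s+(.*))?$")


def tokenize(text: str) -> list[Token]:
    """Lex mwTab text into an ordered token stream.

    Accepts LF and CRLF line endings and a UTF-8 BOM; trailing whitespace on
    a line is stripped.  Lines before the first ``#METABOLOMICS WORKBENCH``
    header are tokenized normally but tagged with a ``LEADING_CONTENT``
    diagnostic.  Never raises on decodable text.
    """
    if text.startswith("\ufeff"):
        text = text[1:]
    tokens: list[Token] = []
    seen_header = False
    open_table: str | None = None
    table_row_index = 0

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        diag = None if seen_header else "LEADING_CONTENT"

        if not line:
            tokens.append(Token(TokenKind.BLANK, lineno, diagnostic=diag))
            continue

        if line.startswith("#"):
            # A section header while a table is still open: the builder
            # recovers (TABLE_WITHOUT_END); the lexer just closes its state.
            open_table = None
            if line == END_LINE:
                tokens.append(Token(TokenKind.END_MARKER, lineno, diagnostic=diag))
            elif line.startswith(FILE_HEADER_PREFIX):
                rest = line[len(FILE_HEADER_PREFIX):].strip()
                tokens.append(Token(TokenKind.FILE_HEADER, lineno, value=rest))
                seen_header = True
            else:
                name = line[1:].strip()
                tokens.append(
                    Token(TokenKind.SECTION_HEADER, lineno, key=name, diagnostic=diag)
                )
            continue

        if open_table is not None:
            m = _SENTINEL_RE.match(line)
            if m and m.group(2) == "END":
                tokens.append(
                    Token(TokenKind.TABLE_END, lineno, key=m.group(1), diagnostic=diag)
                )
                open_table = None
                continue
            cells = line.split("\t")
            kind = (
                TokenKind.TABLE_HEADER_ROW
                if table_row_index == 0
                else TokenKind.TABLE_DATA_ROW
            )
            table_row_index += 1
            tokens.append(Token(kind, lineno, cells=cells, diagnostic=diag))
            continue

        m = _SENTINEL_RE.match(line)
        if m:
            name, which = m.groups()
            if which == "START":
                open_table = name
                table_row_index = 0
                tokens.append(
                    Token(TokenKind.TABLE_START, lineno, key=name, diagnostic=diag)
                )
            else:
                # stray *_END without a matching start; builder flags it
                tokens.append(
                    Token(TokenKind.TABLE_END, lineno, key=name, diagnostic=diag)
                )
            continue

        im = _ITEM_RE.match(line) or _ITEM_RE.match(line.strip())
        key, value = im.group(1), im.group(2) or ""
        tokens.append(Token(TokenKind.ITEM, lineno, key=key, value=value, diagnostic=diag))

    return tokens


def detoken_line(tok: Token, layout: LayoutPolicy | None = None) -> str:
    """Render one token back into its text line (inverse of :func:`tokenize`).

    With a fixed-width layout, keys longer than the key column fall back to
    single-tab separation.
    """
    layout = layout or LayoutPolicy()
    if tok.kind is TokenKind.BLANK:
        return ""
    if tok.kind is TokenKind.END_MARKER:
        return END_LINE
    if tok.kind is TokenKind.FILE_HEADER:
        return FILE_HEADER_PREFIX + (f" {tok.value}" if tok.value else "")
    if tok.kind is TokenKind.SECTION_HEADER:
        return f"#{tok.key}"
    if tok.kind is TokenKind.TABLE_START:
        return f"{tok.key}_START"
    if tok.kind is TokenKind.TABLE_END:
        return f"{tok.key}_END"
    if tok.kind in (TokenKind.TABLE_HEADER_ROW, TokenKind.TABLE_DATA_ROW):
        return "\t".join(tok.cells or [])
    if tok.kind is TokenKind.ITEM:
        key = tok.key or ""
        value = tok.value or ""
        if not value:
            return key
        if layout.key_width and len(key) < layout.key_width:
            return key.ljust(layout.key_width) + "\t" + value
        return key + "\t" + value
    raise ValueError(f"cannot render token kind {tok.kind!r}")


def detokenize(tokens: Iterable[Token], layout: LayoutPolicy | None = None) -> Iterator[str]:
    """Render a token stream into text lines (LF joining is the caller's)."""
    for tok in tokens:
        yield detoken_line(tok, layout)
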