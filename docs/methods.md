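# Methods

## The format and the document model

An mwTab file is a line-oriented flat file. The first line is the
`#METABOLOMICS WORKBENCH` header, optionally carrying `STUDY_ID:ST…` and
`ANALYSIS_ID:AN…` tokens; `VERSION` and `CREATED_ON` items may follow
before the first block. Each `#NAME` line opens a block. Within a block,
an item line is a key field followed by a whitespace run and a value; a
long value is expressed by repeating the key on successive lines
(continuation). The `SUBJECT_SAMPLE_FACTORS` block holds one tab-separated
row per sample (subject type, local sample id, `Name:Value` factor pairs
joined by `" | "`, optional `key=value` annotations joined by `"; "`).
Results blocks wrap a tab-separated matrix between `NAME_START`/`NAME_END`
sentinels: a header row of sample labels, an optional `Factors` row, then
one row per feature. `#END` terminates the file.

`MwTabDocument` mirrors this exactly: an ordered mapping of sections, each
holding ordered items, factor records, or a data table. Three modelling
decisions matter:

* **Everything is text.** Cell values and metadata are stored verbatim as
  strings, never coerced to numbers. This is what makes both round trips
  (mwTab → model → mwTab, model → JSON → model) exact: `12.10` stays
  `12.10`.
* **Prefixes are presentation.** Block-specific key prefixes (`PR:`,
  `ST:`, …, and the block-name prefixes of data sections) are stripped at
  parse time and regenerated from a fixed section → prefix table at write
  time, so keys are clean identifiers in the API.
* **The file header is a pseudo-section.** VERSION, CREATED_ON, STUDY_ID
  and ANALYSIS_ID live in a `HeaderInfo` record but are addressable as
  `doc["METABOLOMICS WORKBENCH"][...]` for uniform access.

Equality of documents compares header fields, section order, item order,
values, factor records and table contents; provenance (`source_id`) and
recoverable parse findings are excluded, so the same content read from a
directory and from an archive compares equal.

## Lexing and parsing

The tokenizer is total: every decodable line becomes exactly one typed
token (file header, section header, item, table sentinel/row, end marker,
blank), and irregular input is tagged with diagnostics rather than
raised — the validator, not the lexer, decides severity. Item lines split
on the first whitespace run after the key field, which accepts both
tab-separated and space-aligned layouts found in deposited files; line
endings may be LF or CRLF and trailing whitespace is stripped from values.

The builder assembles sections in order, merges repeated keys
(continuation) with a single-space separator, and recovers from the defect
classes seen in real repository files: content before the header
(`LEADING_CONTENT`), items before any section (`ORPHAN_ITEM`, diverted to
a synthetic UNATTRIBUTED section), tables not closed by their end sentinel
(`TABLE_WITHOUT_END`, closed at the next section boundary), and rows whose
cell count disagrees with the header (`ROW_ARITY`; such rows are padded
with empty cells or truncated so the in-memory table stays rectangular,
and the defect is reported with its line number). The only fatal parse
error is the absence of the `#METABOLOMICS WORKBENCH` header.

### Writer layout

The writer is parameterised by a `LayoutPolicy`: a fixed-width key column
(default 33 characters, matching the aligned layout of deposited files; a
pure single-tab dialect is available), and value re-wrapping (default 80
value characters) into repeated-key continuation lines. Wrapping only
splits at single-space boundaries — a value containing tabs or runs of
spaces is emitted on one line regardless of width — so re-merging
fragments with a single space is an exact inverse and round trips stay
byte-stable. The continuation separator itself is configurable; it must
match between reader and writer.

## The JSON mapping

One top-level object, keys in document order, with
`"METABOLOMICS WORKBENCH"` holding the four header fields. Ordinary
sections are string-to-string objects. `SUBJECT_SAMPLE_FACTORS` is an
array of `{"Subject type", "Sample ID", "Factors", "Additional sample
data"}` objects. Results sections are `{"Units", "Samples", optional
"Factors", "Data"}` with one row object per feature, keyed `"Metabolite"`
(or `"Bin range"` for NMR binned data) followed by sample → value pairs in
column order; the METABOLITES annotation table uses `{"Fields", "Data"}`
as it has no units concept. All scalars are JSON strings — numbers are
never emitted, for the same losslessness reason as above. The first cell
of a table's text header row ("Samples", "Bin range(ppm)",
"metabolite_name") is canonical per table kind rather than stored, since
the JSON mapping has no slot for it; this keeps both serializations exact
inverses after a first parse.

## Validation

Each block has a schema: required keys, optional keys, and per-key value
rules (regular expression or enumeration). The bundled schema file follows
the official specification — the PROJECT block requires PROJECT_TITLE,
PROJECT_SUMMARY, INSTITUTE, LAST_NAME, FIRST_NAME, ADDRESS, EMAIL and
PHONE, with eight optional fields (PROJECT_TYPE, DEPARTMENT, LABORATORY,
FUNDING_SOURCE, PROJECT_COMMENTS, PUBLICATIONS, CONTRIBUTIONS, DOI) — and
can be replaced wholesale by a user file in the same JSON dialect. The
EMAIL rule requires one `@` with a dotted domain; the PHONE rule accepts
seven or more characters drawn from digits, space and `+-().`. Both are
schema data, not code, and deliberately permissive: their job is to catch
structurally impossible values, not to police international formats.

Findings are data, never exceptions, each with a severity, a stable
machine code from a closed set, the section/key/line, and a human-readable
message. Severity policy: structural breaches and missing required
metadata are errors (MISSING_END, LEADING_CONTENT, EMPTY_UNITS,
MISSING_REQUIRED_FIELD, CONSTRAINT_VIOLATION, SSF_MALFORMED, ROW_ARITY,
ORPHAN_ITEM, TABLE_WITHOUT_END); advisory conditions are warnings
(UNKNOWN_KEY, UNKNOWN_SECTION, UNKNOWN_BLOCK, TRAILING_CONTENT,
COLUMN_MISMATCH, ID_MISMATCH). Real repository files violate the
specification yet remain usable, so validation never fail-fasts and the
CLI derives its exit status from the maximum severity.

Consistency checks span blocks: the results table's sample-column count
against the factor-record count (COLUMN_MISMATCH), re-reported row-arity
defects, and the header analysis id against an `AN…` identifier embedded
in the source path (ID_MISMATCH). Cross-file consistency is limited to
STUDY_ID coherence within a conversion batch: when more than half of a
batch shares one study id, each disagreeing member is flagged once.

`survey_units` tallies the mandatory units value of every results table in
a document stream (empty values counted as missing), optionally
case-folding so spelling variants such as "Peak height" and "peak height"
merge. Only the MS/NMR results tables are surveyed — the METABOLITES
annotation table has no units requirement, so counting it would
misrepresent the missing-units rate.

## Synthetic fixtures

The generator emulates the full block structure of a deposited analysis:
header with synthetic ST/AN identifiers, complete PROJECT/STUDY/SUBJECT/
COLLECTION/TREATMENT/SAMPLEPREP blocks (plus CHROMATOGRAPHY and MS, or
NMR, by platform), one factor record per sample, a results matrix of
uniform pseudo-random decimals rendered at fixed precision, and a
METABOLITES annotation table for MS. Default scale is 6 samples × 40
features with 2 experimental factors — the shape of a small deposited
study — with bounds of 10⁴ samples and 10⁵ features. Metabolite names come
from a bundled list of real metabolite names; values are uniform on
[0, 10⁵], which exercises the format without pretending to be a realistic
concentration distribution. All randomness flows from `FixtureSpec.seed`
through one `random.Random` instance, so a spec renders byte-identical
text every time.

What the fixtures do **not** emulate: the long free-text protocol fields,
vendor-specific optional keys, multi-analysis studies sharing one study
id, and the historical layout quirks of hand-edited depositions beyond the
injected defect classes. Passing tests therefore demonstrate correctness
of the format mechanics and defect detection, not robustness to every
artefact in the wild.

The corruption injector introduces exactly one defect per call and returns
the issue codes the validator must report: leading blank lines, removed
`#END`, blanked mandatory units, a seeded-drawn required key dropped (all
of its continuation lines), a blanked sample id in one factor row, one
cell removed from one data row, and a case-swapped units string. The last
class maps to an empty expected-code set for single-file validation — a
case variant is only observable when surveying units across files — and
its contract is exercised through the case-folded survey instead.

## Numerical and procedural choices

* Continuation merge separator: single space (summaries read naturally);
  configurable via `LayoutPolicy`.
* Directory members are read in lexicographic order; archive members in
  archive order (mirroring streaming decompression). Source-equivalence
  guarantees therefore assume archives built in sorted order.
* Accepted extensions when scanning directories/archives: `.txt`,
  `.mwtab`, `.json` (case-insensitive); repository files are `.txt`.
* Format auto-detection reads the first non-blank character (`{` → JSON).
* Network access is off by default; bare `AN`/`ST` identifiers expand
  through configurable REST URL templates, and tests replace the opener
  rather than touching the network.
* Degenerate inputs: empty text is a fatal parse error (no file header);
  an empty table (no data rows) and a one-sample matrix are legal; an
  empty factor cell is written as `-` and read back as empty.

## Problem sizes in the checks

The round-trip sweep uses 100 seeded fixtures spanning MS/NMR, 1–50
samples and 1–500 features; fault detection uses all seven corruption
classes × 20 seeds; source equivalence uses an 8-file corpus rendered as a
directory and three archive formats. These sizes exercise every code path
(single-sample and single-feature edge shapes included) while keeping the
whole suite near-instant, and the acceptance script recomputes all of the
reported quantities from scratch at run time.

## Known limitations

* The official specification's continuation-merge separator is not
  normative here; a file whose long values were wrapped with a different
  convention will merge with single spaces.
* Multiple results tables in one section are flagged and dropped rather
  than modelled; one results table plus one METABOLITES table per document
  is the supported shape.
* Validation is structural and lexical — no ontology checking of factor
  names, no RefMet/chemical-identifier resolution, and no statistics on
  the measurement matrices.
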