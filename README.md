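# mwtabkit

Read, write, convert and validate **mwTab** files — the flat-file
deposition and exchange format of the Metabolomics Workbench Data
Repository.

An mwTab file describes one metabolomics analysis as a sequence of
`#`-prefixed text blocks: key–value metadata blocks (`#PROJECT`, `#STUDY`,
`#SUBJECT`, `#ANALYSIS`, …), a `#SUBJECT_SAMPLE_FACTORS` block mapping each
sample to its subject and experimental factor values, and results blocks
(`#MS_METABOLITE_DATA`, `#NMR_BINNED_DATA`) holding a feature-by-sample
matrix with a mandatory units field, terminated by `#END`. Every analysis
carries a study identifier (`ST######`, shared across analyses of one
study) and a unique analysis identifier (`AN######`).

`mwtabkit` is for anyone consuming or auditing these files: it parses them
into an ordered document model with pythonic bracket access, converts them
losslessly to and from an equivalent JSON representation (so the data is
usable from any language with a JSON parser), streams them one at a time
from files, directories, zip/tar.gz/tar.bz2 archives, URLs or bare analysis
identifiers, and validates format and required metadata against per-block
schema definitions derived from the official format specification — with
structured, machine-readable findings rather than exceptions.

## What's inside

| Module | Responsibility |
| --- | --- |
| `mwtabkit.model` | ordered document model (`MwTabDocument`, sections, factor records, data tables) |
| `mwtabkit.tokenizer` | lexical analysis: raw text → typed tokens with line numbers |
| `mwtabkit.codec` | syntactic analysis and the bidirectional mwTab ↔ JSON serialization |
| `mwtabkit.fileio` | source resolution and lazy streaming (`read_files`) |
| `mwtabkit.validation` | per-block schemas, document validation, consistency checks, units survey |
| `mwtabkit.converter` + `mwtabkit.cli` | batch conversion and the `mwtabkit` command-line tool |
| `mwtabkit.fixtures` | deterministic synthetic-file generator and single-fault corruption injector |

## Worked example

```python
from mwtabkit import FixtureSpec, generate_mwtab_text, parse_mwtab, validate_document

text, truth = generate_mwtab_text(FixtureSpec(seed=1, n_samples=4, n_metabolites=8))
doc = parse_mwtab(text, source_id=f"{truth.analysis_id}.txt")

print("analysis id:", doc["METABOLOMICS WORKBENCH"]["ANALYSIS_ID"])
print("project title:", doc["PROJECT"]["PROJECT_TITLE"])
print("first data row:", doc.data_table.rows[0])
print("findings:", validate_document(doc))
```

prints

```
analysis id: AN596854
project title: Synthetic metabolomics project ST140892
first data row: ('alanine', ['48022.7', '74373.1', '40428.8', '66474.4'])
findings: []
```

The analysis id is the synthetic deposition identifier; the data row is one
metabolite's measured values (kept verbatim as strings — numeric
interpretation is deliberately left to the consumer so that round trips are
byte-faithful); the empty findings list says the file satisfies every
block schema and structural rule. The `examples/` directory holds one short
script per capability (access, conversion, validation of corrupted files,
units survey, archive streaming).

On the command line:

```sh
mwtabkit convert AN000001.txt AN000001.json --from_format=mwtab --to_format=json
mwtabkit validate AN000001.txt
mwtabkit fixtures ./corpus --count 10 --seed 1 --corrupt MISSING_END
```

`validate` exits 0 when no errors are found, 1 when validation errors are
reported, 2 on usage errors and 3 on I/O failures.

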