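"""Generate a small mwTab file, parse it and access metadata pythonically."""

from mwtabkit import FixtureSpec, generate_mwtab_text, parse_mwtab

text, truth = generate_mwtab_text(FixtureSpec(seed=1, n_samples=4, n_metabolites=8))
doc = parse_mwtab(text, source_id=f"{truth.analysis_id}.txt")

print("analysis id:", doc["METABOLOMICS WORKBENCH"]["ANALYSIS_ID"])
print("project title:", doc["PROJECT"]["PROJECT_TITLE"])
print("samples:", [r.local_sample_id
                   for r in doc.sections["SUBJECT_SAMPLE_FACTORS"].ssf_records])
print("first data row:", doc.data_table.rows[0])

# The analysis id identifies this deposition; the data row is one
# metabolite's measured values (verbatim strings) across the four samples.
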