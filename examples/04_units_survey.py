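"""Survey the mandatory units field across a corpus, merging case variants."""

from mwtabkit import FixtureSpec, generate_document, survey_units

docs = []
for i, units in enumerate(["Peak height", "Peak height", "peak height",
                           "peak area", ""]):
    doc, _ = generate_document(FixtureSpec(seed=i, n_samples=2,
                                           n_metabolites=3, units=units))
    docs.append(doc)

print("verbatim:", survey_units(docs).tally)
folded = survey_units(docs, "case-folded")
print("case-folded:", folded.tally, "| missing:", folded.missing_count)

# Case-folding merges spelling variants of the same unit; the missing count
# exposes results tables whose required units value is empty.
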