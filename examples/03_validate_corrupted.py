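"""Inject known defects into a valid file and watch the validator find them."""

from mwtabkit import (CorruptionClass, FixtureSpec, generate_mwtab_text,
                      inject_corruption, parse_mwtab, validate_document)

text, _ = generate_mwtab_text(FixtureSpec(seed=3, n_samples=5, n_metabolites=6))
print("pristine findings:", validate_document(parse_mwtab(text)))

for cls in (CorruptionClass.MISSING_END, CorruptionClass.EMPTY_UNITS,
            CorruptionClass.DROP_REQUIRED_KEY):
    bad, expected = inject_corruption(text, cls, seed=0)
    found = validate_document(parse_mwtab(bad))
    print(f"{cls.value}: expected {sorted(expected)}")
    for issue in found:
        print("   ", issue)

# Each single fault maps to exactly its documented issue code — the basis
# for auditing a whole repository snapshot for format defects.
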