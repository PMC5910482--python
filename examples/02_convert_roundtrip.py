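"""Convert mwTab text to its JSON representation and back, losslessly."""

from mwtabkit import (FixtureSpec, generate_document, parse_json, parse_mwtab,
                      write_json, write_mwtab)

doc, _ = generate_document(FixtureSpec(seed=2, n_samples=3, n_metabolites=5))

as_json = write_json(doc)
back = parse_json(as_json)
print("JSON round trip exact:", back == doc)

as_text = write_mwtab(back)
print("mwTab round trip exact:", parse_mwtab(as_text) == doc)
print("JSON size / mwTab size:", len(as_json), "/", len(as_text))

# Both serializations carry the identical (section, key, value) triples and
# table cells; JSON is larger but readable from any language.
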