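import zipfile
from pathlib import Path

import pytest

from mwtabkit import FixtureSpec, generate_document, generate_mwtab_text, write_corpus


@pytest.fixture
def ms_spec():
    return FixtureSpec(seed=11, n_samples=6, n_metabolites=40, platform="MS",
                       n_factors=2)


@pytest.fixture
def ms_doc(ms_spec):
    doc, truth = generate_document(ms_spec)
    return doc, truth


@pytest.fixture
def ms_text(ms_spec):
    text, truth = generate_mwtab_text(ms_spec)
    return text, truth


@pytest.fixture
def corpus_dir(tmp_path):
    """Directory of 6 pristine fixture files (mixed MS/NMR)."""
    d = tmp_path / "corpus"
    write_corpus(d, count=6, seed=100)
    return d


def make_zip(src_dir: Path, out: Path) -> Path:
    with zipfile.ZipFile(out, "w") as zf:
        for p in sorted(src_dir.iterdir()):
            zf.write(p, p.name)
    return out
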