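import numpy as np
import pytest

from circtrans.simulate import simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """A 30-circle synthetic study with fixtures written to disk."""
    outdir = tmp_path_factory.mktemp("study")
    manifest = simulate_study(11, n_circles=30, outdir=outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def random_circle_corpus():
    """500 seeded random circles with lengths in [3, 600]."""
    corpus_rng = np.random.default_rng(42)
    seqs = []
    for _ in range(500):
        L = int(corpus_rng.integers(3, 601))
        seqs.append("".join(corpus_rng.choice(list("ACGT"), size=L)))
    return seqs
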