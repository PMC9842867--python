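import numpy as np
import pytest

from hicstruct import synthetic
from hicstruct.embedding import line_embed


@pytest.fixture(scope="session")
def helix30():
    """Planted helix with its noise-free map at gamma=1."""
    s = synthetic.make_structure(30, "helix", seed=0)
    m = synthetic.structure_to_map(s, gamma=1.0, noise_alpha=0.0)
    return s, m


@pytest.fixture(scope="session")
def helix30_embedding(helix30):
    _, m = helix30
    return line_embed(m, e_dim=16, epochs=4, seed=7, samples_per_epoch=20_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_positive(rng, n):
    a = rng.random((n, n)) + 0.1
    a = (a + a.T) / 2
    return a
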