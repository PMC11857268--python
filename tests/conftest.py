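import numpy as np
import pytest

from matlm import AbundanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20250927)


@pytest.fixture
def positive_matrix(rng):
    """A complete, strictly positive 6 x 10 abundance matrix."""
    V = rng.lognormal(mean=2.0, sigma=0.6, size=(6, 10))
    return AbundanceMatrix(
        V,
        [f"s{i}" for i in range(6)],
        [f"met{j}" for j in range(10)],
        np.zeros_like(V, dtype=bool),
    )
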