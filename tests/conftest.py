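import numpy as np
import pytest

from epilasso import SparseBinaryMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_binary_matrix(rng, n, p, density=0.2, real_values=False):
    dense = (rng.random((n, p)) < density).astype(float)
    if real_values:
        vals = rng.uniform(0.2, 2.5, size=(n, p)) * np.where(
            rng.random((n, p)) < 0.5, -1.0, 1.0
        )
        dense = dense * vals
    return SparseBinaryMatrix.from_dense(dense, real_values=real_values), dense


@pytest.fixture
def small_matrix(rng):
    return random_binary_matrix(rng, 50, 8)
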