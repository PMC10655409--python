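import numpy as np
import pytest

from nibclust import BinaryMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def all_ones():
    return BinaryMatrix(np.ones((6, 8), dtype=np.uint8))


@pytest.fixture
def identity4():
    return BinaryMatrix(np.eye(4, dtype=np.uint8))


@pytest.fixture
def block_diagonal():
    """Two disjoint all-ones blocks: rows 0-2 × cols 0-3 and rows 3-5 × cols 4-7."""
    vals = np.zeros((6, 8), dtype=np.uint8)
    vals[:3, :4] = 1
    vals[3:, 4:] = 1
    return BinaryMatrix(vals)


def random_binary(rng, n, m, density):
    return BinaryMatrix((rng.random((n, m)) < density).astype(np.uint8))
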