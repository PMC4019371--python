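import numpy as np
import pytest

from multitad import ContactMatrix, build_scoring_context


def random_symmetric_matrix(n, rng):
    """Uniform(0,1) entries, symmetrized, zero diagonal."""
    A = rng.uniform(0.0, 1.0, size=(n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return A


@pytest.fixture
def uniform_matrix():
    """Constant matrix: every quality is exactly zero."""
    A = np.ones((8, 8))
    return ContactMatrix("chr1", 40_000, A)


@pytest.fixture
def two_block_matrix():
    """Two dense 4-bin blocks with no cross-block contacts."""
    A = np.zeros((8, 8))
    A[:4, :4] = 1.0
    A[4:, 4:] = 1.0
    np.fill_diagonal(A, 0.0)
    return ContactMatrix("chr1", 40_000, A)


@pytest.fixture
def two_block_ctx(two_block_matrix):
    return build_scoring_context(two_block_matrix, min_mean_samples=1)
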