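import numpy as np
import pytest

from barseg.io import MutationMatrix, SiteCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_counts(rng, n_max=30, n_sites_max=10, span=60):
    """A random small SiteCounts instance for oracle cross-checks."""
    N = int(rng.integers(1, n_sites_max + 1))
    n = int(rng.integers(2, n_max + 1))
    pos = np.sort(rng.choice(np.arange(1, span), size=N, replace=False)).astype(float)
    x = rng.integers(0, n + 1, size=N).astype(float)
    return SiteCounts(positions=pos, x=x, n=n)


@pytest.fixture
def small_matrix():
    calls = np.array(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1], [1, 0, 0, 0]],
        dtype=np.uint8,
    )
    return MutationMatrix(
        strand="top",
        positions=np.array([3, 7, 12, 20]),
        calls=calls,
        seq_ids=[f"s{i}" for i in range(5)],
    )
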