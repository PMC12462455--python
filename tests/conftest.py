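import numpy as np
import pytest

from paleoibd.segments import IBDMatrix


def random_symmetric_matrix(rng: np.random.Generator, n: int) -> IBDMatrix:
    """Random non-negative symmetric matrix with zero diagonal."""
    raw = rng.uniform(0, 30, size=(n, n))
    raw = np.triu(raw, k=1)
    values = raw + raw.T
    ids = [f"I{k:02d}" for k in range(n)]
    return IBDMatrix(ids=ids, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    # 6 individuals, hand-checkable values
    values = np.zeros((6, 6))
    entries = {
        (0, 1): 20.0, (0, 2): 14.0, (1, 2): 5.0,
        (3, 4): 30.0, (3, 5): 18.0, (4, 5): 12.0,
        (0, 3): 2.0, (1, 4): 4.0,
    }
    for (i, j), v in entries.items():
        values[i, j] = values[j, i] = v
    return IBDMatrix(ids=list("ABCDEF"), values=values)
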