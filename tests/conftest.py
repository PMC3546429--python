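import numpy as np
import pytest

from curlev import DataMatrix


@pytest.fixture
def diag321() -> DataMatrix:
    return DataMatrix(np.diag([3.0, 2.0, 1.0]))


def random_matrix(seed: int, m: int, n: int) -> DataMatrix:
    rng = np.random.default_rng(seed)
    return DataMatrix(rng.normal(size=(m, n)))


def exact_rank_matrix(seed: int, m: int, n: int, rank: int) -> DataMatrix:
    """Exact-rank-`rank` matrix from a seeded Gaussian factor product."""
    rng = np.random.default_rng(seed)
    return DataMatrix(rng.normal(size=(m, rank)) @ rng.normal(size=(rank, n)))
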