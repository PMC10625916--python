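import numpy as np
import pytest

from atvnetnmf.containers import OmicsMatrix
from atvnetnmf.synthetic import random_network_triple


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_omics(rng):
    """10 features x 8 samples, strictly positive, no zero-variance rows."""
    values = rng.uniform(0.1, 2.0, size=(10, 8))
    return OmicsMatrix(
        values=values,
        feature_ids=[f"g{i}" for i in range(10)],
        sample_ids=[f"s{j}" for j in range(8)],
        layer_name="toy",
    )


@pytest.fixture
def small_nets():
    """Unstructured 20 x 25 correlation-network triple."""
    return random_network_triple(20, 25, n_samples=15, seed=3)


def pearson_loop(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Brute-force pairwise Pearson correlation between rows of A and rows of B."""
    from scipy.stats import pearsonr

    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            out[i, j] = pearsonr(A[i], B[j]).statistic
    return out
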