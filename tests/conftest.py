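import numpy as np
import pytest

from denoiseq import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """6 genes x 3 samples with hand-checkable values."""
    counts = np.array(
        [
            [100.0, 90.0, 110.0],
            [80.0, 85.0, 75.0],
            [40.0, 42.0, 38.0],
            [10.0, 12.0, 9.0],
            [5.0, 4.0, 6.0],
            [1.0, 2.0, 0.0],
        ]
    )
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=["s1", "s2", "s3"],
        counts=counts,
    )


def random_count_matrix(rng, n_genes, n_samples):
    counts = rng.integers(0, 1000, size=(n_genes, n_samples)).astype(float)
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        counts=counts,
    )
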