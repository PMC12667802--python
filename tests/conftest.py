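import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from genespec import Partition


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_block_partition():
    return Partition("p", ("A", "B"), np.array([0, 0, 1, 1]))


def random_sparse_gene(rng, n_cells, density=0.4, max_val=20):
    """Random nonnegative integer gene vector with >= 2 expressing cells."""
    while True:
        x = rng.integers(0, max_val, n_cells) * (rng.random(n_cells) < density)
        if (x > 0).sum() >= 2:
            return x.astype(float)


def random_partition(rng, n_cells, r):
    """Random partition of n_cells into exactly r nonempty blocks."""
    while True:
        codes = rng.integers(0, r, n_cells)
        if len(np.unique(codes)) == r:
            return Partition("rand", tuple(f"b{i}" for i in range(r)), codes)


@pytest.fixture
def tiny_adata():
    """6 cells x 3 genes with sex/tissue/sample metadata."""
    X = sparse.csc_matrix(
        np.array(
            [
                [5.0, 1.0, 0.0],
                [4.0, 1.0, 0.0],
                [0.0, 1.0, 2.0],
                [1.0, 1.0, 3.0],
                [0.0, 1.0, 2.0],
                [0.0, 1.0, 1.0],
            ]
        )
    )
    obs = pd.DataFrame(
        {
            "sex": ["F", "F", "F", "M", "M", "M"],
            "tissue": ["K", "K", "L", "K", "L", "L"],
            "sample_id": ["s1", "s1", "s2", "s3", "s4", "s4"],
        },
        index=[f"c{i}" for i in range(6)],
    )
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=["g0", "g1", "g2"]))
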