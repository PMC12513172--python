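import numpy as np
import pytest
import scipy.sparse as sp

from csgae import (
    CommunityPartition,
    SpatialDataset,
    SpotGraph,
    TissueSimSpec,
    preprocess,
    simulate_tissue,
)


@pytest.fixture(scope="session")
def bands_small():
    """10x10 lattice, 2 bands, strong markers — raw counts with labels."""
    spec = TissueSimSpec(
        grid_shape=(10, 10), n_domains=2, n_genes=50, markers_per_domain=5,
        marker_fold_change=8.0, dropout_rate=0.1, seed=11,
    )
    return simulate_tissue(spec)


@pytest.fixture(scope="session")
def bands_small_pp(bands_small):
    return preprocess(bands_small, target_sum=1e4, n_hvg=3000)


@pytest.fixture(scope="session")
def two_triangles():
    """Two triangles {0,1,2}, {3,4,5} joined by the bridge edge (2,3)."""
    edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    A = np.zeros((6, 6))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    graph = SpotGraph(6, sp.csr_matrix(A), "spatial")
    part = CommunityPartition(np.array([0, 0, 0, 1, 1, 1]))
    return graph, part


def toy_dataset(n=6, p=5, seed=0):
    rng = np.random.default_rng(seed)
    return SpatialDataset(
        expression=rng.poisson(3.0, (n, p)).astype(float) + 1.0,
        coords=np.column_stack([np.arange(n, dtype=float), np.zeros(n)]),
        gene_names=[f"g{j}" for j in range(p)],
        spot_ids=[f"s{i}" for i in range(n)],
    )
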