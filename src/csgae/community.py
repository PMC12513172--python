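"""Community detection, community strength, and community-aware augmentation.

The community strength of a community ``c`` in a binary graph is its summand
of Newman–Girvan modularity,

    S_c = |eps_c| / |eps|  -  [ sum_{v in c} d(v) ]^2 / (4 |eps|^2),

with ``|eps|`` the total undirected edge count, ``|eps_c|`` the edges with
both endpoints in ``c`` and ``d(v)`` the node degree; summing S_c over
communities recovers the modularity Q of the partition.

Two corruption operators use these strengths to build augmented graph views:

* communal attribute voting (CAV): every spot votes for each gene with
  weight equal to its community's strength; genes with a high vote total are
  important and receive a low masking probability, and masking zeroes the
  whole gene column (one Bernoulli draw per gene).
* community edge dropping (CED): edges inside strong communities are
  preferentially retained; inter-community edges get a strictly negative
  penalty, so after clipping their keep-probability is 1 and they are never
  dropped preferentially.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .dataset import SpatialDataset
from .graphs import SpotGraph

__all__ = [
    "CommunityPartition",
    "AugmentedView",
    "detect_communities",
    "community_strength",
    "attribute_penalty",
    "corrupt_features",
    "edge_penalty",
    "corrupt_edges",
    "generate_views",
]


@dataclass
class CommunityPartition:
    """Node-to-community assignment with optional per-community strengths."""

    assignment: np.ndarray
    strength: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be a 1-D integer vector")
        ids = np.unique(self.assignment)
        if len(ids) and (ids[0] != 0 or ids[-1] != len(ids) - 1):
            # relabel to contiguous ids from 0, preserving order of first use
            _, self.assignment = np.unique(self.assignment, return_inverse=True)
        if self.strength is not None:
            self.strength = np.asarray(self.strength, dtype=float)
            if self.strength.shape != (self.n_communities,):
                raise ValueError("strength length must equal n_communities")

    @property
    def n_nodes(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0

    @property
    def indicator(self) -> np.ndarray:
        """Binary membership matrix, one row per node, one column per community."""
        I = np.zeros((self.n_nodes, self.n_communities))
        I[np.arange(self.n_nodes), self.assignment] = 1.0
        return I

    def node_strength(self) -> np.ndarray:
        """Per-node strength of the node's own community (the vector I @ S)."""
        if self.strength is None:
            raise ValueError("strengths not computed; call community_strength first")
        return self.strength[self.assignment]

    def with_strength(self, strength: np.ndarray) -> "CommunityPartition":
        return CommunityPartition(self.assignment.copy(), np.asarray(strength, float))


@dataclass
class AugmentedView:
    """One corrupted (features, adjacency) pair."""

    features: np.ndarray
    adjacency: sp.csr_matrix
    gene_mask: np.ndarray  # 1 = kept, 0 = masked column
    view_index: int
    seed_used: int


def detect_communities(
    ds: SpatialDataset,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 50,
    n_neighbors: int = 15,
) -> CommunityPartition:
    """Leiden partition of a KNN similarity graph built from expression.

    The preprocessed (normalized, log-transformed) profile is reduced to
    ``n_pcs`` principal components, a ``n_neighbors``-NN graph is built on
    the components, and the Leiden algorithm is run at the given resolution.
    Deterministic under ``seed``; community ids are contiguous from 0.
    """
    import igraph as ig
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    if resolution <= 0:
        raise ValueError("resolution must be positive")
    X = ds.dense_expression()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to detect communities")
    comps = min(n_pcs, min(X.shape) - 1)
    if comps >= 1:
        X = PCA(n_components=comps, svd_solver="full").fit_transform(X)
    k = min(n_neighbors, n - 1)
    knn = kneighbors_graph(X, n_neighbors=k, mode="connectivity")
    knn = knn.maximum(knn.T).tocoo()
    mask = knn.row < knn.col
    g = ig.Graph(
        n=n, edges=list(zip(knn.row[mask].tolist(), knn.col[mask].tolist()))
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return CommunityPartition(np.asarray(part.membership, dtype=int))


def community_strength(graph: SpotGraph, part: CommunityPartition) -> np.ndarray:
    """Per-community modularity summand S_c on a binary graph.

    Raises on an edgeless graph (the formula divides by the edge count).
    """
    m = graph.n_edges
    if m == 0:
        raise ValueError("community strength undefined on an edgeless graph")
    deg = graph.degrees().astype(float)
    edges = graph.edge_list()
    assign = part.assignment
    if assign.shape[0] != graph.n_nodes:
        raise ValueError("partition size does not match graph")
    nC = part.n_communities
    intra = assign[edges[:, 0]] == assign[edges[:, 1]]
    eps_c = np.bincount(assign[edges[intra, 0]], minlength=nC).astype(float)
    deg_sum = np.bincount(assign, weights=deg, minlength=nC)
    return eps_c / m - deg_sum**2 / (4.0 * m**2)


def _max_mean_normalize(x: np.ndarray) -> np.ndarray:
    """(x_max - x) / (x_max - x_mean): the largest value maps to 0.

    Values below the mean map above 1 (clipped later, at mask time). A
    constant vector maps to all zeros.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    xmax, xmean = x.max(), x.mean()
    if np.isclose(xmax, xmean):
        return np.zeros_like(x)
    return (xmax - x) / (xmax - xmean)


def attribute_penalty(ds: SpatialDataset, part: CommunityPartition) -> np.ndarray:
    """Per-gene masking penalty from community-strength-weighted voting.

    Each spot votes for each gene with weight equal to its community's
    strength: votes_g = sum_i |X_ig| * s_i. Negative vote totals (communities
    weaker than random) are floored at zero, the totals are log-compressed
    with a +1 offset, and max/mean-normalized so the highest-scoring gene
    gets penalty 0 (kept preferentially).
    """
    s = part.node_strength()
    X = ds.dense_expression()
    votes = np.abs(X).T @ s
    raw = np.log1p(np.maximum(votes, 0.0))
    return _max_mean_normalize(raw)


def corrupt_features(
    X: np.ndarray,
    p_a: np.ndarray,
    lambda_a: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Bernoulli gene masking: keep gene g with prob clip(1 - p_a[g]*lambda_a).

    Returns ``(mask, X_tilde)`` where ``mask`` is the per-gene keep indicator
    and ``X_tilde`` is X with masked columns zeroed (Hadamard structure).
    """
    if not 0 <= lambda_a <= 1:
        raise ValueError("lambda_a must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    p_a = np.asarray(p_a, dtype=float)
    if not np.all(np.isfinite(p_a)):
        raise ValueError("attribute penalties must be finite")
    q = np.clip(1.0 - p_a * lambda_a, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    mask = (rng.random(p_a.shape[0]) < q).astype(float)
    return mask, X * mask[None, :]


def edge_penalty(graph: SpotGraph, part: CommunityPartition) -> np.ndarray:
    """Per-edge dropping penalty, aligned to ``graph.edge_list()`` order.

    Intra-community edges carry their community's strength, max/mean
    normalized among intra-community edges (strong community -> penalty near
    0 -> retained). Inter-community edges score the sum of the two endpoint
    strengths, normalized among themselves, negated and offset by -1 so the
    penalty is strictly negative — after clipping, their keep-probability is
    always 1.
    """
    s = part.node_strength()
    edges = graph.edge_list()
    m = edges.shape[0]
    p = np.zeros(m)
    if m == 0:
        return p
    assign = part.assignment
    intra = assign[edges[:, 0]] == assign[edges[:, 1]]
    if intra.any():
        p[intra] = _max_mean_normalize(s[edges[intra, 0]])
    if (~intra).any():
        pair_sum = s[edges[~intra, 0]] + s[edges[~intra, 1]]
        p[~intra] = -(1.0 + _max_mean_normalize(pair_sum))
    return p


def corrupt_edges(
    graph: SpotGraph,
    p_e: np.ndarray,
    lambda_e: float,
    seed: int,
) -> sp.csr_matrix:
    """Bernoulli edge dropping: keep edge e with prob clip(1 - p_e[e]*lambda_e).

    One draw per undirected edge, applied symmetrically; the result is a
    subset of the input adjacency.
    """
    if not 0 <= lambda_e <= 1:
        raise ValueError("lambda_e must lie in [0, 1]")
    edges = graph.edge_list()
    p_e = np.asarray(p_e, dtype=float)
    if p_e.shape[0] != edges.shape[0]:
        raise ValueError("penalty vector does not align with the edge list")
    q = np.clip(1.0 - p_e * lambda_e, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    keep = rng.random(edges.shape[0]) < q
    kept = edges[keep]
    n = graph.n_nodes
    if kept.size == 0:
        return sp.csr_matrix((n, n))
    rows = np.concatenate([kept[:, 0], kept[:, 1]])
    cols = np.concatenate([kept[:, 1], kept[:, 0]])
    return sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()


def generate_views(
    graph: SpotGraph,
    X: np.ndarray,
    part: CommunityPartition,
    lambdas: dict | None = None,
    seed: int = 0,
) -> tuple[AugmentedView, AugmentedView]:
    """Produce the two corrupted views (CAV + CED) of one graph.

    ``lambdas`` maps ``{"lambda_a1", "lambda_a2", "lambda_e1", "lambda_e2"}``
    to corruption levels in [0, 1]; the two views use independent draws from
    sub-seeds spawned deterministically from ``seed``.
    """
    lam = {
        "lambda_a1": 0.1,
        "lambda_a2": 0.2,
        "lambda_e1": 0.2,
        "lambda_e2": 0.3,
    }
    if lambdas:
        unknown = set(lambdas) - set(lam)
        if unknown:
            raise ValueError(f"unknown corruption parameters: {sorted(unknown)}")
        lam.update(lambdas)
    X = np.asarray(X, dtype=float)
    ds_view = SpatialDataset(
        expression=X,
        coords=np.zeros((X.shape[0], 2)),
        gene_names=[f"g{j}" for j in range(X.shape[1])],
        spot_ids=[f"s{i}" for i in range(X.shape[0])],
    )
    p_a = attribute_penalty(ds_view, part)
    p_e = edge_penalty(graph, part)
    ss = np.random.SeedSequence(seed)
    subseeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    views = []
    for v in (1, 2):
        sa, se = subseeds[2 * (v - 1)], subseeds[2 * (v - 1) + 1]
        mask, Xt = corrupt_features(X, p_a, lam[f"lambda_a{v}"], sa)
        At = corrupt_edges(graph, p_e, lam[f"lambda_e{v}"], se)
        views.append(
            AugmentedView(
                features=Xt, adjacency=At, gene_mask=mask, view_index=v, seed_used=sa
            )
        )
    return views[0], views[1]
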