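"""Spot graphs: alpha-complex spatial adjacency, histology KNN, weighted fusion.

The spatial graph keeps a Delaunay edge (equivalently: the two Voronoi cells
share a boundary) iff its endpoints lie within 2*sigma of each other — the
alpha-complex edge criterion with alpha = sigma. The radius sigma is
estimated as the average k-nearest-neighbor distance over all spots. The
histology graph is a union-symmetrized Euclidean KNN graph on per-spot image
feature vectors. The fused graph is G_w = w_s*A_s + w_h*A_h + I.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SpotGraph",
    "estimate_radius",
    "build_spatial_graph",
    "build_histology_graph",
    "fuse_graphs",
]

GraphKind = Literal["spatial", "histology", "fused"]


@dataclass
class SpotGraph:
    """Symmetric adjacency over spots (binary for spatial/histology, weighted for fused)."""

    n_nodes: int
    adjacency: sp.csr_matrix
    kind: GraphKind

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency)
        if A.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape does not match n_nodes")
        if A.nnz and abs(A - A.T).max() > 1e-12:
            raise ValueError("adjacency must be symmetric")
        self.adjacency = A

    @property
    def n_edges(self) -> int:
        """Undirected edge count, self-loops excluded."""
        A = self.adjacency
        off = A - sp.diags(A.diagonal())
        return int(off.nnz // 2)

    def edge_list(self) -> np.ndarray:
        """Undirected edges (i < j) in lexicographic order, shape (m, 2)."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order], coo.col[order]])

    def degrees(self) -> np.ndarray:
        A = self.adjacency
        off = A - sp.diags(A.diagonal())
        return np.asarray((off != 0).sum(axis=1)).ravel()

    def save(self, path: "str | Path") -> None:
        """Edge-list TSV (i, j, weight) with a JSON sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        coo = sp.triu(self.adjacency, k=0).tocoo()
        with open(path, "w") as fh:
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i}\t{j}\t{w:.10g}\n")
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump({"n_nodes": self.n_nodes, "kind": self.kind}, fh)

    @classmethod
    def load(cls, path: "str | Path") -> "SpotGraph":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            meta = json.load(fh)
        rows, cols, vals = [], [], []
        with open(path) as fh:
            for line in fh:
                i, j, w = line.split("\t")
                rows.append(int(i))
                cols.append(int(j))
                vals.append(float(w))
        n = meta["n_nodes"]
        A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
        diag = sp.diags(A.diagonal())
        A = A + A.T - diag
        return cls(n_nodes=n, adjacency=A.tocsr(), kind=meta["kind"])


def estimate_radius(coords: np.ndarray, k: int = 6) -> float:
    """Mean over spots of the mean Euclidean distance to the k nearest neighbors."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be positive")
    if n <= k:
        raise ValueError(f"need more than k={k} spots, got {n}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain NaN or Inf")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    return float(dist[:, 1:].mean())


def _distance_threshold_edges(coords: np.ndarray, cutoff: float) -> set[tuple[int, int]]:
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    ii, jj = np.where(np.triu(d <= cutoff, k=1))
    return set(zip(ii.tolist(), jj.tolist()))


def build_spatial_graph(
    coords: np.ndarray, sigma: float, jitter_seed: int = 0
) -> SpotGraph:
    """Alpha-complex spatial graph: Delaunay edges no longer than 2*sigma.

    Duplicate coordinates are collapsed to a single Voronoi site; the
    duplicates are connected to each other and inherit the site's edges.
    Degenerate (co-circular) configurations are broken by a deterministic
    jitter of 1e-9 times the bounding-box diagonal before triangulation.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if uniq.shape[0] == 1:
        raise ValueError("all coordinates identical: geometry is degenerate")

    cutoff = 2.0 * sigma
    edges: set[tuple[int, int]] = set()
    if uniq.shape[0] < 3:
        site_edges = _distance_threshold_edges(uniq, cutoff)
    else:
        span = np.sqrt(((uniq.max(axis=0) - uniq.min(axis=0)) ** 2).sum())
        rng = np.random.default_rng(jitter_seed)
        jittered = uniq + rng.normal(0.0, 1e-9 * max(span, 1.0), uniq.shape)
        tri = Delaunay(jittered)
        site_edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    u, v = sorted((int(simplex[a]), int(simplex[b])))
                    if np.linalg.norm(uniq[u] - uniq[v]) <= cutoff:
                        site_edges.add((u, v))

    members: dict[int, list[int]] = {}
    for node, site in enumerate(inverse.ravel()):
        members.setdefault(int(site), []).append(node)
    for u, v in site_edges:
        for a in members[u]:
            for b in members[v]:
                edges.add((min(a, b), max(a, b)))
    for site_members in members.values():
        for ai in range(len(site_members)):
            for bi in range(ai + 1, len(site_members)):
                edges.add((site_members[ai], site_members[bi]))

    return _graph_from_edges(n, edges, "spatial")


def _graph_from_edges(n: int, edges: set[tuple[int, int]], kind: GraphKind) -> SpotGraph:
    if edges:
        arr = np.array(sorted(edges))
        rows = np.concatenate([arr[:, 0], arr[:, 1]])
        cols = np.concatenate([arr[:, 1], arr[:, 0]])
        A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    else:
        A = sp.csr_matrix((n, n))
    return SpotGraph(n_nodes=n, adjacency=A, kind=kind)


def build_histology_graph(image_features: np.ndarray, k: int = 6) -> SpotGraph:
    """Union-symmetrized Euclidean KNN graph on per-spot image feature vectors."""
    F = np.asarray(image_features, dtype=float)
    if F.ndim != 2 or F.shape[1] < 1:
        raise ValueError("image_features must be a 2-D matrix with >= 1 column")
    if not np.all(np.isfinite(F)):
        raise ValueError("image_features contain NaN or Inf")
    n = F.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} spots, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(F)
    _, idx = nn.kneighbors(F)
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        for j in idx[i, 1:]:
            if int(j) != i:
                edges.add((min(i, int(j)), max(i, int(j))))
    return _graph_from_edges(n, edges, "histology")


def fuse_graphs(
    gs: SpotGraph,
    gh: Optional[SpotGraph] = None,
    ws: float = 0.5,
    wh: float = 0.5,
) -> SpotGraph:
    """Weighted fusion G_w = w_s*A_s + w_h*A_h + I; without histology, A_s + I."""
    n = gs.n_nodes
    if gh is None:
        A = gs.adjacency + sp.identity(n, format="csr")
        return SpotGraph(n_nodes=n, adjacency=A.tocsr(), kind="fused")
    if gh.n_nodes != n:
        raise ValueError(
            f"node-count mismatch: spatial {n} vs histology {gh.n_nodes}"
        )
    if ws < 0 or wh < 0 or ws + wh <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    A = ws * gs.adjacency + wh * gh.adjacency + sp.identity(n, format="csr")
    return SpotGraph(n_nodes=n, adjacency=A.tocsr(), kind="fused")
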