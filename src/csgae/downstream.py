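"""Domain calling on the latent embedding and evaluation against annotations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import SpatialDataset
from .model import TrainedModel

__all__ = ["DomainResult", "cluster_embedding", "evaluate_domains", "export_denoised"]


@dataclass
class DomainResult:
    """Predicted spatial domains with optional agreement scores."""

    labels: np.ndarray
    method: str
    parameters: dict
    ari: Optional[float] = None
    nmi: Optional[float] = None

    def __post_init__(self) -> None:
        self.labels = _contiguous(np.asarray(self.labels, dtype=int))


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous ids from 0 in order of first appearance."""
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)


def cluster_embedding(
    Z: np.ndarray,
    method: str = "gmm",
    param: "float | int" = 4,
    seed: int = 0,
    n_neighbors: int = 15,
) -> DomainResult:
    """Cluster the latent embedding into spatial domains.

    ``gmm`` fits a Gaussian mixture with full covariances and k-means
    initialization (``param`` = number of components, standing in for
    model-based clustering); ``louvain``/``leiden`` run on a
    ``n_neighbors``-NN graph of Z with ``param`` as resolution.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("embedding contains NaN or Inf")
    n = Z.shape[0]
    if method == "gmm":
        from sklearn.mixture import GaussianMixture

        k = int(param)
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters must lie in [1, {n}], got {k}")
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            init_params="kmeans",
            random_state=seed,
            n_init=1,
            reg_covar=1e-5,
        ).fit(Z)
        labels = gm.predict(Z)
        return DomainResult(labels, "gmm", {"n_clusters": k})
    if method in ("louvain", "leiden"):
        import igraph as ig
        from sklearn.neighbors import kneighbors_graph

        resolution = float(param)
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        k = min(n_neighbors, n - 1)
        knn = kneighbors_graph(Z, n_neighbors=k, mode="connectivity")
        knn = knn.maximum(knn.T).tocoo()
        m = knn.row < knn.col
        g = ig.Graph(n=n, edges=list(zip(knn.row[m].tolist(), knn.col[m].tolist())))
        if method == "leiden":
            import leidenalg

            part = leidenalg.find_partition(
                g,
                leidenalg.RBConfigurationVertexPartition,
                resolution_parameter=resolution,
                seed=int(seed),
                n_iterations=2,
            )
            labels = np.asarray(part.membership)
        else:
            import random as _random  # igraph's default RNG is python's

            state = _random.getstate()
            _random.seed(int(seed))
            try:
                part = g.community_multilevel(resolution=resolution)
            finally:
                _random.setstate(state)
            labels = np.asarray(part.membership)
        return DomainResult(labels, method, {"resolution": resolution})
    raise ValueError(f"unknown clustering method: {method!r}")


def evaluate_domains(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Adjusted Rand index and NMI (arithmetic normalization) of a labeling."""
    from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    ari = float(adjusted_rand_score(truth, pred))
    nmi = float(normalized_mutual_info_score(truth, pred, average_method="arithmetic"))
    return ari, nmi


def export_denoised(
    model: TrainedModel, ds: SpatialDataset, genes: list[str]
) -> pd.DataFrame:
    """Tidy per-spot table (spot_id, x, y, gene, raw, denoised) for chosen genes."""
    missing = [g for g in genes if g not in ds.gene_names]
    if missing:
        raise KeyError(f"genes not in dataset: {missing}")
    idx = {g: ds.gene_names.index(g) for g in genes}
    X = ds.dense_expression()
    frames = []
    for g in genes:
        j = idx[g]
        frames.append(
            pd.DataFrame(
                {
                    "spot_id": ds.spot_ids,
                    "x": ds.coords[:, 0],
                    "y": ds.coords[:, 1],
                    "gene": g,
                    "raw": X[:, j],
                    "denoised": model.denoised[:, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
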