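"""Synthetic layered-tissue generator.

Emulates a barcoded spatial section: spots on a 2-D integer lattice
partitioned into contiguous domains (horizontal bands mimicking cortical
layers, or irregular Voronoi patches mimicking tumor regions), each domain
carrying a private marker-gene program. Counts are negative-binomial with a
mean/dispersion parameterization (variance = mu + dispersion * mu^2) and
independent dropout; pseudo-histology features are a noisy embedding of the
domain identity, standing in for per-spot image feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .dataset import SpatialDataset

__all__ = ["TissueSimSpec", "simulate_tissue", "simulate_edge_case"]

Geometry = Literal["horizontal-bands", "voronoi-patches"]


@dataclass
class TissueSimSpec:
    """Parameters of one simulated tissue section."""

    grid_shape: tuple[int, int] = (30, 30)
    n_domains: int = 4
    domain_geometry: Geometry = "horizontal-bands"
    n_genes: int = 200
    markers_per_domain: int = 10
    marker_fold_change: float = 5.0
    base_mean: float = 1.0
    dispersion: float = 0.3
    dropout_rate: float = 0.3
    img_dim: int = 0
    img_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape entries must be positive")
        if self.n_domains < 2:
            raise ValueError("n_domains must be at least 2")
        if rows * cols < self.n_domains:
            raise ValueError("grid too small for the requested domain count")
        if self.markers_per_domain * self.n_domains > self.n_genes:
            raise ValueError(
                "markers_per_domain * n_domains exceeds n_genes "
                f"({self.markers_per_domain} * {self.n_domains} > {self.n_genes})"
            )
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must exceed 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.base_mean <= 0 or self.dispersion < 0:
            raise ValueError("base_mean must be positive, dispersion nonnegative")
        if self.img_dim < 0 or self.img_noise_sd <= 0:
            raise ValueError("img_dim must be >= 0 and img_noise_sd > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


def _domain_labels(spec: TissueSimSpec, coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.grid_shape
    if spec.domain_geometry == "horizontal-bands":
        # contiguous, near-equal bands of lattice rows
        band_of_row = np.concatenate(
            [np.full(len(chunk), d) for d, chunk in
             enumerate(np.array_split(np.arange(rows), spec.n_domains))]
        )
        return band_of_row[coords[:, 1].astype(int)]
    if spec.domain_geometry == "voronoi-patches":
        centers = np.column_stack(
            [rng.uniform(0, cols - 1, spec.n_domains), rng.uniform(0, rows - 1, spec.n_domains)]
        )
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)
    raise ValueError(f"unknown domain geometry: {spec.domain_geometry!r}")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion  # gamma shape; variance = mu + dispersion * mu^2
    return rng.poisson(rng.gamma(shape=size, scale=mean / size))


def simulate_tissue(spec: TissueSimSpec) -> SpatialDataset:
    """Draw one section according to ``spec``; bitwise-reproducible from its seed."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    n = rows * cols

    labels = _domain_labels(spec, coords, rng)

    mean = np.full((n, spec.n_genes), spec.base_mean)
    marker_genes: dict[int, np.ndarray] = {}
    for d in range(spec.n_domains):
        genes = np.arange(d * spec.markers_per_domain, (d + 1) * spec.markers_per_domain)
        marker_genes[d] = genes
        mean[np.ix_(labels == d, genes)] = spec.base_mean * spec.marker_fold_change

    counts = _nb_sample(rng, mean, spec.dispersion).astype(float)
    if spec.dropout_rate > 0:
        counts[rng.random(counts.shape) < spec.dropout_rate] = 0.0

    img = None
    if spec.img_dim > 0:
        onehot = np.eye(spec.n_domains)[labels]
        if spec.img_dim >= spec.n_domains:
            embed = np.zeros((spec.n_domains, spec.img_dim))
            embed[:, : spec.n_domains] = np.eye(spec.n_domains)
        else:
            embed = rng.normal(size=(spec.n_domains, spec.img_dim))
            embed /= np.linalg.norm(embed, axis=1, keepdims=True)
        img = onehot @ embed + rng.normal(0.0, spec.img_noise_sd, (n, spec.img_dim))

    width = max(4, len(str(max(n, spec.n_genes))))
    return SpatialDataset(
        expression=counts,
        coords=coords,
        gene_names=[f"gene{j:0{width}d}" for j in range(spec.n_genes)],
        spot_ids=[f"spot{i:0{width}d}" for i in range(n)],
        image_features=img,
        labels=labels,
    )


def simulate_edge_case(name: str) -> SpatialDataset:
    """Small pathological fixtures for error-path testing."""
    rng = np.random.default_rng(7)
    if name == "single-spot":
        return SpatialDataset(
            expression=rng.poisson(2.0, (1, 5)).astype(float) + 1,
            coords=np.array([[0.0, 0.0]]),
            gene_names=[f"g{j}" for j in range(5)],
            spot_ids=["s0"],
        )
    if name == "one-gene":
        return SpatialDataset(
            expression=rng.poisson(2.0, (6, 1)).astype(float) + 1,
            coords=np.column_stack([np.arange(6.0), np.zeros(6)]),
            gene_names=["g0"],
            spot_ids=[f"s{i}" for i in range(6)],
        )
    if name == "all-zero-gene":
        X = rng.poisson(2.0, (6, 4)).astype(float) + 1
        X[:, 2] = 0.0
        return SpatialDataset(
            expression=X,
            coords=np.column_stack([np.arange(6.0), np.zeros(6)]),
            gene_names=[f"g{j}" for j in range(4)],
            spot_ids=[f"s{i}" for i in range(6)],
        )
    if name == "duplicate-coords":
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        return SpatialDataset(
            expression=rng.poisson(2.0, (4, 5)).astype(float) + 1,
            coords=coords,
            gene_names=[f"g{j}" for j in range(5)],
            spot_ids=[f"s{i}" for i in range(4)],
        )
    raise ValueError(f"unknown edge case: {name!r}")
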