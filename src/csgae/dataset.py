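"""Spot-level expression containers, loaders and the preprocessing recipe.

The on-disk formats are the plain-text conventions of the droplet/spatial
ecosystem: a Matrix Market triplet with ``genes.tsv``/``barcodes.tsv``
sidecars plus a ``coords.csv`` table, a set of delimited tables, or an HDF5
single-cell container (``.h5ad``) with the coordinates in ``obsm['spatial']``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

Format = Literal["mtx-dir", "delimited", "h5-container"]

__all__ = ["SpatialDataset", "load_dataset", "save_dataset", "preprocess"]


def _as_2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {a.shape}")
    return a


@dataclass
class SpatialDataset:
    """Spots-by-genes expression with 2-D coordinates.

    ``expression`` may be a dense ndarray or any scipy sparse matrix with
    shape ``(n_spots, n_genes)``; sparsity of the source is preserved by the
    loaders. ``image_features`` holds precomputed per-spot histology feature
    vectors (the pipeline never touches raw images), ``labels`` optional
    integer ground-truth domains for evaluation.
    """

    expression: "np.ndarray | sp.spmatrix"
    coords: np.ndarray
    gene_names: list[str]
    spot_ids: list[str]
    image_features: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not sp.issparse(self.expression):
            self.expression = np.asarray(self.expression, dtype=float)
        self.coords = _as_2d(self.coords)
        self.gene_names = [str(g) for g in self.gene_names]
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
        if self.image_features is not None:
            self.image_features = _as_2d(self.image_features)
        self._validate()

    def _validate(self) -> None:
        n, p = self.expression.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{n} spots x 2 dimensions"
            )
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot ids for {n} spots")
        if len(self.gene_names) != p:
            raise ValueError(f"{len(self.gene_names)} gene names for {p} genes")
        if len(set(self.gene_names)) != p:
            raise ValueError("gene names are not unique")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot ids are not unique")
        if self.labels is not None and self.labels.shape != (n,):
            raise ValueError("labels length does not match spot count")
        if self.image_features is not None and self.image_features.shape[0] != n:
            raise ValueError("image_features row count does not match spot count")
        for name, arr in (
            ("expression", self.expression),
            ("coords", self.coords),
            ("image_features", self.image_features),
        ):
            if arr is None:
                continue
            data = arr.data if sp.issparse(arr) else arr
            if not np.all(np.isfinite(data)):
                raise ValueError(f"{name} contains NaN or Inf")

    # -- convenience -------------------------------------------------------

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def dense_expression(self) -> np.ndarray:
        X = self.expression
        return np.asarray(X.todense()) if sp.issparse(X) else X

    def copy(self) -> "SpatialDataset":
        X = self.expression
        return SpatialDataset(
            expression=X.copy(),
            coords=self.coords.copy(),
            gene_names=list(self.gene_names),
            spot_ids=list(self.spot_ids),
            image_features=None
            if self.image_features is None
            else self.image_features.copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.expression if sp.issparse(self.expression) else self.expression.copy(),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        adata.obsm["spatial"] = self.coords.copy()
        if self.image_features is not None:
            adata.obsm["image_features"] = self.image_features.copy()
        if self.labels is not None:
            adata.obs["label"] = self.labels
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "SpatialDataset":
        if "spatial" not in adata.obsm:
            raise ValueError("container is missing obsm['spatial'] coordinates")
        labels = None
        if "label" in adata.obs:
            labels = np.asarray(adata.obs["label"], dtype=int)
        X = adata.X
        if sp.issparse(X):
            X = X.tocsr().astype(float)
        else:
            X = np.asarray(X, dtype=float)
        return cls(
            expression=X,
            coords=np.asarray(adata.obsm["spatial"], dtype=float),
            gene_names=list(map(str, adata.var_names)),
            spot_ids=list(map(str, adata.obs_names)),
            image_features=np.asarray(adata.obsm["image_features"], dtype=float)
            if "image_features" in adata.obsm
            else None,
            labels=labels,
        )


# -- loaders ---------------------------------------------------------------

_MTX_FILES = ("matrix.mtx", "genes.tsv", "barcodes.tsv", "coords.csv")


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required file not found: {path}")
    return path


def _read_coords(path: Path, spot_ids: Sequence[str]) -> np.ndarray:
    tab = pd.read_csv(path)
    for col in ("spot_id", "x", "y"):
        if col not in tab.columns:
            raise ValueError(f"{path} is missing required column '{col}'")
    if len(tab) != len(spot_ids):
        raise ValueError(
            f"coordinate table {path} has {len(tab)} rows for "
            f"{len(spot_ids)} spots"
        )
    tab = tab.set_index("spot_id").loc[list(spot_ids)]
    return tab[["x", "y"]].to_numpy(dtype=float)


def load_dataset(path: "str | os.PathLike", format: Format = "mtx-dir") -> SpatialDataset:
    """Load a :class:`SpatialDataset` from disk.

    ``mtx-dir`` expects ``matrix.mtx`` (genes x spots, CellRanger
    orientation), ``genes.tsv``, ``barcodes.tsv``, ``coords.csv`` and
    optionally ``image_features.csv`` / ``labels.csv`` in one directory.
    ``delimited`` expects ``expression.csv`` (spots x genes, indexed by spot
    id) plus the same sidecars. ``h5-container`` is a single ``.h5ad`` file.
    """
    path = Path(path)
    if format == "mtx-dir":
        if not path.is_dir():
            raise FileNotFoundError(f"not a directory: {path}")
        for fname in _MTX_FILES:
            _require(path / fname)
        mat = scipy.io.mmread(path / "matrix.mtx")  # genes x spots
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        X = sp.csr_matrix(mat.T) if sp.issparse(mat) else np.asarray(mat).T
        if X.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape} inconsistent with "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        coords = _read_coords(path / "coords.csv", barcodes)
        img = lab = None
        if (path / "image_features.csv").exists():
            img = (
                pd.read_csv(path / "image_features.csv", index_col=0)
                .loc[barcodes]
                .to_numpy(dtype=float)
            )
        if (path / "labels.csv").exists():
            lab = (
                pd.read_csv(path / "labels.csv", index_col="spot_id")
                .loc[barcodes, "label"]
                .to_numpy(dtype=int)
            )
        return SpatialDataset(X, coords, genes, barcodes, img, lab)
    if format == "delimited":
        if not path.is_dir():
            raise FileNotFoundError(f"not a directory: {path}")
        expr = pd.read_csv(_require(path / "expression.csv"), index_col=0)
        spot_ids = list(map(str, expr.index))
        coords = _read_coords(_require(path / "coords.csv"), spot_ids)
        img = lab = None
        if (path / "image_features.csv").exists():
            img = (
                pd.read_csv(path / "image_features.csv", index_col=0)
                .loc[spot_ids]
                .to_numpy(dtype=float)
            )
        if (path / "labels.csv").exists():
            lab = (
                pd.read_csv(path / "labels.csv", index_col="spot_id")
                .loc[spot_ids, "label"]
                .to_numpy(dtype=int)
            )
        return SpatialDataset(
            expr.to_numpy(dtype=float), coords, list(map(str, expr.columns)),
            spot_ids, img, lab,
        )
    if format == "h5-container":
        import anndata as ad

        _require(path)
        return SpatialDataset.from_anndata(ad.read_h5ad(path))
    raise ValueError(f"unknown format: {format!r}")


def save_dataset(ds: SpatialDataset, path: "str | os.PathLike", format: Format = "mtx-dir") -> None:
    """Write ``ds`` such that :func:`load_dataset` inverts the write."""
    if ds.n_genes == 0 or ds.n_spots == 0:
        raise ValueError("refusing to write a dataset with zero spots or genes")
    path = Path(path)
    if format == "h5-container":
        path.parent.mkdir(parents=True, exist_ok=True)
        ds.to_anndata().write_h5ad(path)
        return
    path.mkdir(parents=True, exist_ok=True)
    coords = pd.DataFrame(
        {"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
    )
    coords.to_csv(path / "coords.csv", index=False)
    if ds.image_features is not None:
        pd.DataFrame(ds.image_features, index=pd.Index(ds.spot_ids, name="spot_id")).to_csv(
            path / "image_features.csv"
        )
    if ds.labels is not None:
        pd.DataFrame({"spot_id": ds.spot_ids, "label": ds.labels}).to_csv(
            path / "labels.csv", index=False
        )
    if format == "mtx-dir":
        X = ds.expression
        mat = X.T if sp.issparse(X) else sp.csr_matrix(X.T)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(mat))
        pd.Series(ds.gene_names).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(ds.spot_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    elif format == "delimited":
        pd.DataFrame(
            ds.dense_expression(),
            index=pd.Index(ds.spot_ids, name="spot_id"),
            columns=ds.gene_names,
        ).to_csv(path / "expression.csv")
    else:
        raise ValueError(f"unknown format: {format!r}")


# -- preprocessing ---------------------------------------------------------


def preprocess(
    ds: SpatialDataset,
    target_sum: float = 1e4,
    n_hvg: int = 3000,
    flavor: str = "dispersion",
) -> SpatialDataset:
    """Library-size normalize, log1p-transform and keep highly variable genes.

    Each spot's counts are scaled to ``target_sum`` total, log(1+x) is
    applied, and the ``n_hvg`` most variable genes are retained. The default
    criterion ranks genes by dispersion (variance over mean) of the
    log-normalized values, unbinned, which behaves sensibly down to
    tiny fixtures; ``flavor='seurat'`` or ``'cell_ranger'`` delegates to the
    scanpy mean-binned variants instead. Genes with zero counts everywhere
    are dropped before ranking; ties are broken by gene name so the
    selection is deterministic.
    """
    import scanpy as sc

    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    if n_hvg <= 0:
        raise ValueError("n_hvg must be positive")
    X = ds.expression
    data = X.data if sp.issparse(X) else X
    if np.any(data < 0):
        raise ValueError("expression must be nonnegative")
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = [ds.spot_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"spots with zero total count: {bad}")

    adata = ds.to_anndata()
    # drop all-zero genes before ranking: their dispersion is undefined
    gene_totals = np.asarray(adata.X.sum(axis=0)).ravel()
    adata = adata[:, gene_totals > 0].copy()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    if adata.n_vars > n_hvg:
        if flavor == "dispersion":
            Y = adata.X
            Y = np.asarray(Y.todense()) if sp.issparse(Y) else np.asarray(Y)
            mean = Y.mean(axis=0)
            var = Y.var(axis=0)
            disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
        else:
            sc.pp.highly_variable_genes(adata, flavor=flavor, n_top_genes=n_hvg)
            disp = adata.var["dispersions_norm"].to_numpy(dtype=float)
            disp = np.nan_to_num(disp, nan=-np.inf)
        order = sorted(
            range(adata.n_vars), key=lambda j: (-disp[j], adata.var_names[j])
        )
        keep = sorted(order[:n_hvg])
        adata = adata[:, keep].copy()
    out = SpatialDataset.from_anndata(adata)
    return out
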