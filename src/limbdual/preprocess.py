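"""QC filtering, log-normalization, variable-gene selection, PCA and clustering.

These stages form the substrate on which the dual-identity calling operates:
cells are filtered on detected genes (nFeatures), total molecules (nCounts)
and mitochondrial fraction (pMito); counts are depth-normalized with the
median total as scale factor and log-transformed; highly variable genes are
picked by binned standardized dispersion; PCA is computed on centred,
unit-scaled (capped) values, and cells are clustered by modularity community
detection on a k-nearest-neighbour graph of the PC scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import anndata as ad
import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

LOGNORM_LAYER = "lognorm"


class QCError(ValueError):
    """QC filtering produced an unusable result (e.g. no cells left)."""


@dataclass
class QCThresholds:
    """Per-cell QC cutoffs.

    ``max_counts=None`` resolves to the ``max_counts_quantile`` quantile of the
    observed per-cell totals (a percentile rule standing in for the manual
    outlier identification on an nFeature-vs-nCount scatter).
    """

    min_features: int = 200
    max_features: int | None = None
    min_counts: int = 500
    max_counts: float | None = None
    max_counts_quantile: float = 0.995
    max_pmito: float = 0.10

    def validate(self) -> None:
        if self.max_features is not None and self.min_features > self.max_features:
            raise QCError("min_features > max_features")
        if self.max_counts is not None and self.min_counts > self.max_counts:
            raise QCError("min_counts > max_counts")
        if not (0.0 <= self.max_pmito <= 1.0):
            raise QCError("max_pmito must lie in [0, 1]")

    def resolve(self, n_counts: np.ndarray) -> "QCThresholds":
        """Concrete thresholds for this dataset (quantile rule evaluated)."""
        out = replace(self)
        if out.max_counts is None:
            out.max_counts = float(np.quantile(n_counts, out.max_counts_quantile))
        if out.max_features is None:
            out.max_features = np.iinfo(np.int64).max
        return out


@dataclass
class QCReport:
    cells: pd.DataFrame  # barcode-indexed: n_features, n_counts, p_mito, kept
    thresholds: QCThresholds
    removed_by: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.cells)

    @property
    def n_kept(self) -> int:
        return int(self.cells["kept"].sum())

    def to_tsv(self, path: str) -> None:
        self.cells.to_csv(path, sep="\t")


def qc_stats(adata: ad.AnnData, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell nFeatures, nCounts and pMito (pMito = 0 for zero-count cells)."""
    X = adata.X.tocsr() if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    n_counts = np.asarray(X.sum(axis=1)).ravel()
    n_features = np.asarray((X > 0).sum(axis=1)).ravel()
    mito = adata.var_names.str.startswith(mito_prefix)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_mito = np.where(n_counts > 0, mito_counts / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {"n_features": n_features.astype(int), "n_counts": n_counts, "p_mito": p_mito},
        index=adata.obs_names,
    )


def qc_filter(
    adata: ad.AnnData,
    thresholds: QCThresholds | None = None,
    mito_prefix: str = "MT-",
) -> tuple[ad.AnnData, QCReport]:
    """Remove cells violating any QC threshold; report per-threshold tallies."""
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    stats = qc_stats(adata, mito_prefix=mito_prefix)
    resolved = thresholds.resolve(stats["n_counts"].to_numpy())

    fails = {
        "low_features": stats["n_features"] < resolved.min_features,
        "high_features": stats["n_features"] > resolved.max_features,
        "low_counts": stats["n_counts"] < resolved.min_counts,
        "high_counts": stats["n_counts"] > resolved.max_counts,
        "high_pmito": stats["p_mito"] > resolved.max_pmito,
    }
    kept = ~np.logical_or.reduce([f.to_numpy() for f in fails.values()])
    cells = stats.copy()
    cells["kept"] = kept
    report = QCReport(
        cells=cells,
        thresholds=resolved,
        removed_by={name: int(mask.sum()) for name, mask in fails.items()},
    )
    if not kept.any():
        raise QCError("empty after QC: every cell violates at least one threshold")
    return adata[kept].copy(), report


def log_normalize(adata: ad.AnnData, scale_factor: float | None = None) -> float:
    """Depth-normalize and log-transform counts into the ``lognorm`` layer.

    value(g, c) = ln(1 + count(g, c) / total(c) * s), with s the median of
    per-cell totals unless given explicitly.  Returns the scale factor used.
    A value is zero iff the raw count is zero, and the transform is strictly
    monotone within each cell.
    """
    X = adata.X.tocsr() if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    if (totals <= 0).any():
        raise QCError(
            "log_normalize: cells with zero total counts present; run qc_filter first"
        )
    s = float(np.median(totals)) if scale_factor is None else float(scale_factor)
    if s <= 0:
        raise ValueError("scale_factor must be positive")
    norm = X.multiply((s / totals)[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    adata.layers[LOGNORM_LAYER] = norm
    adata.uns["scale_factor"] = s
    return s


def get_norm(adata: ad.AnnData, layer: str = LOGNORM_LAYER) -> sparse.csr_matrix:
    if layer not in adata.layers:
        raise KeyError(f"layer {layer!r} not found; run log_normalize first")
    M = adata.layers[layer]
    return M.tocsr() if sparse.issparse(M) else sparse.csr_matrix(M)


def _gene_moments(M: sparse.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = M.shape[0]
    mean = np.asarray(M.mean(axis=0)).ravel()
    sq = np.asarray(M.multiply(M).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))
    return mean, var


def select_hvg(
    adata: ad.AnnData, n_hvg: int, n_bins: int = 20, layer: str = LOGNORM_LAYER
) -> list[str]:
    """Top genes by standardized dispersion (variance z-scored within
    equal-frequency mean-expression bins).  Deterministic; ties broken by
    gene order."""
    if n_hvg <= 0:
        raise ValueError("n_hvg must be positive")
    if n_hvg > adata.n_vars:
        raise ValueError(f"n_hvg={n_hvg} exceeds number of genes {adata.n_vars}")
    M = get_norm(adata, layer)
    mean, var = _gene_moments(M)
    n_bins = max(1, min(n_bins, adata.n_vars))
    ranks = pd.Series(mean).rank(method="first")
    bins = pd.qcut(ranks, n_bins, labels=False, duplicates="drop")
    z = np.zeros_like(var)
    for b in np.unique(bins):
        sel = bins == b
        mu = var[sel].mean()
        sd = var[sel].std(ddof=0)
        z[sel] = (var[sel] - mu) / sd if sd > 0 else 0.0
    z[var == 0] = -np.inf  # invariant genes are never variable
    # stable order: standardized dispersion, then raw dispersion, then gene order
    order = np.lexsort((np.arange(len(z)), -var, -z))
    return [adata.var_names[i] for i in order[:n_hvg]]


@dataclass
class Embedding:
    scores: np.ndarray  # cells x n_pcs
    loadings: np.ndarray  # genes x n_pcs
    variance_explained: np.ndarray  # fraction of total retained variance
    hvg_used: list[str]
    barcodes: pd.Index

    def to_tsv(self, scores_path: str, loadings_path: str) -> None:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        pd.DataFrame(self.scores, index=self.barcodes, columns=cols).to_csv(scores_path, sep="\t")
        pd.DataFrame(self.loadings, index=self.hvg_used, columns=cols).to_csv(loadings_path, sep="\t")


def scale_matrix(
    M: np.ndarray, max_scale: float | None = 10.0, center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and unit-scale columns, capping scaled values at ``max_scale``."""
    if center is None:
        center = M.mean(axis=0)
    if scale is None:
        scale = M.std(axis=0, ddof=1)
    safe = np.where(scale > 1e-10, scale, 1.0)
    Z = (M - center) / safe
    if max_scale is not None:
        Z = np.minimum(Z, max_scale)
    return Z, center, scale


def _residualize(M: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    C = np.column_stack([np.ones(len(M)), covariates])
    beta, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ beta


def embed_pca(
    adata: ad.AnnData,
    hvg: Sequence[str],
    n_pcs: int,
    covariates: np.ndarray | pd.DataFrame | None = None,
    max_scale: float = 10.0,
    layer: str = LOGNORM_LAYER,
) -> Embedding:
    """PCA of centred, unit-scaled (capped) HVG expression.

    Covariates, if given, are regressed out of each gene by least squares
    before scaling (the generic hook for e.g. cell-cycle scores).
    """
    hvg = list(hvg)
    if n_pcs < 2:
        raise ValueError("n_pcs must be >= 2")
    if n_pcs > len(hvg):
        raise ValueError(f"n_pcs={n_pcs} exceeds number of HVGs {len(hvg)}")
    missing = [g for g in hvg if g not in adata.var_names]
    if missing:
        raise KeyError(f"HVGs absent from matrix: {missing}")
    M = np.asarray(get_norm(adata, layer)[:, [adata.var_names.get_loc(g) for g in hvg]].todense())
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if len(cov) != adata.n_obs:
            raise ValueError("covariates must have one row per cell")
        M = _residualize(M, cov)
    Z, _, _ = scale_matrix(M, max_scale=max_scale)
    Z = Z - Z.mean(axis=0)  # re-center after the cap
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = S**2
    total = var.sum()
    return Embedding(
        scores=U[:, :n_pcs] * S[:n_pcs],
        loadings=Vt[:n_pcs].T,
        variance_explained=var[:n_pcs] / total if total > 0 else var[:n_pcs],
        hvg_used=hvg,
        barcodes=adata.obs_names.copy(),
    )


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-cell cluster id, contiguous from 0
    barcodes: pd.Index
    resolution: float
    k_neighbors: int
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def to_tsv(self, path: str) -> None:
        pd.Series(self.labels, index=self.barcodes, name="cluster").to_csv(path, sep="\t")


def knn_graph(scores: np.ndarray, k_neighbors: int) -> ig.Graph:
    """Undirected, unweighted union-of-kNN graph on Euclidean PC distances."""
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    edges = set()
    for i, row in enumerate(idx):
        for j in row:
            if j != i:
                edges.add((min(i, int(j)), max(i, int(j))))
    return ig.Graph(n=len(scores), edges=sorted(edges), directed=False)


def cluster_cells(
    embedding: Embedding, k_neighbors: int = 20, resolution: float = 1.0, seed: int = 0
) -> ClusterAssignment:
    """Modularity community detection (Leiden/RBConfiguration) on the kNN graph.

    Cells are processed in barcode order internally, so the partition is
    invariant to the input ordering of cells.
    """
    n = len(embedding.scores)
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be smaller than the cell count {n}")
    order = np.argsort(embedding.barcodes.to_numpy(), kind="stable")
    g = knn_graph(embedding.scores[order], k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # relabel contiguously by first appearance in barcode order
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap)
    canonical = np.array([remap[lab] for lab in raw])
    labels = np.empty(n, dtype=int)
    labels[order] = canonical
    return ClusterAssignment(
        labels=labels,
        barcodes=embedding.barcodes.copy(),
        resolution=resolution,
        k_neighbors=k_neighbors,
        seed=seed,
    )
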