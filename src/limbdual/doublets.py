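"""Simulated-doublet nearest-neighbour scoring and removal.

Synthetic doublets are built by summing the raw counts of random cell pairs;
observed and synthetic profiles are jointly depth-normalized and embedded
(PCA fitted on observed cells only, synthetic profiles projected), and each
observed cell is scored by the fraction of its k nearest neighbours that are
synthetic.  The raw fraction is converted to an odds-style score corrected
for the synthetic:observed imbalance, so a cell whose neighbourhood contains
synthetic doublets at the global background rate scores about 1.

Because depth is removed by the joint normalization, discrimination rests on
mixed expression profiles alone — deliberately the hard, honest case for
distinguishing genuine transitional cells from two-cell captures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .preprocess import scale_matrix

SIM_PREFIX = "SIMDBL:"


@dataclass
class DoubletScores:
    table: pd.DataFrame  # barcode-indexed: raw, adjusted, call
    n_simulated: int
    k_neighbors: int
    n_pcs: int
    threshold: float | None = None
    strategy: str | None = None

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t")


def default_n_sim(n_obs: int, multiplier: float = 2.0) -> int:
    return int(round(multiplier * n_obs))


def default_k(n_total: int) -> int:
    return max(1, int(round(0.5 * math.sqrt(n_total))))


def simulate_synthetic_doublets(adata: ad.AnnData, n_sim: int, seed: int) -> ad.AnnData:
    """``n_sim`` profiles, each the raw-count sum of two distinct random cells."""
    if n_sim <= 0:
        raise ValueError("n_sim must be >= 1")
    n = adata.n_obs
    if n < 2:
        raise ValueError("need at least 2 cells to simulate doublets")
    rng = np.random.default_rng(seed)
    i1 = rng.integers(0, n, size=n_sim)
    i2 = (i1 + 1 + rng.integers(0, n - 1, size=n_sim)) % n
    X = adata.X.tocsr() if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    sim = ad.AnnData(
        X=(X[i1] + X[i2]).tocsr(),
        obs=pd.DataFrame(
            {
                "parent1": adata.obs_names.to_numpy()[i1],
                "parent2": adata.obs_names.to_numpy()[i2],
            },
            index=pd.Index([f"{SIM_PREFIX}{i:06d}" for i in range(n_sim)], name="barcode"),
        ),
        var=adata.var.copy(),
    )
    return sim


def _lognorm_dense(X: sparse.spmatrix, s: float) -> np.ndarray:
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    totals = np.maximum(totals, 1.0)
    M = X.multiply((s / totals)[:, None]).tocsr()
    M.data = np.log1p(M.data)
    return np.asarray(M.todense())


def adjusted_score(n_sim_neighbors: np.ndarray, k: int, n_obs: int, n_sim: int) -> np.ndarray:
    """Odds of simulated neighbours, corrected for the simulated:observed ratio.

    adjusted = raw/(1-raw) * n_obs/n_sim; a saturated neighbourhood (raw = 1)
    is mapped to a large finite odds by flooring the denominator at 0.5.
    """
    n_sim_neighbors = np.asarray(n_sim_neighbors, dtype=float)
    odds = n_sim_neighbors / np.maximum(k - n_sim_neighbors, 0.5)
    return odds * (n_obs / n_sim)


def score_doublets(
    observed: ad.AnnData,
    simulated: ad.AnnData,
    k_neighbors: int | None = None,
    n_pcs: int = 30,
    seed: int = 0,
) -> DoubletScores:
    """Score each observed cell by simulated-doublet density in its PC
    neighbourhood."""
    if simulated.n_obs == 0:
        raise ValueError("simulated doublet set is empty")
    if list(simulated.var_names) != list(observed.var_names):
        raise ValueError("observed and simulated matrices must share the gene axis")
    n_obs, n_sim = observed.n_obs, simulated.n_obs
    n_total = n_obs + n_sim
    k = default_k(n_total) if k_neighbors is None else int(k_neighbors)
    if k >= n_total:
        raise ValueError(f"k_neighbors={k} must be smaller than the combined size {n_total}")
    n_pcs = min(n_pcs, observed.n_vars, n_obs - 1)

    Xo = observed.X.tocsr() if sparse.issparse(observed.X) else sparse.csr_matrix(observed.X)
    Xs = simulated.X.tocsr() if sparse.issparse(simulated.X) else sparse.csr_matrix(simulated.X)
    s = float(np.median(np.asarray(Xo.sum(axis=1)).ravel()))
    Mo = _lognorm_dense(Xo, s)
    Ms = _lognorm_dense(Xs, s)

    Zo, center, scale = scale_matrix(Mo)
    Zs, _, _ = scale_matrix(Ms, center=center, scale=scale)
    Zo = Zo - Zo.mean(axis=0)
    _, S, Vt = np.linalg.svd(Zo, full_matrices=False)
    basis = Vt[:n_pcs].T
    emb = np.vstack([Zo @ basis, Zs @ basis])

    is_sim = np.zeros(n_total, dtype=bool)
    is_sim[n_obs:] = True
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n_obs])
    # drop self from each neighbourhood (robust to exact ties at distance 0)
    neigh = np.empty((n_obs, k), dtype=int)
    for i in range(n_obs):
        row = idx[i]
        neigh[i] = row[row != i][:k]
    n_sim_nb = is_sim[neigh].sum(axis=1)
    raw = n_sim_nb / k
    adjusted = adjusted_score(n_sim_nb, k, n_obs, n_sim)

    table = pd.DataFrame(
        {"raw": raw, "adjusted": adjusted, "call": np.zeros(n_obs, dtype=bool)},
        index=observed.obs_names.copy(),
    )
    return DoubletScores(table=table, n_simulated=n_sim, k_neighbors=k, n_pcs=n_pcs)


def call_doublets(
    scores: DoubletScores, strategy: str = "fixed_quantile", param: float = 0.05
) -> DoubletScores:
    """Flag doublets by adjusted score: top ``param`` fraction
    (``fixed_quantile``, ties broken by barcode order) or score > ``param``
    (``fixed_threshold``)."""
    table = scores.table.copy()
    if strategy == "fixed_threshold":
        table["call"] = table["adjusted"] > param
    elif strategy == "fixed_quantile":
        if not (0.0 < param < 1.0):
            raise ValueError("fixed_quantile param must lie in (0, 1)")
        n_call = int(round(param * len(table)))
        order = table.sort_values("adjusted", ascending=False, kind="stable")
        # stable sort on descending score; equal scores resolve by barcode order
        flagged = order.index[:n_call]
        table["call"] = table.index.isin(flagged)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return replace(scores, table=table, threshold=float(param), strategy=strategy)


def remove_doublets(adata: ad.AnnData, scores: DoubletScores) -> ad.AnnData:
    keep = ~scores.table.loc[adata.obs_names, "call"].to_numpy()
    return adata[keep].copy()
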