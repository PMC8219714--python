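"""Self-implemented differential-expression statistics.

Wilcoxon rank-sum (exact permutation distribution for small groups, tie- and
continuity-corrected normal approximation otherwise), Fisher's exact test,
Benjamini-Hochberg step-up correction, one-vs-rest marker discovery, the
dual-vs-(CT u M) comparison with its bi-phasic marker summary,
expressing-fraction comparisons, and the 2^-ddCt qPCR quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import gammaln, ndtr
from scipy.stats import rankdata

from .identity import MarkerPanel
from .preprocess import get_norm

_ALTERNATIVES = ("two_sided", "less", "greater")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_ranksum_tail(ranks2: np.ndarray, n1: int, w2: int) -> tuple[float, float]:
    """P(W <= w), P(W >= w) for the rank sum W of a size-n1 subset, by a
    subset-sum DP over doubled midranks (exact under exchangeability, ties
    included)."""
    ranks2 = np.sort(ranks2)
    max_sum = int(ranks2[-n1:].sum())
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        hi = min(n1, len(ranks2))
        for j in range(hi, 0, -1):
            if r <= max_sum:
                dp[j, r:] += dp[j - 1, : max_sum + 1 - r]
    counts = dp[n1]
    total = counts.sum()
    w2 = min(max(w2, 0), max_sum)
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    return float(p_le), float(p_ge)


def _tie_term(pooled: np.ndarray) -> float:
    _, t = np.unique(pooled, return_counts=True)
    return float((t**3 - t).sum())


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Rank-sum test of two samples; returns (rank sum of x, p-value).

    Midranks for ties.  For min(|x|, |y|) >= 8 the normal approximation with
    tie-corrected variance and 0.5 continuity correction is used; otherwise
    the exact permutation distribution of the rank sum.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    N = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    W = float(ranks[:n1].sum())
    if np.unique(pooled).size == 1:
        return W, 1.0

    if min(n1, n2) >= 8:
        mu = n1 * (N + 1) / 2.0
        var = n1 * n2 / 12.0 * ((N + 1) - _tie_term(pooled) / (N * (N - 1)))
        if var <= 0:
            return W, 1.0
        sd = np.sqrt(var)
        if alternative == "two_sided":
            d = max(abs(W - mu) - 0.5, 0.0)
            p = 2.0 * float(ndtr(-d / sd))
        elif alternative == "less":
            p = float(ndtr((W - mu + 0.5) / sd))
        else:
            p = float(ndtr(-(W - mu - 0.5) / sd))
        return W, min(p, 1.0)

    ranks2 = np.rint(2.0 * ranks).astype(np.int64)
    w2 = int(round(2.0 * W))
    # exact: rank x's before y's so the subset in question is x
    nx = n1 if n1 <= n2 else n2
    if n1 <= n2:
        p_le, p_ge = _exact_ranksum_tail(ranks2, nx, int(ranks2[:n1].sum()))
    else:
        # work with the smaller sample; tails swap (W_x + W_y is fixed)
        p_le_y, p_ge_y = _exact_ranksum_tail(ranks2, nx, int(ranks2[n1:].sum()))
        p_le, p_ge = p_ge_y, p_le_y
    if alternative == "two_sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "less":
        p = p_le
    else:
        p = p_ge
    return W, p


def _ranksum_p_vectorized(values: np.ndarray, mask_in: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided rank-sum p per column of *values* (cells x genes), comparing
    mask_in cells against the rest.  Normal approximation with tie correction
    and continuity; suitable when both groups have >= 8 cells."""
    n1 = int(mask_in.sum())
    n2 = values.shape[0] - n1
    N = n1 + n2
    ranks = rankdata(values, axis=0)
    W = ranks[mask_in].sum(axis=0)
    mu = n1 * (N + 1) / 2.0
    tie = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        tie[j] = _tie_term(values[:, j])
    var = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    d = np.maximum(np.abs(W - mu) - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(sd > 0, 2.0 * ndtr(-d / np.maximum(sd, 1e-300)), 1.0)
    return W, np.minimum(p, 1.0)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table, alternative: str = "two_sided") -> float:
    """Fisher's exact p for a 2x2 table [[a, b], [c, d]].

    Two-sided p sums hypergeometric probabilities of tables at most as likely
    as the observed one (relative tolerance 1e-7 for probability ties).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    (a, b), (c, d) = table
    cells = np.array([a, b, c, d])
    if (cells < 0).any() or not np.all(cells == np.floor(cells)):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(v) for v in cells)
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == N:
        return 1.0

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(r2 + 1) - gammaln(c1 - support + 1) - gammaln(r2 - c1 + support + 1)
        - (gammaln(N + 1) - gammaln(c1 + 1) - gammaln(N - c1 + 1))
    )
    pmf = np.exp(logp)
    pmf = pmf / pmf.sum()
    p_obs = pmf[a - lo]
    if alternative == "less":
        p = pmf[support <= a].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    else:
        p = pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# multiple-testing correction
# ---------------------------------------------------------------------------

def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bonferroni(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


_ADJUST = {"bh": benjamini_hochberg, "bonferroni": bonferroni}


# ---------------------------------------------------------------------------
# marker discovery / group DE
# ---------------------------------------------------------------------------

DE_COLUMNS = ("gene", "group", "log_fc", "p_raw", "p_adj", "pct_in", "pct_out", "direction")
_LOGFC_EPS = 1e-9


def _dense_values(adata: ad.AnnData, genes, layer: str) -> tuple[np.ndarray, list[str]]:
    genes = list(genes) if genes is not None else list(adata.var_names)
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    cols = [adata.var_names.get_loc(g) for g in genes]
    M = get_norm(adata, layer)[:, cols]
    return np.asarray(M.todense()), genes


def _log_fc(values_in: np.ndarray, values_out: np.ndarray) -> np.ndarray:
    mean_in = np.expm1(values_in).mean(axis=0)
    mean_out = np.expm1(values_out).mean(axis=0)
    return np.log(mean_in + _LOGFC_EPS) - np.log(mean_out + _LOGFC_EPS)


def _de_one_comparison(
    values: np.ndarray, genes: list[str], mask_in: np.ndarray, group_name: str,
    min_pct: float, logfc_min: float, p_adjust: str,
) -> pd.DataFrame:
    mask_in = np.asarray(mask_in, dtype=bool)
    vin, vout = values[mask_in], values[~mask_in]
    pct_in = (vin > 0).mean(axis=0)
    pct_out = (vout > 0).mean(axis=0)
    log_fc = _log_fc(vin, vout)
    testable = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (np.abs(log_fc) >= logfc_min)

    p_raw = np.full(len(genes), np.nan)
    idx = np.flatnonzero(testable)
    if idx.size:
        if min(mask_in.sum(), (~mask_in).sum()) >= 8:
            _, p = _ranksum_p_vectorized(values[:, idx], mask_in)
        else:
            p = np.array(
                [wilcoxon_rank_sum(vin[:, j], vout[:, j])[1] for j in idx]
            )
        p_raw[idx] = p
    p_adj = np.full(len(genes), np.nan)
    if idx.size:
        p_adj[idx] = _ADJUST[p_adjust](p_raw[idx])

    df = pd.DataFrame(
        {
            "gene": genes,
            "group": group_name,
            "log_fc": log_fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "direction": np.where(log_fc > 0, "up", np.where(log_fc < 0, "down", "flat")),
        }
    )
    df = df[~df["p_raw"].isna()]
    return df


def _sort_de(df: pd.DataFrame) -> pd.DataFrame:
    df = df.assign(_abslfc=-df["log_fc"].abs())
    df = df.sort_values(["p_adj", "_abslfc", "gene"], kind="stable").drop(columns="_abslfc")
    return df.reset_index(drop=True)


def find_markers(
    adata: ad.AnnData,
    groups,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    alpha_adj: float = 0.05,
    genes=None,
    p_adjust: str = "bh",
    layer: str = "lognorm",
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker discovery per group, BH-corrected within
    each group.  Groups with fewer than 3 cells are skipped with a warning."""
    groups = np.asarray(groups)
    if len(groups) != adata.n_obs:
        raise ValueError("groups must have one label per cell")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    values, gene_list = _dense_values(adata, genes, layer)
    frames = []
    for g in uniq:
        mask = groups == g
        if mask.sum() < 3:
            warnings.warn(f"group {g!r} has fewer than 3 cells; skipped", stacklevel=2)
            continue
        df = _de_one_comparison(
            values, gene_list, mask, str(g), min_pct, logfc_min, p_adjust
        )
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=[*DE_COLUMNS, "significant"])
    out = _sort_de(pd.concat(frames, ignore_index=True))
    out["significant"] = out["p_adj"] < alpha_adj
    return out


def top_markers(de_table: pd.DataFrame, n: int = 10, positive_only: bool = True) -> pd.DataFrame:
    """Top-n significant markers per group (the heatmap gene lists)."""
    df = de_table[de_table["significant"]]
    if positive_only:
        df = df[df["log_fc"] > 0]
    # the table is already sorted by (p_adj, |log_fc|, gene) within each group
    return df.groupby("group", sort=False).head(n).reset_index(drop=True)


def de_dual_vs_union(
    adata: ad.AnnData,
    labels,
    panel: MarkerPanel | None = None,
    genes=None,
    min_pct: float = 0.1,
    logfc_min: float = 0.0,
    alpha_adj: float = 0.05,
    p_adjust: str = "bh",
    layer: str = "lognorm",
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """DE of CT/M cells against the combined CT and M cells, plus the
    bi-phasic marker summary.

    The summary reports, for each CT marker, the sign and significance of
    CT/M vs CT, and for each muscle marker CT/M vs (CT u M) — the comparison
    under which the transit signature reads "CT markers down, muscle markers
    up".  Returns (DE table, bi-phasic summary, status).
    """
    panel = panel or MarkerPanel()
    labels = np.asarray(labels, dtype=str)
    dual = labels == "CT_M"
    union = (labels == "CT") | (labels == "M")
    if not dual.any():
        empty = pd.DataFrame(columns=[*DE_COLUMNS, "significant"])
        return empty, pd.DataFrame(columns=["gene", "panel", "versus", "log_fc", "p_adj", "call"]), "no dual cells"

    gene_list = list(genes) if genes is not None else list(adata.var_names)
    for g in panel.all_genes:  # the summary always covers the panel
        if g not in gene_list:
            gene_list.append(g)
    values, gene_list = _dense_values(adata, gene_list, layer)

    sub = dual | union
    de = _de_one_comparison(
        values[sub], gene_list, dual[sub], "CT_M", min_pct, logfc_min, p_adjust
    )
    de = _sort_de(de)
    de["significant"] = de["p_adj"] < alpha_adj

    rows = []
    gidx = {g: i for i, g in enumerate(gene_list)}
    ct_mask = labels == "CT"
    for g in panel.ct_genes:
        col = values[:, gidx[g]]
        _, p = wilcoxon_rank_sum(col[dual], col[ct_mask])
        lfc = float(_log_fc(col[dual, None], col[ct_mask, None])[0])
        rows.append((g, "ct", "CT", lfc, p))
    for g in panel.m_genes:
        col = values[:, gidx[g]]
        _, p = wilcoxon_rank_sum(col[dual], col[union])
        lfc = float(_log_fc(col[dual, None], col[union, None])[0])
        rows.append((g, "m", "CT+M", lfc, p))
    summary = pd.DataFrame(rows, columns=["gene", "panel", "versus", "log_fc", "p_raw"])
    summary["p_adj"] = _ADJUST[p_adjust](summary["p_raw"].to_numpy())
    sig = summary["p_adj"] < alpha_adj
    summary["call"] = np.where(
        sig & (summary["log_fc"] > 0), "up", np.where(sig & (summary["log_fc"] < 0), "down", "ns")
    )
    return de, summary, "ok"


def fraction_expressing_compare(
    adata: ad.AnnData,
    gene_set,
    labels,
    group_a: str,
    group_b: str,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Per-gene (and pooled "expresses any set gene") expressing fractions in
    two identity groups, compared by two-sided Fisher's exact test."""
    labels = np.asarray(labels, dtype=str)
    mask_a = labels == group_a
    mask_b = labels == group_b
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"empty group: {group_a if not mask_a.any() else group_b}")
    values, gene_list = _dense_values(adata, list(gene_set), layer)
    rows = []
    for j, g in enumerate(gene_list):
        ea = int((values[mask_a, j] > 0).sum())
        eb = int((values[mask_b, j] > 0).sum())
        na, nb = int(mask_a.sum()), int(mask_b.sum())
        p = fisher_exact_2x2([[ea, na - ea], [eb, nb - eb]])
        rows.append((g, ea / na, eb / nb, p))
    any_a = (values[mask_a] > 0).any(axis=1)
    any_b = (values[mask_b] > 0).any(axis=1)
    ea, eb = int(any_a.sum()), int(any_b.sum())
    na, nb = len(any_a), len(any_b)
    rows.append(("__pooled__", ea / na, eb / nb, fisher_exact_2x2([[ea, na - ea], [eb, nb - eb]])))
    return pd.DataFrame(rows, columns=["gene", f"frac_{group_a}", f"frac_{group_b}", "p"])


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

@dataclass
class DdctResult:
    table: pd.DataFrame  # sample-indexed: condition, delta_ct, ddct, rel_level
    target_gene: str
    reference_genes: tuple[str, ...]
    control_condition: str


def ddct(
    data: pd.DataFrame,
    target_gene: str,
    reference_genes=("GAPDH", "RPS17"),
    control_condition: str = "control",
) -> DdctResult:
    """2^-ddCt relative expression from long-format Ct values.

    ``data`` columns: sample, condition, gene, ct.  dCt = Ct(target) minus the
    mean reference-gene Ct per sample; ddCt subtracts the mean control dCt, so
    the control condition is centred at a relative level of 1 (its geometric
    mean is exactly 1).
    """
    required = {"sample", "condition", "gene", "ct"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    reference_genes = tuple(reference_genes)
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    if not np.isfinite(data["ct"].to_numpy(dtype=float)).all():
        raise ValueError("Ct values must be finite")

    wide = data.pivot_table(index=["sample", "condition"], columns="gene", values="ct")
    for g in (target_gene, *reference_genes):
        if g not in wide.columns or wide[g].isna().any():
            raise ValueError(f"missing Ct values for gene {g!r}")
    delta = wide[target_gene] - wide[list(reference_genes)].mean(axis=1)
    conditions = delta.index.get_level_values("condition")
    if control_condition not in set(conditions):
        raise ValueError(f"control condition {control_condition!r} has no samples")
    control_mean = delta[conditions == control_condition].mean()
    ddct_vals = delta - control_mean
    table = pd.DataFrame(
        {
            "condition": conditions,
            "delta_ct": delta.to_numpy(),
            "ddct": ddct_vals.to_numpy(),
            "rel_level": np.power(2.0, -ddct_vals.to_numpy()),
        },
        index=delta.index.get_level_values("sample"),
    )
    return DdctResult(
        table=table,
        target_gene=target_gene,
        reference_genes=reference_genes,
        control_condition=control_condition,
    )
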