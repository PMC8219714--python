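"""End-to-end orchestration: simulate/load -> QC -> doublet removal ->
normalize -> HVG -> PCA -> cluster -> annotate -> dual call -> identity ->
scores -> DE -> report, plus the parameter-recovery benchmark.

A single global seed is expanded into per-stage seeds through a documented
counter scheme (SeedSequence over (seed, stage index)), so each stage is
individually reproducible and stages never share streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de_stats import de_dual_vs_union, find_markers, fraction_expressing_compare, top_markers
from .doublets import (
    DoubletScores,
    call_doublets,
    default_n_sim,
    remove_doublets,
    score_doublets,
    simulate_synthetic_doublets,
)
from .identity import (
    FractionReport,
    MarkerPanel,
    annotate_clusters,
    assign_identity,
    call_dual,
    identity_fraction_report,
    module_score,
)
from .preprocess import (
    ClusterAssignment,
    Embedding,
    QCReport,
    QCThresholds,
    cluster_cells,
    embed_pca,
    log_normalize,
    qc_filter,
    select_hvg,
)
from .simulate import SimConfig, read_dataset, simulate_counts

log = logging.getLogger("limbdual")

_STAGES = (
    "simulate", "qc", "doublet_sim", "doublet_knn", "cluster",
    "score_ct", "score_m", "de", "report",
)


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration keys."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed of the global seed."""
    if stage not in _STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class DoubletConfig:
    enabled: bool = True
    n_sim_multiplier: float = 2.0
    k_neighbors: int | None = None
    # compact embedding: enough components to span the population structure;
    # excess components add unstructured noise dims that dilute the
    # simulated-doublet density signal around rare states
    n_pcs: int = 6
    strategy: str = "fixed_quantile"
    param: float = 0.05


@dataclass
class DEConfig:
    min_pct: float = 0.1
    logfc_min: float = 0.25
    alpha_adj: float = 0.05
    p_adjust: str = "bh"
    gene_universe: str = "hvg"  # 'all' or 'hvg'
    top_n: int = 10


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    doublet: DoubletConfig = field(default_factory=DoubletConfig)
    de: DEConfig = field(default_factory=DEConfig)
    mito_prefix: str = "MT-"
    scale_factor: float | None = None
    n_hvg: int = 150
    n_pcs: int = 30
    k_neighbors: int = 20
    resolution: float = 1.0
    ct_genes: tuple[str, ...] = MarkerPanel().ct_genes
    m_genes: tuple[str, ...] = MarkerPanel().m_genes
    score_bins: int = 25
    score_ctrl: int = 100
    annotate_margin: float = 0.5
    probe_genes: tuple[str, ...] = ("ID1", "ID2", "ID3", "MYOG", "PAX7", "OSR1")
    seed: int = 0

    @property
    def panel(self) -> MarkerPanel:
        return MarkerPanel(tuple(self.ct_genes), tuple(self.m_genes))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        def build(dc_type, data, path):
            if data is None:
                return dc_type()
            if not isinstance(data, dict):
                raise ConfigError(f"{path}: expected a mapping")
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(data) - names
            if unknown:
                raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
            kwargs = {}
            for f in dataclasses.fields(dc_type):
                if f.name not in data:
                    continue
                v = data[f.name]
                if dataclasses.is_dataclass(f.type) or f.name in ("sim", "qc", "doublet", "de"):
                    sub = {"sim": SimConfig, "qc": QCThresholds, "doublet": DoubletConfig, "de": DEConfig}[f.name]
                    v = build(sub, v, f"{path}.{f.name}")
                elif isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
            return dc_type(**kwargs)

        return build(cls, payload, "config")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    adata: ad.AnnData
    qc_report: QCReport
    doublet_scores: DoubletScores | None
    embedding: Embedding
    clusters: ClusterAssignment
    cluster_classes: dict[int, str]
    fractions: FractionReport
    markers: pd.DataFrame
    de_dual: pd.DataFrame
    biphasic: pd.DataFrame
    de_status: str
    manifest: dict

    def write(self, out_dir: str | os.PathLike) -> None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        obs_cols = [
            c for c in (
                "population", "pseudotime", "is_doublet", "cluster", "cluster_class",
                "dual", "identity", "ct_score", "m_score",
            ) if c in self.adata.obs
        ]
        self.adata.obs[obs_cols].to_csv(os.path.join(out_dir, "cells.tsv"), sep="\t")
        self.qc_report.to_tsv(os.path.join(out_dir, "qc_report.tsv"))
        if self.doublet_scores is not None:
            self.doublet_scores.to_tsv(os.path.join(out_dir, "doublet_scores.tsv"))
        self.clusters.to_tsv(os.path.join(out_dir, "clusters.tsv"))
        self.embedding.to_tsv(
            os.path.join(out_dir, "pca_scores.tsv"), os.path.join(out_dir, "pca_loadings.tsv")
        )
        self.markers.to_csv(os.path.join(out_dir, "markers.tsv"), sep="\t", index=False)
        top_markers(self.markers).to_csv(
            os.path.join(out_dir, "top_markers.tsv"), sep="\t", index=False
        )
        self.de_dual.to_csv(os.path.join(out_dir, "de_dual_vs_union.tsv"), sep="\t", index=False)
        self.biphasic.to_csv(os.path.join(out_dir, "biphasic_summary.tsv"), sep="\t", index=False)
        self.fractions.to_tsv(os.path.join(out_dir, "fractions.tsv"))
        self.fractions.to_json(os.path.join(out_dir, "summary.json"))
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _log_stage(stage: str, **info) -> None:
    details = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage %-12s %s", stage, details)


def run_pipeline(
    config: PipelineConfig,
    adata: ad.AnnData | None = None,
    data_dir: str | None = None,
    out_dir: str | None = None,
) -> ResultBundle:
    """Execute all stages in the fixed order and return the result bundle."""
    if not logging.getLogger().handlers and not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")

    if adata is None:
        if data_dir is not None:
            adata = read_dataset(data_dir)
            _log_stage("load", cells=adata.n_obs, genes=adata.n_vars)
        else:
            adata = simulate_counts(config.sim)
            _log_stage("simulate", cells=adata.n_obs, genes=adata.n_vars)

    try:
        adata, qc_report = qc_filter(adata, config.qc, mito_prefix=config.mito_prefix)
    except Exception as exc:
        raise type(exc)(f"stage qc_filter: {exc}") from exc
    _log_stage("qc", kept=qc_report.n_kept, removed=qc_report.n_input - qc_report.n_kept)

    doublet_scores = None
    if config.doublet.enabled:
        n_sim = default_n_sim(adata.n_obs, config.doublet.n_sim_multiplier)
        sim = simulate_synthetic_doublets(adata, n_sim, seed=stage_seed(config.seed, "doublet_sim"))
        doublet_scores = score_doublets(
            adata, sim,
            k_neighbors=config.doublet.k_neighbors,
            n_pcs=config.doublet.n_pcs,
            seed=stage_seed(config.seed, "doublet_knn"),
        )
        doublet_scores = call_doublets(doublet_scores, config.doublet.strategy, config.doublet.param)
        adata.obs["doublet_adjusted"] = doublet_scores.table.loc[adata.obs_names, "adjusted"].to_numpy()
        adata.obs["doublet_call"] = doublet_scores.table.loc[adata.obs_names, "call"].to_numpy()
        adata = remove_doublets(adata, doublet_scores)
        _log_stage("doublets", flagged=int(doublet_scores.table["call"].sum()), kept=adata.n_obs)

    scale = log_normalize(adata, scale_factor=config.scale_factor)
    _log_stage("normalize", scale_factor=round(scale, 3))

    n_hvg = min(config.n_hvg, adata.n_vars)
    hvg = select_hvg(adata, n_hvg)
    embedding = embed_pca(adata, hvg, n_pcs=min(config.n_pcs, n_hvg))
    _log_stage("pca", n_hvg=n_hvg, n_pcs=embedding.scores.shape[1])

    clusters = cluster_cells(
        embedding,
        k_neighbors=config.k_neighbors,
        resolution=config.resolution,
        seed=stage_seed(config.seed, "cluster"),
    )
    adata.obs["cluster"] = clusters.labels
    _log_stage("cluster", n_clusters=clusters.n_clusters)

    panel = config.panel
    panel.validate(adata.var_names)
    # panel and probe genes differ between the populations the scores compare,
    # so they are barred from every control pool
    score_exclude = [*panel.all_genes, *config.probe_genes]
    ct_score = module_score(
        adata, panel.ct_genes, n_bins=config.score_bins, n_ctrl=config.score_ctrl,
        seed=stage_seed(config.seed, "score_ct"), exclude=score_exclude,
    )
    m_score = module_score(
        adata, panel.m_genes, n_bins=config.score_bins, n_ctrl=config.score_ctrl,
        seed=stage_seed(config.seed, "score_m"), exclude=score_exclude,
    )
    adata.obs["ct_score"] = ct_score
    adata.obs["m_score"] = m_score

    cluster_classes = annotate_clusters(
        adata, clusters, panel, margin=config.annotate_margin,
        ct_score=ct_score, m_score=m_score,
    )
    adata.obs["cluster_class"] = [cluster_classes[c] for c in clusters.labels]

    dual = call_dual(adata, panel)
    adata.obs["dual"] = dual
    identity = assign_identity(clusters, cluster_classes, dual)
    adata.obs["identity"] = identity
    _log_stage(
        "identity",
        ct=int((identity == "CT").sum()), ct_m=int((identity == "CT_M").sum()),
        m=int((identity == "M").sum()), other=int((identity == "OTHER").sum()),
    )

    probe = [g for g in config.probe_genes if g in adata.var_names]
    fractions = identity_fraction_report(identity, adata, panel, probe_genes=probe)

    universe = hvg if config.de.gene_universe == "hvg" else None
    markers = find_markers(
        adata, clusters.labels,
        min_pct=config.de.min_pct, logfc_min=config.de.logfc_min,
        alpha_adj=config.de.alpha_adj, genes=universe, p_adjust=config.de.p_adjust,
    )
    de_dual, biphasic, de_status = de_dual_vs_union(
        adata, identity, panel, genes=universe,
        min_pct=config.de.min_pct, alpha_adj=config.de.alpha_adj, p_adjust=config.de.p_adjust,
    )
    _log_stage("de", markers=len(markers), dual_de=len(de_dual), status=de_status)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_cells_input": qc_report.n_input,
        "n_cells_final": adata.n_obs,
        "n_genes": adata.n_vars,
        "n_clusters": clusters.n_clusters,
        "scale_factor": scale,
        "identity_percent": fractions.identity_percent,
    }
    bundle = ResultBundle(
        adata=adata, qc_report=qc_report, doublet_scores=doublet_scores,
        embedding=embedding, clusters=clusters, cluster_classes=cluster_classes,
        fractions=fractions, markers=markers,
        de_dual=de_dual, biphasic=biphasic, de_status=de_status, manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# recovery benchmark
# ---------------------------------------------------------------------------

def _auroc(score: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUROC (equivalent to the Mann-Whitney statistic)."""
    from scipy.stats import rankdata

    truth = np.asarray(truth, dtype=bool)
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(score)
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def recovery_benchmark(
    base_config: PipelineConfig,
    dual_fractions,
    doublet_rates,
    n_seeds: int = 3,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Grid of pipeline runs recording estimated vs planted dual fraction,
    doublet AUROC, transitional-flagged rate and cluster/population ARI."""
    if n_seeds < 3:
        raise ValueError("n_seeds must be >= 3")
    rows = []
    for f in dual_fractions:
        for r in doublet_rates:
            for s in range(n_seeds):
                seed = base_seed + s
                cfg = dataclasses.replace(
                    base_config,
                    sim=dataclasses.replace(base_config.sim, dual_fraction=f, doublet_rate=r, seed=seed),
                    seed=seed,
                )
                sim = simulate_counts(cfg.sim)
                bundle = run_pipeline(cfg, adata=sim)
                rows.append(
                    {
                        "dual_fraction": f,
                        "doublet_rate": r,
                        "seed": seed,
                        **run_metrics(bundle, sim),
                    }
                )
    return pd.DataFrame(rows)


def run_metrics(bundle: ResultBundle, sim: ad.AnnData) -> dict[str, float]:
    """Ground-truth metrics for a pipeline run on a simulated dataset."""
    from sklearn.metrics import adjusted_rand_score

    obs = bundle.adata.obs
    metrics: dict[str, float] = {
        "est_dual_pct": bundle.fractions.identity_percent["CT_M"],
        "planted_dual_pct": 100.0
        * float((sim.obs["population"] == "TRANSITIONAL").sum())
        / max(int((~sim.obs["is_doublet"]).sum()), 1),
        "n_cells_final": float(bundle.adata.n_obs),
    }
    if bundle.doublet_scores is not None:
        table = bundle.doublet_scores.table
        truth = sim.obs.loc[table.index, "is_doublet"].to_numpy()
        metrics["doublet_auroc"] = _auroc(table["adjusted"].to_numpy(), truth)
        trans = sim.obs.loc[table.index, "population"].to_numpy() == "TRANSITIONAL"
        metrics["trans_flagged_pct"] = (
            100.0 * float((table["call"].to_numpy() & trans).sum()) / float(trans.sum())
            if trans.any() else float("nan")
        )
    if "population" in obs and "cluster" in obs:
        singlet = (~obs["is_doublet"].to_numpy()) & (obs["population"].to_numpy() != "TRANSITIONAL")
        if singlet.any():
            metrics["identity_ari"] = float(
                adjusted_rand_score(
                    obs.loc[singlet, "population"].to_numpy(), obs.loc[singlet, "cluster"].to_numpy()
                )
            )
    return metrics


def aggregate_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of each metric per (dual_fraction, doublet_rate) grid point."""
    metrics = [c for c in df.columns if c not in ("dual_fraction", "doublet_rate", "seed")]
    agg = df.groupby(["dual_fraction", "doublet_rate"])[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
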