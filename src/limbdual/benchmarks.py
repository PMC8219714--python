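"""Canned benchmark runs used by the validation suite and reporting scripts.

These wrap the pipeline at the study conditions (5,000 singlets, planted dual
fraction 4%, doublet rate 5%) and at a larger scale used for the qualitative
bi-phasic checks, returning ground-truth-based metrics per seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .de_stats import wilcoxon_rank_sum
from .pipeline import PipelineConfig, ResultBundle, run_metrics, run_pipeline
from .simulate import SimConfig, simulate_counts

QUAL_SCALE = 1.6  # cell-count multiplier for the score/DE qualitative checks


def default_metrics(seeds, dual_fraction: float = 0.04) -> pd.DataFrame:
    """Run the default pipeline once per seed; one row of truth-based metrics
    per run."""
    rows = []
    for seed in seeds:
        sim_cfg = SimConfig(seed=int(seed), dual_fraction=dual_fraction)
        cfg = PipelineConfig(sim=sim_cfg, seed=int(seed))
        adata = simulate_counts(sim_cfg)
        bundle = run_pipeline(cfg, adata=adata)
        rows.append({"seed": int(seed), **run_metrics(bundle, adata)})
    return pd.DataFrame(rows)


def qualitative_run(mode: str, seed: int, scale: float = QUAL_SCALE) -> ResultBundle:
    """One pipeline run in the given bi-phasic mode, scaled up so the dual
    population holds a few hundred cells."""
    base = SimConfig()
    pops = {k: int(round(v * scale)) for k, v in base.n_cells_per_population.items()}
    sim_cfg = dataclasses.replace(
        base, n_cells_per_population=pops, biphasic_mode=mode, seed=int(seed)
    )
    return run_pipeline(PipelineConfig(sim=sim_cfg, seed=int(seed)), adata=simulate_counts(sim_cfg))


def score_comparisons(bundle: ResultBundle) -> pd.DataFrame:
    """Group medians and CT_M-vs-group Wilcoxon p for both module scores."""
    obs = bundle.adata.obs
    rows = []
    for score in ("ct_score", "m_score"):
        med = obs.groupby("identity", observed=True)[score].median()
        for group in ("CT", "M"):
            _, p = wilcoxon_rank_sum(
                obs.loc[obs["identity"] == "CT_M", score],
                obs.loc[obs["identity"] == group, score],
            )
            rows.append(
                {
                    "score": score,
                    "versus": group,
                    "median_ctm": float(med["CT_M"]),
                    "median_group": float(med[group]),
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def biphasic_calls(bundle: ResultBundle) -> dict[str, int]:
    """Counts of up/down calls per panel side in the bi-phasic summary."""
    bi = bundle.biphasic
    out = {}
    for side in ("ct", "m"):
        sub = bi[bi["panel"] == side]
        out[f"{side}_down"] = int((sub["call"] == "down").sum())
        out[f"{side}_up"] = int((sub["call"] == "up").sum())
        out[f"{side}_total"] = len(sub)
    return out
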