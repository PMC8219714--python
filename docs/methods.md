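# Methods

This note documents the generative model behind the synthetic limb datasets,
the analysis pipeline's methodological choices and defaults, and what the
validation on synthetic data does and does not establish.

## The synthetic limb model

### Count model

Each cell `c` draws a library size `L_c ~ LogNormal(μ, σ)` with defaults
`μ = ln 5000`, `σ = 0.35` (droplet libraries of a few thousand UMIs with
realistic spread). Gene `g` in cell `c` then draws
`count ~ NB(mean = L_c · r_{g,p(c)}, size = θ)` with dispersion `θ = 2.0`,
giving the heavy-tailed over-dispersion and dropout typical of UMI data.
Rates `r` are expressed as expected counts per unit of library size.

### Gene panel

The default 600-gene panel contains:

| block | genes | rate (per unit library) |
|---|---|---|
| CT markers | PRRX1, TWIST2, PDGFRA, OSR1, SCX | 0.005 in CT cells, 0 elsewhere |
| muscle markers | PAX7, MYF5, MYOD1, MYOG | 0.005 in M cells, 0 elsewhere |
| BMP-readout genes | ID1, ID2, ID3 | 0.0005 everywhere; 0.004 in transitional cells |
| per-population programs | 50 per population | log-spread 0.004–0.036 in the own population |
| mitochondrial | 20 genes, `MT-` prefix | 0.0025 everywhere |
| housekeeping | remainder (~300) | log-spaced grid 0.0002–0.02 |

Two structural choices matter and are deliberate:

- **Abundance continua.** Housekeeping and program rates are log-spread rather
  than constant. Real transcriptomes have a continuum of abundances; if all
  program genes shared one rate they would occupy entire mean-expression bins
  by themselves, which breaks both binned-dispersion HVG selection (the
  population signal standardizes away inside program-only bins) and
  bin-matched control sampling for module scores.
- **Markers below programs.** Marker transcription factors (rate 0.005) sit
  below structural program genes (centre 0.012), as TFs do in real data, so
  markers and programs fall in different expression bins.

A configurable fraction of cells (default 5%) gets its mitochondrial rates
multiplied by 16, producing pMito ≈ 20% against a ≈2% baseline — QC bait that
separates from the 10% cutoff by several NB standard deviations (the reason
for 20 mitochondrial genes: the NB noise of the mito *sum* scales as
`1/sqrt(k·θ)`).

### The transitional (dual) population

Transitional cells interpolate between the CT and M expression states along a
latent pseudotime `u` using two logistic switches of steepness 10:

- muscle **markers** rise early: multiplier `σ(10(u − t_m))`;
- CT markers fall and the CT **program** hands over to the muscle program at a
  later switch: multipliers `1 − σ(10(u − t_ct))` and `σ(10(u − t_ct))`.

"Marker TFs lead, programs follow" encodes the bi-phasic observation that in
the earliest dual cells the myogenic regulators are already up while the CT
state is untouched. Because the program swap is complementary at a single
switch, the library composition of a transitional cell stays close to constant
along the trajectory — avoiding spurious compositional "downregulation" of
unrelated genes under depth normalization.

Modes: `late` uses `(t_m, t_ct) = (0.20, 0.55)` with `u ~ U(0, 1)` (both
switches traversed; dual cells show intermediate states), `early` uses
`(0.10, 0.90)` with `u ~ U(0, 0.5)` (muscle markers emphatically up, CT
markers statistically flat — residual leakage of the late switch is < 2%).
The transitional count is `round(f·N/(1−f))` so transitional cells make up
fraction `f` of singlets.

### Doublets

`inject_doublets` appends `ceil(rate · n_final)` barcodes
(`n_final = n_singlets/(1 − rate)`), each the **raw elementwise sum** of two
distinct uniformly chosen singlets — conserving the elevated library size that
real doublets carry. Population proportions default to CT 30%, M 30% and three
unrelated populations (vessel/nerve/ectoderm-like) at ~13% each; proportions
are illustrative of a whole-limb dissociation, not fitted to any dataset.

## Pipeline stages and defaults

- **QC**: `min_features = 200`, `min_counts = 500`, `max_counts` = 99.5th
  percentile of totals (a percentile rule standing in for manual outlier
  removal on an nFeatures-vs-nCounts scatter), `max_pmito = 0.10`. A
  zero-count cell has pMito defined as 0 and is removed by `min_counts`.
  Applying the *resolved* thresholds again is a no-op; the percentile rule
  itself re-resolves on the filtered data by design.
- **Normalization**: `ln(1 + count/total × s)`, `s` = median of per-cell
  totals. Natural log, pseudocount 1. Zero iff the raw count is zero, strictly
  monotone within a cell.
- **HVG**: variance of normalized values z-scored within 20 equal-frequency
  mean-expression bins; zero-variance genes are never selected; ties resolve
  by raw variance then gene order. Default 150 genes.
- **PCA**: per-gene centre and unit-scale (sd, ddof 1), scaled values capped
  at 10 to stop rare-cell outliers dominating components; deterministic SVD
  with sign fixed by the largest-magnitude loading. Optional covariates are
  regressed out of each gene by least squares before scaling (the generic
  hook for cell-cycle scores; no cycle gene lists are shipped).
- **Clustering**: unweighted union-of-kNN graph (`k = 20`) on PC scores,
  Leiden modularity (RBConfiguration) at resolution 1.0. Cells are processed
  in barcode order internally, making the partition order-invariant.
- **Doublet filter**: `n_sim = 2 × n_obs` synthetic doublets; joint
  log-normalization with the observed median as scale factor; PCA fitted on
  observed cells only, synthetic profiles projected; `k =
  round(0.5·sqrt(n_obs + n_sim))` nearest neighbours; raw score = simulated
  fraction among neighbours; adjusted score = `raw/(1−raw) · n_obs/n_sim`
  (saturated neighbourhoods floor the denominator at 0.5). Calls default to
  the top 5% by adjusted score (the expected doublet rate), ties broken by
  barcode order. The embedding uses **6 PCs**: enough to span the population
  structure; additional components contribute almost pure NB noise, and in a
  Euclidean kNN that noise dilutes the local density of simulated doublets
  precisely around rare intermediate states, inflating their false-flag rate.
  Because depth is removed by the joint normalization, discrimination rests on
  mixed expression alone — deliberately the hard case for separating genuine
  transitional cells from two-cell captures.
- **Dual call**: strictly `value > 0` for ≥1 CT marker and ≥1 muscle marker;
  no other genes consulted. `MYOD` is accepted as an alias of `MYOD1` when
  reading feature tables.
- **Module scores**: genes ranked by mean expression and cut into 25
  equal-frequency bins; for each set gene up to 100 controls are sampled
  (seeded, without replacement) from its bin; score = mean(set) −
  mean(controls). Set genes are always excluded from control pools; the
  pipeline additionally excludes the *whole* marker panel and the probe genes
  from every control pool, because genes that differ between the compared
  populations corrupt the baseline they are supposed to provide. Scores are
  exactly invariant (to float precision) under a global additive shift.
- **Cluster annotation**: a cluster is CT if mean(ct_score) − mean(m_score) >
  margin, M if < −margin, else Other. Margin default 0.5: control sampling
  induces a constant per-score offset of up to a few tenths, while genuine CT
  and muscle clusters separate by 2–3 score units, so the margin must sit
  between those scales.
- **Differential statistics**: Wilcoxon rank-sum with midranks; for
  `min(n1, n2) ≥ 8` a normal approximation with tie-corrected variance and
  0.5 continuity correction, otherwise the exact permutation distribution of
  the rank sum computed by a subset-sum dynamic program over doubled midranks
  (exact for any sample sizes, ties included). Fisher's exact two-sided p sums
  hypergeometric probabilities at most the observed one (relative tie
  tolerance 1e−7). Multiple testing defaults to Benjamini–Hochberg with
  Bonferroni available (`p_adjust`); the DE gene universe defaults to the
  HVGs (`de_gene_universe: all|hvg`). Marker log-fold-changes are
  `ln((mean expm1(in) + 1e−9)/(mean expm1(out) + 1e−9))`; genes are tested when
  expressed in ≥10% of either side and `|log_fc| ≥ 0.25` (marker discovery)
  or with no fold-change gate for the dual-vs-union comparison.
- **Bi-phasic summary**: per CT marker, sign/significance of CT_M vs CT; per
  muscle marker, CT_M vs the combined CT∪M cells. The muscle side is compared
  against the union because dual cells sit *below* pure muscle cells for most
  of the trajectory — against pure M the planted "upregulation" would read as
  down, whereas against the union (half of which are marker-negative CT
  cells) the transit signature reads, correctly, "CT markers down, muscle
  markers up".
- **2^−ΔΔCt**: ΔCt = Ct(target) − mean(Ct of reference genes) per sample;
  ΔΔCt subtracts the mean control-condition ΔCt. The control condition is
  centred at 1 — exactly its geometric mean; the arithmetic mean of control
  relative levels is ≥ 1 whenever control samples vary.
- **Seeds**: one global seed expands into per-stage seeds via
  `SeedSequence([seed, stage_index])`; every stochastic stage (simulation,
  synthetic doublets, kNN/Leiden, control sampling) consumes its own stream.

## Validation design and problem sizes

The validation suite runs the full pipeline on ten simulated datasets at the
study conditions — 5,000 singlet cells, planted dual fraction 4%, doublet rate
5% — plus ten null datasets (no dual cells) and scaled-up (×1.6) late- and
early-mode runs so the dual group holds ≥300 cells for the score and DE
checks. Headline checks: mean recovered dual fraction within ±1.5 percentage
points of 4.0; null recovery ≤1%; doublet-score AUROC ≥ 0.85 with genuine
transitional cells flagged below 20%; strict intermediate median orderings of
both module scores in late mode; and the early-mode asymmetry (muscle markers
up, no systematic CT decline). Statistics engines are checked exhaustively
against independent enumeration oracles (all tie-free rank patterns with
n ≤ 10; all 2×2 tables with N ≤ 40 in exact integer arithmetic).

One caveat on "no change" claims: with hundreds of cells per group, a Wilcoxon
test detects arbitrarily small residual shifts (including the ~1–2% switch
leakage the trajectory model allows), so the early-mode "CT not down" property
is asserted as *no systematic downregulation* (marker call counts and a small
median-gap bound) rather than as a pointwise p > 0.05.

## What the simulator does not emulate

No batch effects or ambient RNA; no UMI collisions or read-level error; no
cell-cycle transcriptional programs (the covariate-regression hook is provided
but unused by default); population expression states are homogeneous apart
from the planted trajectory, so real-data substructure within CT or muscle
clusters is absent; doublet composition is a uniform pair draw, not modelled
on droplet loading. Passing the synthetic validation therefore demonstrates
that the *method* recovers planted structure under realistic count noise — it
does not certify performance on any particular real dataset, where manual QC
choices, resolution selection and annotation judgement re-enter.

## Known limitations

- The quantile-based doublet call needs a sensible expected rate; no automatic
  bimodality thresholding is implemented (future work).
- Expected-doublet-rate estimation from loading statistics is out of scope.
- Cluster annotation by score margin replaces expert marker inspection; for
  unusual panels the margin may need retuning.
- The stage presets (`configs/e4|e6|e10.yaml`) map simulator settings to
  developmental stages illustratively (dual fraction, bi-phasic mode, dataset
  size); they are not fitted to the real stage datasets.
- Dual-identity percentages use all retained cells as denominator; restricting
  the denominator to CT∪M cells would roughly triple the percentages.
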