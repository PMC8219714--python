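# limbdual

Detection and characterisation of rare **dual connective-tissue/myogenic (CT/M)
cells** in single-cell RNA-seq of developing limbs — with a fully ground-truthed
synthetic data generator, so every stage of the analysis can be validated
without downloading anything.

During limb development a small subpopulation of lateral-plate-derived
connective-tissue (CT) fibroblasts converts to a myogenic fate. In whole-limb
scRNA-seq these cells appear as a rare population (≈0.5–4% of cells) that
co-expresses CT markers (*PRRX1*, *TWIST2*, *PDGFRA*, *OSR1*, *SCX*) together
with muscle markers (*PAX7*, *MYF5*, *MYOD1*, *MYOG*). Detecting them reliably
requires ruling out the obvious artifact — two-cell droplets (doublets) that
mix a fibroblast with a myoblast — and showing that the co-expressing cells
carry an *intermediate*, bi-phasic expression state rather than the additive
profile of a doublet.

## What the package does

The library implements the complete analysis as composable stages:

1. **`limbdual.simulate`** — negative-binomial count simulator with log-normal
   library sizes. It plants distinct CT, muscle and unrelated populations, a
   transitional population that interpolates CT→muscle expression along a
   latent pseudotime via two logistic switches, barcode doublets (raw parent
   count sums), and high-mitochondrial cells as QC bait. Ground truth for every
   barcode is carried in the dataset (`truth.tsv`).
2. **`limbdual.preprocess`** — QC on detected genes (nFeatures), total
   molecules (nCounts) and mitochondrial fraction (pMito); log-normalization
   with the median total as scale factor, `value = ln(1 + count/total × s)`;
   highly-variable-gene selection by binned standardized dispersion; PCA on
   centred, unit-scaled (capped) values with an optional covariate-regression
   hook; Leiden community detection on a kNN graph.
3. **`limbdual.doublets`** — a simulated-doublet kNN scorer: synthetic doublets
   are sums of random cell pairs; each observed cell is scored by the fraction
   of simulated profiles among its nearest neighbours in PC space, converted to
   imbalance-corrected odds; calls by top-quantile or fixed threshold.
4. **`limbdual.identity`** — the core classification. A cell is **dual (CT/M)**
   iff it has log-normalized expression > 0 for at least one CT marker *and*
   at least one muscle marker. Clusters are annotated CT/M/Other by their mean
   CT-vs-M module-score gap, and every cell receives exactly one of four
   identities: `CT`, `CT_M`, `M`, `OTHER` (dual cells are `CT_M` regardless of
   cluster). CT and M **module scores** are bin-controlled "corrected average
   expression": mean expression of the marker set minus the mean of control
   genes drawn from matching expression bins.
5. **`limbdual.de_stats`** — self-implemented statistics: Wilcoxon rank-sum
   (exact permutation distribution for small groups; tie-corrected normal
   approximation with continuity correction otherwise), Fisher's exact test,
   Benjamini–Hochberg (and Bonferroni) correction, one-vs-rest marker
   discovery, CT/M-vs-(CT∪M) differential expression with a bi-phasic marker
   summary, expressing-fraction comparisons, and 2^−ΔΔCt qPCR quantification.
6. **`limbdual.pipeline` / `limbdual.cli`** — orchestration
   (QC → doublet removal → normalize → HVG → PCA → cluster → annotate →
   dual call → identity → scores → DE → report), a YAML config with strict key
   checking, per-stage seed derivation, and a parameter-recovery benchmark.

## Worked example

Simulate a mid-stage limb dataset (planted dual fraction 4%, doublet rate 5%)
and run the full pipeline:

```bash
limbdual simulate --config configs/e6.yaml --out e6_data
limbdual run --config configs/e6.yaml --data e6_data --out e6_out
```

The run logs each stage to stderr:

```
stage load         cells=3608 genes=600
stage qc           kept=3402 removed=206
stage doublets     flagged=170 kept=3232
stage normalize    scale_factor=10927.0
stage pca          n_hvg=150 n_pcs=30
stage cluster      n_clusters=6
stage identity     ct=937 ct_m=121 m=942 other=1232
stage de           markers=601 dual_de=124 status=ok
```

and prints the machine-readable summary (abridged):

```json
{
  "identity_percent":   {"CT": 28.99, "CT_M": 3.74, "M": 29.15, "OTHER": 38.12},
  "dual_among_positive": {"MYOG": 11.36, "PAX7": 11.09, "OSR1": 10.38},
  "marker_fraction_in_dual": {"PRRX1": 85.95, "TWIST2": 85.95, "PAX7": 96.69}
}
```

Reading this: 3.74% of retained cells carry the dual CT/M identity (4% was
planted; the gap is doublet removal plus trajectory ends where one marker side
has dropped out), 11.4% of MYOG-expressing cells are dual, and 86% of dual
cells still express *PRRX1* — the qualitative fingerprint of a population in
transit from fibroblast to muscle. `e6_out/` also contains per-cell tables
(identity, CT/M scores, doublet scores), cluster markers, the CT/M-vs-(CT∪M)
DE table and the bi-phasic summary (`biphasic_summary.tsv`), which for this
dataset flags every CT marker *down* and every muscle marker *up* in the dual
cells.

The same pipeline runs on any 10x-style triplet directory
(`matrix.mtx` + `features.tsv` + `barcodes.tsv`); `truth.tsv` is optional and
only used for benchmarking.

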