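# fibrosen

Fibroblast-senescence signature analysis for tumor transcriptomics:
single-cell senescence scoring, cross-dataset signature construction,
bulk-cohort stratification, immunotherapy-response and survival modeling,
and CRISPR immune-screen integration for target nomination.

## The problem

Senescent cancer-associated fibroblasts (CAFs) reshape the tumor
microenvironment and are suspected to blunt the response to immune
checkpoint inhibitors (ICI). `fibrosen` implements the full analysis chain
that turns that hypothesis into testable quantities:

1. **Per-cell senescence scores.** Each cell receives a single-sample
   enrichment score of a senescence gene set, computed with a GSVA-style
   weighted Kolmogorov–Smirnov random walk over gene ranks: genes are
   rank-transformed per gene (`z_ij = ecdf_i(x_ij)`), ordered per cell, and
   the walk statistic `ES = max(0, max ν) + min(0, min ν)` with symmetric
   rank weights `|p/2 − s|` is min-max normalized to [0, 1].
2. **Fibroblast senescence signature (FSS).** Per dataset,
   `FS_x` (genes with Spearman R > 0 and FDR < 0.05 against the senescence
   score within fibroblasts) is intersected with `FS_y` (fibroblast-
   upregulated markers, log2FC > 0.25, min.pct ≥ 0.1, Wilcoxon). A gene
   joins the signature when the geometric mean of its Spearman R across
   supporting datasets exceeds 0.25.
3. **Bulk stratification.** Bulk cohorts are scored with the FSS, split at
   medians into HF/LF × HT/LT subgroups (FSS × tumor mutation burden), and
   immune marker-set abundances are compared across subgroups
   (Mann–Whitney U, BH).
4. **Outcome models.** A gradient-boosting classifier predicts ICI response
   from FSS-gene features (8:2 stratified split, repeated 10-fold CV,
   Mann–Whitney ROC AUC, Kaplan–Meier/log-rank on risk groups). A
   from-scratch multi-task logistic regression (MTLR) survival model with
   differential-expression feature selection produces per-patient survival
   curves and risk scores, evaluated by Harrell's (or Uno's) C-index.
5. **Target nomination.** CRISPR screens are z-scored per dataset,
   aggregated, ranked ascending (most depleted under immune pressure
   first), the top 10% flagged, signature enrichment tested
   (hypergeometric/Fisher), and flagged signature genes intersected with
   the survival model's features to yield hub targets.

Every stage runs on seeded synthetic data with planted ground truth
(`fibrosen.synthdata`), so recovery of known structure is a testable claim.

## Worked example

```python
from fibrosen import PipelineConfig, run_pipeline

config = PipelineConfig(seed=1)
config.stages["ici"] = False       # skip the (slower) response classifier
report = run_pipeline(config, out_dir="demo")

print(report["fss"]["n_members"])               # 39
print(report["bulk"]["cytotoxic_group_means"])  # LFHT 0.562 > LFLT 0.165 > HFHT -0.140 > HFLT -0.593
print(report["mtlr"]["harrell_c"])              # 0.722
print(report["crispr"]["hub_genes"])            # ['G0005', 'G0027', 'G0042', 'G0078', 'G0256', 'G1368']
```

What the numbers mean: from 8 simulated single-cell datasets the pipeline
assembles a 39-gene signature (39 of the 40 planted fibroblast-senescence
genes, no false members). On the simulated bulk cohorts, cytotoxic-marker
abundance across the FSS × TMB subgroups reproduces the expected immune
ordering LFHT > LFLT > HFHT > HFLT — low-senescence/high-TMB tumors are
the most immune-infiltrated, high-senescence/low-TMB the least. The MTLR
risk score reaches a concordance of 0.722 (the true latent burden attains
≈0.72 on the same cohort, so the model is near the attainable ceiling),
and the hub list contains all five genes planted with triple evidence
(signature member + prognostic + screen-depleted), plus one signature gene
flagged by chance.

The same stages are exposed on the command line (`fibrosen simulate`,
`qc`, `score-cells`, `markers`, `build-fss`, `score-bulk`, `stratify`,
`train-ici`, `fit-mtlr`, `rank-crispr`, `run`), reading and writing
MTX/TSV/GMT/JSON.

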