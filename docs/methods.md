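# Methods

`fibrosen` implements an end-to-end analysis that asks whether the
transcriptional senescence state of cancer-associated fibroblasts (CAFs)
carries prognostic and immunotherapy-predictive information, and whether the
genes that define that state can nominate therapeutic targets when combined
with survival modeling and CRISPR immune-screen evidence. Because the
analysis chain is long (single-cell scoring → cross-dataset signature →
bulk stratification → response and survival models → screen integration),
every stage is exercised on synthetic data with planted ground truth; this
note records the models, the defaults, and the reasoning behind the open
design choices.

## Single-sample enrichment score

The per-sample (per-cell or per-bulk-sample) gene-set score is the
GSVA-style weighted Kolmogorov–Smirnov random walk:

1. Gene-level statistic. For gene *i* and sample *j*,
   `z_ij = (1/n) · #{k : x_ik ≤ x_ij}` (empirical CDF; default for
   log-normalized single-cell matrices where it is exact, deterministic, and
   invariant to monotone transforms of any gene), or a Gaussian-kernel CDF
   estimate `z_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i)` with `h_i = sd_i/4`
   (sample sd, ddof = 1; floor 1e-12 for constant genes) for continuous bulk
   profiles.
2. Walk. Per sample, genes are sorted by decreasing `z` (ties broken by
   ascending gene index, for reproducibility) and position `s` receives the
   symmetric rank weight `r = |p/2 − s|`. The walk gains the normalized
   member weight `r^τ / Σ_members r^τ` at member genes and loses
   `1/(p − |set|)` at non-members; the enrichment score is
   `max(0, max walk) + min(0, min walk)` (the "mx.diff"-style combination),
   always in [−1, 1]. Degenerate rule: if every member lands at a zero rank
   weight (possible only at very small p), members are weighted uniformly so
   the walk stays defined; with two genes the score is then exactly ±1.
3. Normalization and grouping. Scores are min-max normalized within the
   scored population ("senescence scores"); constant populations map to 0.5
   with a logged warning. High-/low-senescence groups split at the median,
   ties assigned to the low group (deterministic).

Min-max normalization is per dataset (not pooled across datasets): the
enrichment score's scale depends on the dataset's gene universe, so pooling
would let one platform dominate the group split.

## Synthetic data: what it emulates and what it does not

`SimConfig` defaults define the study conditions; the generators are
seeded and bit-reproducible.

**Single cell.** Eight datasets of 1,500 cells over a 1,500-gene universe
(a highly-variable-gene-scale panel). Cell types are drawn from fixed
proportions (25% fibroblast, 30% malignant, 20% T, 10% B, 10% myeloid, 5%
endothelial). Each cell has a latent senescence state `s_c ∈ [0, 1]`:
Beta(5, 2) in fibroblasts, Beta(2, 5) elsewhere — matching the [0, 1] range
of the min-max-normalized score the pipeline estimates. Counts are negative
binomial with a single global dispersion (0.08) around
`depth · softmax-free expression`, with log-normal depths (median 15,000).
Planted programs, all disjoint: a 50-gene senescence set whose log-mean
rises by γ·s_c (γ = 1) in **all** cells; a 40-gene fibroblast-senescence
program rising by β·s_c (β = 1) in fibroblasts **only**, plus a fibroblast
marker shift; 20 marker genes per cell type (+1.3 log units); 10 `MT-`
genes at a higher baseline (~2% of counts); 15 cytotoxic-effector genes
(used in bulk); 10% of cells at 5% depth to exercise QC. Not emulated:
ambient RNA, doublets, UMI saturation, cancer-type-specific biology —
passing tests therefore demonstrate the pipeline's statistical behavior
under its own model assumptions, not robustness to those artifacts.

**Bulk.** 400 samples in 4 cohorts. A latent senescence burden
`S_i ~ Beta(2, 2)` scales the planted program's expression (slope 2.0 in
log units); cell-type mixing weights (Dirichlet) drive the marker sets;
per-cohort per-gene batch shifts are Normal(0, 0.5); residual noise
Normal(0, 0.5). Survival is exponential with hazard
`h_0 · exp(β_s · S_i)` (`h_0` = 1/1000 days, β_s = 3.0 — an
interquartile hazard ratio of ≈2.5, typical of a strong prognostic index).
Censoring is an independent exponential whose rate is calibrated by
bisection so the expected censored fraction hits the 30% target (for two
independent exponentials the censored probability is `c/(c+h)`, monotone in `c`, so
bisection is exact). Response is Bernoulli with logit dropping by β_r = 3
per **standard deviation** of burden (per-SD rather than per-unit: a
Beta(2, 2) burden spans only ~0.22 SD units, and a per-unit slope of 3
cannot produce a usefully discriminative marker — the true-burden AUC
would be capped near 0.70, whereas the per-SD form yields ≈0.90). TMB is
log-normal and independent of burden. Cytotoxic genes decrease in `S_i`
(−1.0) and increase in standardized log TMB (+0.15); the coefficient ratio
keeps the senescence effect dominant, which is what makes the
LFHT > LFLT > HFHT > HFLT ordering of cytotoxic abundance across the
FSS × TMB subgroups recoverable.

**CRISPR screens.** 17 datasets; per dataset gene logFC ~
Normal(μ_d, σ_d²) with μ_d ~ Normal(0, 0.5) and σ_d ~ Uniform(0.5, 2),
emulating heterogeneous library conditions. Fifteen planted
immune-resistance genes are shifted by −2; five of them are also members
of the planted fibroblast-senescence program and carry a doubled bulk
prognostic slope. These five are the designed "triple-evidence" targets:
signature member, survival-model feature, and screen-depleted — the
end-to-end nomination the hub intersection should recover. Screens are
generated with full gene coverage; the aggregation layer nevertheless
supports missing values and a minimum-support filter.

## Signature construction

Per dataset, after QC (≥500 detected genes, ≤5% mitochondrial counts) and
depth normalization (`log1p(1e4·count/total)`):

* **FS_x**: genes detected in ≥10% of fibroblasts whose expression
  correlates positively with the per-cell senescence score (tie-corrected
  Spearman, two-sided t-approximation p, BH FDR < 0.05 within the
  dataset). The scoring gene set itself is excluded from the candidates:
  members of the set correlate with the score by construction (they
  generate it), and without the exclusion they flood the signature with
  self-fulfilling members. This circularity guard is the package's own
  choice and is the single deliberate departure from a purely
  threshold-based screen.
* **FS_y**: fibroblast-upregulated genes (two-sided Wilcoxon rank-sum,
  log2 fold change > 0.25 on pseudocounted expm1-back-transformed means,
  `max(pct_in, pct_out) ≥ 0.1`, upregulated only, no additional p-value
  cutoff; BH-adjusted p reported for downstream use).
* **FS_n = FS_x ∩ FS_y**, carrying the FS_x correlation.

Across datasets, a gene's geometric mean of its per-dataset Spearman R is
taken **over the datasets whose FS_n contains it**, and membership requires
geometric mean > 0.25 plus support in ≥25% of datasets. Averaging only
over supporting datasets (rather than all) is forced: a geometric mean with
absent-as-zero entries would annihilate every gene; the support floor then
guards against single-dataset flukes.

## Bulk scoring, stratification, response model

Bulk cohorts are standardized gene-wise within each cohort (mean 0, sd 1;
sd-0 genes set to 0) before scoring — a declared, rank-preserving surrogate
for empirical-Bayes batch correction: it adds no bespoke modeling content,
and it preserves everything the downstream rank-based statistics use. FSS scores
use the same enrichment engine in Gaussian-kernel mode. Immune-population
abundance is a marker-mean score over user-supplied GMT panels (panel
curation is data, not method; synthetic panels ship with the generator).
Stratification splits at pooled pan-cohort medians (per-cohort option
exposed): HF/LF on the FSS score, HT/LT on TMB, ties to the low label;
subgroup differences use pairwise two-sided Mann–Whitney U with BH.

The response harness partitions samples 8:2 (training size =
round-half-up(0.8·n); largest-remainder stratified allocation, reproducing
657/164 on 821 samples), trains a gradient-boosting classifier (or a
logistic baseline) on signature-gene features by grid search over repeated
stratified CV (10-fold × 5 repeats by default, config-overridable), and
evaluates by
Mann–Whitney ROC AUC plus Kaplan–Meier/log-rank comparison of predicted
risk groups (lifelines). The other eight learner families of the original
comparison are out of scope; the harness accepts any sklearn-style
estimator.

## MTLR survival model

Feature selection: the cohort's median observed time splits samples into
poor (died before the median) and good (observed at or beyond it) outcomes;
samples censored before the median are excluded as uninformative — the
conservative choice, since their class is unknowable. Per-gene Wilcoxon p-values rank the genes; the 10 smallest-p genes
become features (ties by larger absolute median difference, then gene id).

The time axis uses `m = clamp(ceil(√#events), 2, 30)` boundaries at evenly
spaced event-time quantiles (a standard convention for this model family). Each sample's
outcome is one of `m+1` monotone binary sequences; sequence `s_j` (death in
interval `j+1`) has score `Σ_{k>j} (θ_k·x + b_k)` and softmax probability.
Censored subjects contribute the summed probability of all sequences with
death at or after the censoring interval — including the interval the
censoring time falls in, since death later in that interval is possible.
The objective adds `(C1/2)Σ‖θ_k‖²` and a temporal-smoothness penalty
`(C2/2)Σ‖θ_{k+1}−θ_k‖²` (both default 1.0; the smoothness term stabilizes
small-n grids) and is minimized by L-BFGS with an analytic gradient from
zero initialization — deterministic, with the gradient of the log-partition
reducing to differences of cumulative sequence probabilities. With one
boundary and no censoring the model is exactly a ridge logistic regression
of `I(T ≤ t₁)`, which the tests verify against scikit-learn to 1e-4.

The risk score is `Σ_k (1 − S(t_k))` — the predicted death mass accumulated
over the grid — chosen because it is monotone in predicted risk and its
ordering is grid-independent for proportional models. Concordance: Harrell's C over usable pairs (earlier time is
an event), ties counted one half, verified against exhaustive enumeration
and lifelines; Uno's IPCW variant (weights `Ĝ(t⁻)⁻²` from the censoring
Kaplan–Meier, horizon at the 90th time percentile) is provided as an
option. Begg's and the Gönen–Heller index are out of scope.

## Screen integration

Per dataset, finite logFC values are z-scored (sample sd) to remove
location and scale; a gene's aggregate is the mean z over datasets
measuring it (minimum support 1 by default, as heterogeneous
condition-specific datasets are the norm). Ranking is ascending — the most
negative aggregate ranks first, because depletion under immune pressure
marks knockouts that enhance antitumor immunity; a config flag flips the
direction for fitness-style screens. The top `ceil(0.10·G)` genes are
flagged; signature over-representation among flags uses the hypergeometric
upper tail (identical to one-sided Fisher), and the hub list is the sorted
intersection of flagged signature genes with the survival model's features.

## Numerical and reproducibility choices

* All tie-breaks are pinned (gene index in the walk, gene id in rankings,
  low label at medians) so outputs are bit-stable.
* The pipeline derives one seed per stage from the master seed
  (multiplicative hash + CRC32 of the stage name, below 2³¹), so disabling
  a stage does not shift another stage's stream.
* BH adjustment via `scipy.stats.false_discovery_control`; rank-sum tests
  via `scipy.stats.mannwhitneyu` (exact at tiny tie-free sizes, tie-corrected
  normal approximation otherwise).
* Degenerate inputs fail loudly: all-cells-filtered QC, zero-depth cells,
  constant score vectors, constant-logFC screens, event-free survival data,
  and undefined median splits each raise a named error.

## Test and reporting problem sizes

The regression suite runs most statistics on miniature instances against
brute-force oracles; the recovery checks run the full defaults (8 × 1,500
cells) once per session, a 500-sample cohort for the survival-recovery
check, and 20 independently seeded end-to-end pipeline runs (response-model
stage disabled, as hub nomination does not consume it) for the hub-recovery
rate. `scripts/acceptance.py` recomputes all of these from scratch at the
same sizes.

## Known limitations

* The synthetic generative model is intentionally simple; none of the
  distributional defaults were fit to real data, and recovery rates on real
  cohorts will be lower.
* The signature cutoff (geometric mean > 0.25) interacts with the planted
  effect size; with 40 real datasets of heterogeneous quality the support
  rule, not the cutoff, would likely bind.
* The per-cohort standardization surrogate does not shrink gene-wise
  variances the way empirical-Bayes correction does; with very small
  cohorts it over-corrects.
* The MTLR feature count defaults to 10; no stability selection is
  performed across resamples.
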