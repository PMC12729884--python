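# Methods

This note documents the models and procedures implemented in `oxstrata`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Per-cell gene-set scoring

All scorers operate on log1p-transformed, depth-normalized expression
(each cell scaled to 10,000 total counts; the scale is configurable).

* **Binned-control module score.** Genes are ranked by dataset-average
  expression and cut into 24 equal-count bins; for each set gene, 100
  control genes are drawn (seeded, with replacement) from the *non-set*
  genes of its bin, falling back to all non-set genes if a bin holds only
  set members. The score is the set-mean minus the pooled-control mean.
  Excluding set genes from the control pool keeps the score an unbiased
  contrast even for tiny universes; on a constant matrix it is exactly 0.
* **U-statistic rank score (UCell-style).** Per cell, genes get descending
  average-tie ranks, clamped at `max_rank + 1` (default `max_rank` 1,500 —
  the standard published default; ranks past it are considered noise). The
  clamped Mann–Whitney statistic U′ is normalized by its *attainable*
  maximum `n_s(max_rank+1) − n_s(n_s+1)/2`, so the score spans exactly
  [0, 1]: a set occupying the top ranks scores 1, a fully clamped set 0.
* **Recovery-curve AUC (AUCell-style).** Within the top 5% of each cell's
  ranking (configurable `top_frac`), the step curve of cumulative set genes
  recovered is integrated and normalized by the best achievable curve.
  Ties break deterministically by gene order.
* **Mean-rank score (singscore-style).** The mean ascending rank of set
  genes, affinely mapped so the minimum possible mean rank is 0 and the
  maximum 1.
* **Weighted-KS enrichment (ssGSEA-style).** Genes sorted by descending
  expression; in-set steps weighted by `rank^alpha` (`alpha` 0.25, the
  published default; the top gene carries rank G) normalized to the total
  in-set weight, out-of-set steps by `1/(G − n_s)`; the statistic is the
  integral (sum) of the running sum. Because no within-cell normalization
  bounds this statistic, the column is min-max rescaled across cells so it
  can participate in inverse-variance weighting.

## Composite integration

Weights are computed per (method, set) column: columns are min-max
rescaled, weighted by reciprocal variance, Z-scored, and averaged; the
weighted average is Z-scored again so the composite has mean 0, SD 1.
Variance is measured on the min-max scale *before* Z-scoring (post-Z
variances are all 1 and carry no information). Per-source weights reported
to the user are the marginal sums of column weights over each gene-set
source; this subsumes both a per-method and a per-set reading of
inverse-variance weighting. Constant columns (infinite weight) are dropped
with a warning.

The min-max step makes the composite invariant to positive affine maps of
any scorer's raw output, and the three rank-based scorers are invariant to
any monotone transform of expression — both properties are asserted in the
test suite.

## Stratification

Quartile hinges use linear-interpolation ("type 7") quantiles: this is the
convention under which 64,510 distinct scores split exactly
16,128 / 32,254 / 16,128. Boundary cells exactly at a hinge are DTOX (the
interquartile interval is closed). The mito-threshold sensitivity analysis
re-derives quartiles per filtered subset by default (matching proportional
representation); a fixed-threshold mode is exposed because the alternative
reading is equally defensible.

## Plasticity

Raw plasticity is the per-cell variance of log-normalized expression over
the HVG panel (2,000 genes by default; variance-ranked with deterministic
gene-id tie-breaks). Entropy (natural log, on depth-normalized count
proportions obtained by inverting the log1p) is reported alongside but not
residualized — variance is the statistic of record. Residualization is OLS
on nCount, nFeature and percent.mt plus an intercept; collinear covariates
are dropped by QR rank detection; the residual is Z-scored. Residuals are
orthogonal to the retained design by construction (tested to 1e-6·n).

## Pseudotime

PCA is computed on centered (not variance-scaled) HVG expression: the HVG
panel is already variance-selected, and unit-scaling was found to drown the
dominant stress program in noise-dimension variance. The principal curve
uses the classical projection/smoothing iteration: initialize the
projection index from PC1; smooth each coordinate by a local running mean
(span 0.1 of the cells, 100 nodes); project all cells onto the resulting
polyline; repeat until the mean normalized change drops below 1e-4 or 20
iterations. Terminal segments project without clamping, so cells beyond
the smoothed curve's ends keep distinct ordered positions (on a noiseless
1-D line, pseudotime rank-equals position exactly). Arc length is rescaled
to [0,1] and the direction flipped if LOX cells sit above HOX cells on
average, resolving PC sign ambiguity so the low-stress end maps to 0.

## Pseudobulk and TMM

Donor-level sums are exact integer aggregations (donors ordered lexically).
The CPM filter is strict (`CPM > 1` in ≥ 3 donors) and idempotent. TMM
follows the published trimmed-mean-of-M-values definition: reference =
donor with upper-quartile CPM closest to the mean; genes zero in either
library excluded; double trim of 30% on M and 5% on A by rank; inverse
binomial-variance precision weights; factors rescaled to geometric mean 1.

## Consensus biomarker framework

All fitted transforms are train-only. The batch adjustment is the standard
parametric empirical-Bayes location/scale model: per-gene standardization
by the training grand mean and pooled SD, per-batch mean/variance effects
shrunk toward normal and inverse-gamma priors (moment-matched
hyperparameters, fixed-point iteration to 1e-4), then removed. With a
single batch the transform is the identity. Note that EB shrinkage leaves
a small residual between per-batch means even on training data — that is
the intended bias-variance trade-off; `shrink=False` disables it and
removes observed batch means exactly (the tests verify both behaviors,
the no-shrinkage path against a loop-based oracle).

Selector realizations (the thresholds are implementation decisions):

| id | realization | selection rule |
|----|-------------|----------------|
| rf | random forest, 100 trees, balanced weights | Gini importance above the 95th percentile of importances pooled from 5 shuffled-label refits |
| gbt_a | XGBoost, depth 3, lr 0.1, 100 rounds, `scale_pos_weight` | positive gain |
| gbt_b | gradient boosting, depth 2, lr 0.05, subsample 0.8, balanced sample weights | positive importance |
| l1_logistic | L1 logistic regression, 10-value C path, 3-fold CV | nonzero coefficient at the CV-optimal penalty |
| boruta | shadow-feature test, 50-tree forests, ≤ 25 iterations | binomial p < 0.05 for beating the best shadow feature |
| tree | single decision tree, depth ≤ 5, balanced weights | used in any split |

The repeated CV runs 5 seeded repeats of stratified 10-fold partitions by
default; a gene's fold frequency is its selection rate over all folds.

The permutation null uses an algorithm-agnostic statistic (absolute
point-biserial association of each gene with the label) so one null serves
all selectors. Because genes enter the test standardized, their permuted
statistics are exchangeable across genes, and the null is **pooled** across
genes by default: with G genes and B permutations the attainable p-value
floor is 1/(GB+1) rather than 1/(B+1). This matters: with ~500 candidate
genes and ≤ 1,000 permutations, a per-gene floor of 1/1001 can never reach
BH q < 0.05 for a handful of true markers (q_min ≈ 500/(5·1001) ≈ 0.1), so
an un-pooled null makes the consensus rule vacuous at this scale. The
per-gene formula remains available (`pool=False`) and is tested against its
boundary cases.

Held-out evaluation is per-gene Mann–Whitney AUC with midrank tie handling
and DeLong variance for the 95% CI and the two-sided test against 0.5.

## The synthetic-data generator

The single-cell generator emulates the statistical skeleton the analysis
assumes, not cardiac biology: gamma-Poisson (negative binomial) counts with
lognormal gene baselines (log-mean log 0.4, log-SD 1.0) and lognormal
gene-wise dispersions (median 0.4); ~20 donors / 29 samples (every donor
guaranteed a sample, the rest assigned uniformly); N(0, 0.15) donor-by-gene
log-scale batch effects; a lognormal (log-SD 0.5) right-skewed per-cell
latent stress, amplified 1.5× in case-condition cells; and the five
oxidative-stress gene sets (sizes 23/18/17/16/16, 25% shared core) whose
union forms the planted stress program (+1 log2 per latent unit by
default). Two structural choices deserve emphasis:

* **Library size is technical.** Each cell's expected counts are rescaled
  to its lognormal (log-SD 0.3) depth factor times the baseline total, so
  biological state changes composition rather than sequencing depth — as
  in UMI data, where depth is a property of the assay.
* **The stress response is transcriptome-wide.** Besides the ~80-gene core
  program, 30% of genes respond weakly (N(0, 0.5) log-effects per latent
  unit, random sign). A stress response confined to 80 of 2,000 genes puts
  the stress axis far below realistic leading-PC variance shares; the
  diffuse component gives PC1 a realistic relationship to the program, as
  observed in the real cohorts this generator emulates.

Optional modes: `biphasic=True` replaces the i.i.d. latent with a U-shaped
function of a uniform latent time (dip at t = 0.35) plus a 100-gene
trajectory program linear in time, supporting the falling-then-rising
stress-profile analysis; `plasticity_link > 0` scales per-cell, per-gene
lognormal noise with the stress latent, planting the high-stress →
high-plasticity gradient. Both default to off: the default dataset
isolates the stress program itself. Doublets (0.61% of cells by default)
are sums of two random parent cells; mito% is gamma-distributed
(mean 10, SD 5, percent units) independent of stress, which makes the
mito-threshold sensitivity property hold by construction. The bulk
generator plants additive standardized effects (d = 1.5 by default) on 5
marker genes among 500 noise genes, N(0, 0.5) batch-by-gene shifts over 6
round-robin batches, and an exact round(0.5833 · 120) = 70-case design.

**What passing tests show** — that the implemented statistics recover
planted structure of the stated effect sizes under negative-binomial noise,
batch effects and technical covariates, with correct error control on null
data. **What they do not show** — performance under real-data features the
generator omits: ambient RNA, UMI saturation, cell-type-specific programs
correlated with stress, donor-level confounding of condition, non-additive
batch effects, or annotation error.

## Problem sizes

Default analyses run at 5,000 cells × 2,000 genes (single-cell) and 120
samples × 505 genes (bulk). The heavy framework properties use reduced
cross-validation settings chosen to keep a laptop-scale run comfortable:
the 20-trial type-I control runs 1 repeat × 5 folds with 200 permutations;
the planted-marker recovery run uses 2 repeats × 5 folds. The package
defaults remain 5 repeats × 10 folds and 1,000 permutations.

## Known limitations

* The principal curve is a stiff, local-averaging implementation; on data
  whose leading PCs are mostly noise it inherits the classical tendency of
  projection/smoothing iterations to drift, and the iteration cap is part
  of the regularization.
* The EB batch adjustment assumes roughly normal per-gene intensities, as
  the parametric priors do; heavy-tailed platforms would need the
  non-parametric variant, which is not implemented.
* The consensus rule's fold-frequency criterion uses an any-of reading
  across qualifying algorithms; an all-of reading would be stricter.
* Scorer defaults (max_rank 1,500, top_frac 0.05, alpha 0.25, 24 bins /
  100 controls) follow published conventions rather than data-driven
  tuning.
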