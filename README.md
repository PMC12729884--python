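# oxstrata

Oxidative-stress stratification of post-infarction cardiomyocytes: composite
gene-set scoring, quartile cell-state strata, principal-curve pseudotime, and
consensus biomarker selection — with a synthetic-data generator so the whole
pipeline is testable end to end without external cohorts.

## The problem

After acute myocardial infarction (AMI), cardiomyocytes do not experience
oxidative stress uniformly: a high-stress subpopulation shows paradoxically
elevated transcriptional plasticity and sits at the endpoint of a stress
trajectory. Resolving that heterogeneity requires (i) a robust per-cell
oxidative-stress score, (ii) a principled stratification into cell states,
(iii) trajectory and plasticity statistics, and (iv) a validated bulk-cohort
biomarker panel. `oxstrata` implements that full analysis for researchers
working with single-cell and bulk cardiac transcriptomics.

## The model

**Composite score.** For each cell *c*, five scoring algorithms (binned-
control module average, UCell-style U-statistic rank score, AUCell-style
recovery-curve AUC, singscore-style mean-rank score, and a single-sample
weighted-KS enrichment) are applied to five curated oxidative-stress gene
sets (sizes 23/18/17/16/16). Each (method, set) column *s<sub>j</sub>* is
min-max rescaled, and the composite is the inverse-variance weighted average
of the Z-scored columns,

&nbsp;&nbsp;&nbsp;&nbsp;w<sub>j</sub> ∝ 1 / Var(s̃<sub>j</sub>),&nbsp;&nbsp;
S<sub>c</sub> = Z( Σ<sub>j</sub> w<sub>j</sub> · z<sub>j,c</sub> ),

so more stable scorers carry more weight. Four alternative composites
(Simple_Avg, ZScore_Avg, Weighted_Avg, Rank_Avg) and their Pearson
concordance matrix quantify robustness of the integration.

**Strata.** Cells are partitioned by type-7 (linear-interpolation) quartiles
of S: LOX (S < Q1), DTOX (Q1 ≤ S ≤ Q3), HOX (S > Q3). On *n* distinct
scores this yields an exact ⌊n/4⌋ / rest / ⌊n/4⌋ split.

**Plasticity and pseudotime.** Per-cell plasticity is the variance of
log-normalized expression over 2,000 highly variable genes, OLS-residualized
against nCount, nFeature and percent.mt and Z-scored; Shannon entropy is
reported alongside. Pseudotime is arc-length position along a principal
curve (Hastie–Stuetzle projection/smoothing iteration, initialized from
PC1) in the top-10 PC space of the HVGs, rescaled to [0,1] and rooted at
the LOX centroid.

**Pseudobulk.** Donor-level raw-count sums, a CPM > 1 in ≥ 3 donors filter,
and TMM normalization factors (double-trimmed, precision-weighted mean of
M-values; geometric mean 1) prepare inputs for count-based differential
testing.

**Consensus biomarkers.** On a bulk cohort (120 samples, 6 batches, 58.3%
case prevalence), a leakage-safe pipeline — stratified 84/36 split,
parametric empirical-Bayes batch adjustment and per-gene Z-scaling fitted on
training data only — feeds repeated stratified cross-validation over six
feature selectors (random forest with a shuffled-label importance null, two
gradient-boosted-tree configurations, L1 logistic regression, a
Boruta-style shadow-feature test, and a decision tree). A gene enters the
consensus panel if ≥ 4 of 6 algorithms select it, at least one does so in
> 50% of folds, and its label-permutation BH q-value is < 0.05. Panel genes
are evaluated on the held-out split by Mann–Whitney AUC with DeLong
confidence intervals.

## Worked example

```python
import oxstrata as ox

model = ox.OxidativeStressModel.from_synthetic(seed=7, n_cells=2000, n_genes=800)
results = model.fit(seed=7)
print(results.summary())
```

```
Oxidative-stress stratification results
=======================================================
Cells retained after QC: 1,912 (of 2,000; doublet rate 0.60%)

Composite score weights by gene-set source (%):
  KEGG        21.47
  HALLMARK    20.47
  REACTOME    20.36
  WP          20.10
  GOBP        17.60
Alternative-composite concordance (Pearson r): 0.9921-0.9998

Quartile thresholds (type 7): Q1 = -0.751, Q3 = 0.681
Strata: LOX = 478, DTOX = 956, HOX = 478

Trajectory: Spearman(PC1, composite) = 0.651
Plasticity ordering (one-sided rank-sum):
  HOX > DTOX: diff = +0.242, p = 5.36e-19
  HOX > LOX: diff = +0.446, p = 2.1e-27
  DTOX > LOX: diff = +0.204, p = 1.29e-07
```

Reading the output: 88 of 2,000 simulated cells fail QC (mito ≥ 20% or
flagged doublets, itemized separately); the five gene-set sources receive
near-equal inverse-variance weight on this synthetic cohort; quartiles of
the Z-scored composite split the cells 478/956/478; PC1 of the
highly-variable genes tracks the composite (ρ = 0.65); and — because this
dataset was generated without the stress-plasticity link — you can regenerate
with `SCSimConfig(plasticity_link=0.3, ...)` to plant and then detect the
HOX > DTOX > LOX plasticity ordering shown here.

The bulk half works the same way:

```python
cohort = ox.generate_bulk(ox.BulkSimConfig(seed=1))   # 70 cases / 50 controls
model = ox.ConsensusBiomarkerModel(cohort, split=ox.SplitSpec(84, 36),
                                   n_repeats=2, n_folds=5, n_perm=200)
print(model.fit(seed=123).summary())
# -> consensus = exactly the 5 planted marker genes, held-out AUCs 0.85-0.97
```

A thin CLI mirrors the library: `oxstrata simulate-sc`, `simulate-bulk`,
`qc`, `score`, `select` (see `oxstrata --help`).

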