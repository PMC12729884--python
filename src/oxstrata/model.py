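"""Model/Results front-ends tying the pipeline stages together.

Two fitted-model objects cover the two halves of the analysis:

* :class:`OxidativeStressModel` — single-cell half: QC filtering, five-
  method gene-set scoring, inverse-variance composite, quartile LOX/DTOX/
  HOX stratification, plasticity scoring, and principal-curve pseudotime.
* :class:`ConsensusBiomarkerModel` — bulk half: leakage-safe preprocessing
  and the six-algorithm consensus biomarker selection with held-out ROC
  evaluation.

Both follow the familiar pattern: construct from data, call ``fit()``, and
inspect the returned Results object (``summary()`` prints a report).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from . import consensus as cns
from .genesets import GeneSetCollection
from .qc import QCReport, QCThresholds, filter_mito, tally_cells
from .scoring import (
    METHODS,
    CompositeScores,
    NormalizedExpression,
    alternative_composites,
    compute_score_matrix,
    normalize_expression,
)
from .simulate import SyntheticBulkCohort, default_sc_dataset
from .stratify import StratumAssignment, assign_strata, mito_sensitivity, quantile_thresholds
from .trajectory import (
    HVGSet,
    PlasticityScores,
    TrajectoryResult,
    fit_trajectory,
    plasticity_ordering_test,
    plasticity_raw,
    residualize,
    select_hvgs,
    stress_along_pseudotime,
)


@dataclass
class OxidativeStressResults:
    """Fitted single-cell stratification results."""

    adata: AnnData
    expr: NormalizedExpression
    qc_report: QCReport
    tally: pd.DataFrame
    score_matrix: pd.DataFrame
    composites: CompositeScores
    strata: StratumAssignment
    hvgs: HVGSet
    plasticity: PlasticityScores
    trajectory: TrajectoryResult

    @property
    def composite(self) -> pd.Series:
        return self.composites.composite

    def stress_profile(self, n_bins: int = 20) -> pd.DataFrame:
        return stress_along_pseudotime(
            self.trajectory.pseudotime, self.composite, n_bins=n_bins
        )

    def plasticity_tests(self) -> pd.DataFrame:
        return plasticity_ordering_test(self.plasticity.z, self.strata)

    def sensitivity(self, recompute_quartiles: bool = True) -> pd.DataFrame:
        return mito_sensitivity(
            self.adata, self.composite, recompute_quartiles=recompute_quartiles
        )

    def cell_table(self) -> pd.DataFrame:
        """Per-cell table of scores, stratum, plasticity and pseudotime."""
        return pd.DataFrame(
            {
                "composite": self.composite,
                "stratum": self.strata.labels,
                "plasticity_z": self.plasticity.z,
                "entropy": self.plasticity.entropy,
                "pseudotime": self.trajectory.pseudotime,
                "PC1": self.trajectory.pcs["PC1"],
            }
        )

    def summary(self) -> str:
        thr = self.strata.thresholds
        w = self.composites.weights.summary_percent()
        conc = self.composites.concordance.to_numpy()
        off = conc[~np.eye(conc.shape[0], dtype=bool)]
        tests = self.plasticity_tests()
        lines = [
            "Oxidative-stress stratification results",
            "=" * 55,
            f"Cells retained after QC: {self.qc_report.n_retained:,} "
            f"(of {self.qc_report.n_input:,}; doublet rate "
            f"{self.qc_report.doublet_rate:.2f}%)",
            "",
            "Composite score weights by gene-set source (%):",
            *(f"  {src:<10s} {val:6.2f}" for src, val in w.items()),
            f"Alternative-composite concordance (Pearson r): "
            f"{off.min():.4f}-{off.max():.4f}",
            "",
            f"Quartile thresholds (type 7): Q1 = {thr.q1:.3f}, Q3 = {thr.q3:.3f}",
            "Strata: "
            + ", ".join(
                f"{s} = {self.strata.counts[s]:,}" for s in ("LOX", "DTOX", "HOX")
            ),
            "",
            f"Trajectory: Spearman(PC1, composite) = "
            f"{self.trajectory.pc1_score_rho:.3f}",
            "Plasticity ordering (one-sided rank-sum):",
            *(
                f"  {r.higher} > {r.lower}: diff = {r.mean_diff:+.3f}, "
                f"p = {r.p_value:.3g}"
                for r in tests.itertuples()
            ),
        ]
        return "\n".join(lines)


class OxidativeStressModel:
    """Single-cell oxidative-stress stratification model.

    Parameters
    ----------
    adata
        Cells x genes raw counts with per-cell metadata (donor, sample,
        condition, percent_mt, n_count, n_feature, cell_type).
    gene_sets
        Oxidative-stress gene-set collection (GMT-backed).
    qc_thresholds
        Mito/count/feature cutoffs applied before scoring.
    n_hvgs
        Size of the highly-variable-gene panel for plasticity/pseudotime.
    methods
        Scoring algorithms to include (default: all five).
    """

    def __init__(
        self,
        adata: AnnData,
        gene_sets: GeneSetCollection,
        qc_thresholds: QCThresholds | None = None,
        n_hvgs: int = 2000,
        methods: tuple[str, ...] = METHODS,
        drop_doublets: bool = True,
    ):
        self.adata = adata
        self.gene_sets = gene_sets
        self.qc_thresholds = qc_thresholds or QCThresholds()
        self.n_hvgs = n_hvgs
        self.methods = methods
        self.drop_doublets = drop_doublets

    @classmethod
    def from_synthetic(cls, seed: int = 42, n_cells: int = 5000,
                       n_genes: int = 2000, stress_effect: float = 1.0,
                       biphasic: bool = False, **kwargs) -> "OxidativeStressModel":
        """Build the model on the default synthetic cardiomyocyte dataset."""
        dataset, sets = default_sc_dataset(
            seed=seed, n_cells=n_cells, n_genes=n_genes,
            stress_effect=stress_effect, biphasic=biphasic,
        )
        return cls(dataset.adata, sets, **kwargs)

    def fit(self, seed: int = 0) -> OxidativeStressResults:
        adata, qc_report = filter_mito(
            self.adata, self.qc_thresholds, drop_doublets=self.drop_doublets
        )
        expr = normalize_expression(adata)
        sets = self.gene_sets.restrict(expr.genes)
        scores = compute_score_matrix(expr, sets, methods=self.methods, seed=seed)
        composites = alternative_composites(scores, sources=sets.sources)
        thresholds = quantile_thresholds(composites.composite.to_numpy())
        strata = assign_strata(composites.composite, thresholds)
        hvgs = select_hvgs(expr, n=self.n_hvgs)
        raw, entropy = plasticity_raw(expr, hvgs)
        plasticity = residualize(
            raw, adata.obs[["n_count", "n_feature", "percent_mt"]], entropy
        )
        traj = fit_trajectory(
            expr, hvgs, strata, composites.composite, seed=seed
        )
        return OxidativeStressResults(
            adata=adata,
            expr=expr,
            qc_report=qc_report,
            tally=tally_cells(adata),
            score_matrix=scores,
            composites=composites,
            strata=strata,
            hvgs=hvgs,
            plasticity=plasticity,
            trajectory=traj,
        )


# ---------------------------------------------------------------------------
# bulk consensus model
# ---------------------------------------------------------------------------

@dataclass
class ConsensusBiomarkerResults:
    """Fitted consensus-selection results with held-out evaluation."""

    train_ids: pd.Index
    test_ids: pd.Index
    batch_model: cns.BatchAdjustModel
    scaler: cns.ScalerModel
    selector_results: dict[str, cns.SelectorResult]
    permutation: pd.DataFrame
    report: cns.ConsensusReport
    roc: pd.DataFrame

    @property
    def consensus(self) -> list[str]:
        return self.report.consensus

    def summary(self) -> str:
        sizes = self.report.selected_sizes()
        lines = [
            "Consensus biomarker selection results",
            "=" * 55,
            f"Training samples: {len(self.train_ids)}; "
            f"held-out test samples: {len(self.test_ids)}",
            "Genes selected per algorithm (any fold): "
            + ", ".join(f"{a}={n}" for a, n in sizes.items()),
            f"Consensus genes ({len(self.consensus)}): "
            + (", ".join(self.consensus) if self.consensus else "none"),
        ]
        if len(self.roc):
            lines.append("Held-out AUCs:")
            for g, row in self.roc.iterrows():
                lines.append(
                    f"  {g}: AUC = {row.auc:.3f} "
                    f"[{row.ci_low:.3f}, {row.ci_high:.3f}], p = {row.p_value:.3g}"
                )
        return "\n".join(lines)


class ConsensusBiomarkerModel:
    """Six-algorithm consensus biomarker selection on a bulk cohort.

    The fitted pipeline is leakage-safe: the batch-adjustment and scaling
    parameters and every selector see training data only; the test set is
    used solely for the final per-gene ROC evaluation.
    """

    def __init__(
        self,
        cohort: SyntheticBulkCohort,
        split: cns.SplitSpec | None = None,
        n_repeats: int = 5,
        n_folds: int = 10,
        n_perm: int = 1000,
        shrink: bool = True,
    ):
        self.cohort = cohort
        n = len(cohort.expr)
        self.split = split or cns.SplitSpec(
            n_train=int(round(0.7 * n)), n_test=n - int(round(0.7 * n))
        )
        self.n_repeats = n_repeats
        self.n_folds = n_folds
        self.n_perm = n_perm
        self.shrink = shrink

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "ConsensusBiomarkerModel":
        """Build from a sample x (batch, label, genes...) table."""
        batch = frame["batch"].astype(int)
        label = frame["label"].astype(str)
        expr = frame.drop(columns=["batch", "label"]).astype(float)
        cohort = SyntheticBulkCohort(expr=expr, batch=batch, label=label, truth={})
        return cls(cohort, **kwargs)

    def fit(self, seed: int = 123) -> ConsensusBiomarkerResults:
        cohort = self.cohort
        spec = cns.SplitSpec(
            n_train=self.split.n_train, n_test=self.split.n_test, seed=seed
        )
        train_ids, test_ids = cns.stratified_split(cohort, spec)
        X_train = cohort.expr.loc[train_ids]
        X_test = cohort.expr.loc[test_ids]
        y = pd.Series(cohort.y, index=cohort.expr.index)
        y_train = y.loc[train_ids].to_numpy()
        y_test = y.loc[test_ids].to_numpy()

        adj_train, adj_test, batch_model = cns.fit_apply_batch_adjust(
            X_train, X_test, cohort.batch, shrink=self.shrink
        )
        z_train, z_test, scaler = cns.fit_apply_zscore(adj_train, adj_test)

        selector_results = cns.nested_cv_select(
            z_train, y_train, n_repeats=self.n_repeats, n_folds=self.n_folds,
            seed=seed,
        )
        perm = cns.permutation_null(z_train, y_train, n_perm=self.n_perm,
                                    seed=seed)
        report = cns.consensus_genes(selector_results, perm)
        roc = cns.evaluate_auc(z_test, y_test, report.consensus)
        return ConsensusBiomarkerResults(
            train_ids=train_ids,
            test_ids=test_ids,
            batch_model=batch_model,
            scaler=scaler,
            selector_results=selector_results,
            permutation=perm,
            report=report,
            roc=roc,
        )
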