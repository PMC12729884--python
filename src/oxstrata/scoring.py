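"""Per-cell gene-set scoring by five algorithms and the composite score.

Five scorers over each gene set:

* ``module_avg`` — binned-control module score: set-mean expression minus the
  mean of control genes drawn from matching average-expression bins.
* ``ucell`` — Mann-Whitney U rank score with a maximum-rank clamp, in [0,1].
* ``aucell`` — area under the gene-recovery step curve within the top
  fraction of each cell's ranking, in [0,1].
* ``singscore`` — mean rank of set genes rescaled by its attainable range,
  in [0,1].
* ``ssgsea`` — single-sample weighted Kolmogorov-Smirnov running-sum
  statistic (integral form), min-max rescaled across cells.

The composite integrates every (method, set) column by inverse-variance
weighting: columns are min-max rescaled, weighted by the reciprocal of their
rescaled variance, Z-scored, averaged, and the weighted average Z-scored
again.  Four alternative composites (Simple_Avg, ZScore_Avg, Weighted_Avg,
Rank_Avg) and their Pearson concordance matrix quantify the robustness of
the integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import rankdata

from ._utils import fractional_ranks, minmax, zscore
from .exceptions import DegenerateDataError, EmptyGeneSetError, InvalidConfigError
from .genesets import GeneSetCollection

METHODS = ("module_avg", "ucell", "aucell", "ssgsea", "singscore")


@dataclass
class NormalizedExpression:
    """Log1p depth-normalized expression, cells x genes (dense)."""

    X: np.ndarray
    genes: pd.Index
    cells: pd.Index
    scale: float = 1e4

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def gene_indices(self, gene_set: list[str], context: str = "") -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        present = [g for g in gene_set if g in lookup]
        absent = len(gene_set) - len(present)
        if absent:
            warnings.warn(f"{absent} gene(s) absent from matrix {context}".strip())
        if not present:
            raise EmptyGeneSetError(f"gene set empty after intersection {context}")
        return np.array([lookup[g] for g in present])


def normalize_expression(adata: AnnData, scale: float = 1e4) -> NormalizedExpression:
    """Depth-normalize each cell to ``scale`` total counts, then log1p."""
    X = adata.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    X = X.astype(float)
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cell(s); left as zero vectors")
    safe = np.where(zero, 1.0, totals)
    return NormalizedExpression(
        X=np.log1p(X / safe[:, None] * scale),
        genes=pd.Index(adata.var_names),
        cells=pd.Index(adata.obs_names),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# individual scorers
# ---------------------------------------------------------------------------

def score_module_avg(
    expr: NormalizedExpression,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control module score.

    Genes are binned into ``n_bins`` equal-count bins of dataset-average
    expression; for each set gene, ``n_ctrl`` control genes are drawn (with
    replacement, seeded) from its bin.  The score is the set mean minus the
    pooled control mean, per cell.
    """
    idx = expr.gene_indices(gene_set, "(module_avg)")
    rng = np.random.default_rng(seed)
    data_avg = expr.X.mean(axis=0)
    n_bins_eff = min(n_bins, expr.n_genes)
    # equal-count binning on the average-expression ranking; control
    # candidates are the non-set genes of each set gene's bin (falling back
    # to all non-set genes when a bin holds only set genes)
    order_rank = rankdata(data_avg, method="ordinal") - 1
    bins = (order_rank * n_bins_eff // expr.n_genes).astype(int)
    in_set = np.zeros(expr.n_genes, dtype=bool)
    in_set[idx] = True
    members: dict[int, np.ndarray] = {
        b: np.where((bins == b) & ~in_set)[0] for b in np.unique(bins)
    }
    fallback = np.where(~in_set)[0]
    if fallback.size == 0:
        raise DegenerateDataError("no control genes outside the set")
    ctrl_pool = np.concatenate(
        [
            rng.choice(
                members[bins[g]] if members[bins[g]].size else fallback,
                size=n_ctrl, replace=True,
            )
            for g in idx
        ]
    )
    return expr.X[:, idx].mean(axis=1) - expr.X[:, ctrl_pool].mean(axis=1)


def score_ucell(
    expr: NormalizedExpression, gene_set: list[str], max_rank: int = 1500
) -> np.ndarray:
    """U-statistic rank score in [0,1].

    Genes are ranked per cell in descending expression (average ties); ranks
    beyond ``max_rank`` are clamped to ``max_rank + 1``.  The clamped
    Mann-Whitney statistic U' is normalized by its attainable maximum so a
    set occupying the top ranks scores 1 and a fully clamped set scores 0.
    """
    idx = expr.gene_indices(gene_set, "(ucell)")
    n_s = idx.size
    if n_s > max_rank:
        raise InvalidConfigError(f"set size {n_s} exceeds max_rank {max_rank}")
    ranks = rankdata(-expr.X, axis=1)
    ranks = np.minimum(ranks, max_rank + 1)
    u = ranks[:, idx].sum(axis=1) - n_s * (n_s + 1) / 2.0
    u_max = n_s * (max_rank + 1) - n_s * (n_s + 1) / 2.0
    return 1.0 - u / u_max


def score_aucell(
    expr: NormalizedExpression, gene_set: list[str], top_frac: float = 0.05
) -> np.ndarray:
    """Recovery-curve AUC within the top ``top_frac`` of each cell's ranking.

    A set gene at (1-based) position p <= W of the descending ordering
    contributes W - p + 1 to the step-curve integral; the score is the
    integral normalized by its maximum (all set genes packed at the top).
    Ties are broken deterministically by gene order.
    """
    idx = expr.gene_indices(gene_set, "(aucell)")
    n_genes = expr.n_genes
    window = int(np.ceil(top_frac * n_genes))
    if window < 1:
        raise InvalidConfigError("top window smaller than 1 gene")
    order = np.argsort(-expr.X, axis=1, kind="stable")
    positions = np.empty_like(order)
    np.put_along_axis(
        positions, order, np.arange(1, n_genes + 1)[None, :].repeat(len(order), 0),
        axis=1,
    )
    pos_set = positions[:, idx].astype(float)
    contrib = np.clip(window - pos_set + 1.0, 0.0, None)
    auc = contrib.sum(axis=1)
    x = np.arange(1, window + 1)
    max_auc = np.minimum(x, idx.size).sum()
    return auc / max_auc


def score_singscore(expr: NormalizedExpression, gene_set: list[str]) -> np.ndarray:
    """Mean-rank score rescaled to [0,1] by the attainable rank range."""
    idx = expr.gene_indices(gene_set, "(singscore)")
    n_s, G = idx.size, expr.n_genes
    if n_s == G:
        raise DegenerateDataError("set equals the full gene universe")
    ranks = rankdata(expr.X, axis=1)  # ascending: highest expression = rank G
    mean_rank = ranks[:, idx].mean(axis=1)
    lo = (n_s + 1) / 2.0
    return (mean_rank - lo) / (G - n_s)


def score_ssgsea(
    expr: NormalizedExpression, gene_set: list[str], alpha: float = 0.25
) -> np.ndarray:
    """Weighted KS running-sum enrichment (integral form), min-max rescaled.

    Genes are ordered per cell by descending expression (deterministic
    tie-break); in-set steps carry weight rank^alpha where the top gene has
    rank G, normalized to the total in-set weight; out-of-set steps are
    1/(G - n_s).  The per-cell statistic is the sum of the running-sum
    values; the column is min-max rescaled across cells to [0,1].
    """
    idx = expr.gene_indices(gene_set, "(ssgsea)")
    n_s, G = idx.size, expr.n_genes
    if n_s >= G:
        raise DegenerateDataError("set complement is empty")
    order = np.argsort(-expr.X, axis=1, kind="stable")
    in_set = np.zeros(G, dtype=bool)
    in_set[idx] = True
    sorted_in = in_set[order]
    w = (G - np.arange(G)).astype(float) ** alpha  # weight at each position
    w_in = sorted_in * w[None, :]
    w_tot = w_in.sum(axis=1, keepdims=True)
    steps = w_in / w_tot - (~sorted_in) / (G - n_s)
    walk = np.cumsum(steps, axis=1)
    return minmax(walk.sum(axis=1))


_SCORERS = {
    "module_avg": score_module_avg,
    "ucell": score_ucell,
    "aucell": score_aucell,
    "ssgsea": score_ssgsea,
    "singscore": score_singscore,
}


def compute_score_matrix(
    expr: NormalizedExpression,
    gene_sets: GeneSetCollection,
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
    **params,
) -> pd.DataFrame:
    """Score every (method, gene set) pair; cells x MultiIndex columns."""
    unknown = set(methods) - set(_SCORERS)
    if unknown:
        raise InvalidConfigError(f"unknown scoring methods: {sorted(unknown)}")
    cols = {}
    for method in methods:
        fn = _SCORERS[method]
        for name, genes in gene_sets:
            kwargs = dict(params.get(method, {}))
            if method == "module_avg":
                kwargs.setdefault("seed", seed)
            cols[(method, name)] = fn(expr, genes, **kwargs)
    out = pd.DataFrame(cols, index=expr.cells)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["method", "set"])
    return out


# ---------------------------------------------------------------------------
# composite integration
# ---------------------------------------------------------------------------

@dataclass
class WeightVector:
    """Inverse-variance weights per (method, set) column and per set source."""

    per_column: pd.Series
    per_source: pd.Series

    def summary_percent(self) -> pd.Series:
        """Per-source marginal weights as percentages, largest first."""
        return (100.0 * self.per_source).sort_values(ascending=False).round(2)


@dataclass
class CompositeScores:
    composite: pd.Series              # Z-scored inverse-variance composite
    alternatives: pd.DataFrame        # Simple_Avg / ZScore_Avg / Weighted_Avg / Rank_Avg
    concordance: pd.DataFrame         # 4x4 Pearson matrix
    weights: WeightVector


def inverse_variance_weights(variances: pd.Series) -> pd.Series:
    """Normalize reciprocal variances to sum 1 (variances 1 and 4 -> .8/.2)."""
    w = 1.0 / variances
    return w / w.sum()


def _prepare_columns(scores: pd.DataFrame):
    if scores.shape[1] < 2:
        raise DegenerateDataError("need at least two score columns")
    M = scores.apply(lambda c: pd.Series(minmax(c.to_numpy()), index=scores.index))
    variances = M.var(axis=0, ddof=0)
    constant = variances == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant score column(s) "
            "(infinite inverse-variance weight)"
        )
        M = M.loc[:, ~constant]
        variances = variances[~constant]
        if M.shape[1] < 2:
            raise DegenerateDataError("fewer than two non-constant score columns")
    Z = M.apply(lambda c: pd.Series(zscore(c.to_numpy()), index=M.index))
    return M, Z, variances


def integrate_composite(
    scores: pd.DataFrame, sources: dict[str, str] | None = None
) -> tuple[WeightVector, pd.Series]:
    """Inverse-variance composite of score columns.

    Columns are min-max rescaled; weights are proportional to the reciprocal
    of the rescaled variance (computed before Z-scoring, where variances are
    informative); the composite is the weighted average of the Z-scored
    columns, itself Z-scored.  Per-source marginal weights sum the column
    weights of each set source.
    """
    M, Z, variances = _prepare_columns(scores)
    w = inverse_variance_weights(variances)
    composite = pd.Series(
        zscore((Z * w).sum(axis=1).to_numpy()), index=scores.index, name="composite"
    )
    if sources and isinstance(M.columns, pd.MultiIndex):
        src = pd.Series(
            [sources.get(s, "unknown") for _, s in M.columns], index=M.columns
        )
        per_source = w.groupby(src).sum()
    else:
        per_source = w.copy()
    return WeightVector(per_column=w, per_source=per_source), composite


def alternative_composites(
    scores: pd.DataFrame, sources: dict[str, str] | None = None
) -> CompositeScores:
    """The four alternative composites and their Pearson concordance."""
    weights, composite = integrate_composite(scores, sources=sources)
    M, Z, _ = _prepare_columns(scores)
    w = weights.per_column
    ranks = scores.loc[:, M.columns].apply(
        lambda c: pd.Series(fractional_ranks(c.to_numpy()), index=scores.index)
    )
    alts = pd.DataFrame(
        {
            "Simple_Avg": M.mean(axis=1),
            "ZScore_Avg": Z.mean(axis=1),
            "Weighted_Avg": (Z * w).sum(axis=1),
            "Rank_Avg": ranks.mean(axis=1),
        }
    )
    concordance = alts.corr(method="pearson")
    return CompositeScores(
        composite=composite, alternatives=alts, concordance=concordance,
        weights=weights,
    )
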