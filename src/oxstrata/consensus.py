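"""Consensus biomarker selection on an external bulk cohort.

The framework mirrors a leakage-safe diagnostic-marker pipeline:

1. stratified train/test split preserving case prevalence (84/36 of 120 at
   58.3% prevalence by default);
2. parametric empirical-Bayes batch adjustment (location/scale, normal and
   inverse-gamma priors) fitted on the training set only and applied to
   both sets;
3. per-gene Z-scaling with training-set parameters;
4. repeated stratified cross-validation in which six feature-selection
   algorithms vote per fold: random forest (importance vs shuffled-label
   null), two gradient-boosted-tree configurations, L1-penalized logistic
   regression, a Boruta-style shadow-feature test, and a single decision
   tree;
5. a consensus rule — selected by >= 4 of 6 algorithms, present in > 50% of
   folds for at least one qualifying algorithm, and permutation BH q < 0.05;
6. per-gene held-out ROC evaluation with DeLong confidence intervals.

Class imbalance is handled with inverse-class-frequency weights throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateDataError, InvalidConfigError
from .simulate import SyntheticBulkCohort

ALGORITHMS = ("rf", "gbt_a", "gbt_b", "l1_logistic", "boruta", "tree")


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    n_train: int = 84
    n_test: int = 36
    seed: int = 123


def stratified_split(
    cohort: SyntheticBulkCohort, spec: SplitSpec | None = None
) -> tuple[pd.Index, pd.Index]:
    """Deterministic stratified split preserving the case prevalence.

    Per-class training counts are ``round(n_train * n_class / n)`` with a
    nearest-integer correction when the rounded counts do not sum to
    ``n_train``.  120 samples with 70 cases split 84/36 puts exactly 49
    cases and 35 controls in training.
    """
    spec = spec or SplitSpec()
    y = cohort.y
    n = len(y)
    if spec.n_train + spec.n_test != n:
        raise InvalidConfigError(
            f"n_train + n_test = {spec.n_train + spec.n_test} != cohort size {n}"
        )
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateDataError("both classes must be present to stratify")
    rng = np.random.default_rng(spec.seed)
    takes = {c: int(round(spec.n_train * (y == c).sum() / n)) for c in classes}
    drift = spec.n_train - sum(takes.values())
    if drift != 0:
        warnings.warn("exact stratification infeasible; nearest-integer allocation")
        largest = max(takes, key=lambda c: (y == c).sum())
        takes[largest] += drift
    train_mask = np.zeros(n, dtype=bool)
    for c in classes:
        idx = np.where(y == c)[0]
        chosen = rng.choice(idx, size=takes[c], replace=False)
        train_mask[chosen] = True
    ids = cohort.expr.index
    return ids[train_mask], ids[~train_mask]


# ---------------------------------------------------------------------------
# train-fitted batch adjustment (parametric empirical Bayes)
# ---------------------------------------------------------------------------

@dataclass
class BatchAdjustModel:
    """Location/scale batch adjustment with parametric EB shrinkage.

    Per gene, data are standardized by the training grand mean and pooled
    SD; per-batch location (gamma) and scale (delta^2) effects are shrunk
    toward normal / inverse-gamma priors estimated across genes, and
    removed.  All parameters come from the training set; labels are never
    consulted.  ``shrink=False`` disables the EB step (gamma*, delta* equal
    their per-batch estimates), which removes observed batch means exactly.
    """

    shrink: bool = True
    fitted: bool = field(default=False, init=False)

    def fit(self, X: pd.DataFrame, batch: pd.Series) -> "BatchAdjustModel":
        batch = batch.loc[X.index]
        self.batches_ = sorted(batch.unique())
        self.genes_ = X.columns
        if len(self.batches_) == 1:
            self.identity_ = True
            self.fitted = True
            return self
        self.identity_ = False
        V = X.to_numpy(dtype=float)            # samples x genes
        b_arr = batch.to_numpy()
        n = len(V)
        self.batch_sizes_ = {}
        means = {}
        for b in self.batches_:
            mask = b_arr == b
            if mask.sum() < 2:
                raise DegenerateDataError(
                    f"batch {b!r} has fewer than 2 training samples"
                )
            self.batch_sizes_[b] = int(mask.sum())
            means[b] = V[mask].mean(axis=0)
        self.batch_train_means_ = means
        w = np.array([self.batch_sizes_[b] / n for b in self.batches_])
        stacked = np.stack([means[b] for b in self.batches_])
        self.alpha_ = w @ stacked
        resid = np.empty_like(V)
        for b in self.batches_:
            mask = b_arr == b
            resid[mask] = V[mask] - means[b]
        var_pooled = (resid**2).mean(axis=0)
        var_pooled = np.where(var_pooled <= 0, 1e-8, var_pooled)
        self.sigma_ = np.sqrt(var_pooled)

        Z = (V - self.alpha_) / self.sigma_
        self.gamma_star_, self.delta_star_ = {}, {}
        for b in self.batches_:
            mask = b_arr == b
            Zb = Z[mask]
            nb = Zb.shape[0]
            gamma_hat = Zb.mean(axis=0)
            delta_hat = Zb.var(axis=0, ddof=1)
            if not self.shrink:
                self.gamma_star_[b] = gamma_hat
                self.delta_star_[b] = np.where(delta_hat <= 0, 1e-8, delta_hat)
                continue
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
            if s2 <= 0:
                a_prior, b_prior = 2.0, m
            else:
                a_prior = (2 * s2 + m**2) / s2
                b_prior = (m * s2 + m**3) / s2
            g_star = gamma_hat.copy()
            d_star = delta_hat.copy()
            for _ in range(100):
                g_new = (nb * tau2 * gamma_hat + d_star * gamma_bar) / (
                    nb * tau2 + d_star
                )
                sum2 = ((Zb - g_new) ** 2).sum(axis=0)
                d_new = (b_prior + 0.5 * sum2) / (nb / 2.0 + a_prior - 1.0)
                change = max(
                    np.max(np.abs(g_new - g_star) / (np.abs(g_star) + 1e-12)),
                    np.max(np.abs(d_new - d_star) / (np.abs(d_star) + 1e-12)),
                )
                g_star, d_star = g_new, d_new
                if change < 1e-4:
                    break
            self.gamma_star_[b] = g_star
            self.delta_star_[b] = np.where(d_star <= 0, 1e-8, d_star)
        self.fitted = True
        return self

    def transform(self, X: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
        if not self.fitted:
            raise RuntimeError("BatchAdjustModel must be fitted before apply")
        if self.identity_:
            return X.copy()
        batch = batch.loc[X.index]
        V = X.to_numpy(dtype=float)
        out = np.empty_like(V)
        Z = (V - self.alpha_) / self.sigma_
        train_mat = np.stack(
            [self.batch_train_means_[b] for b in self.batches_]
        )
        for b in batch.unique():
            mask = (batch == b).to_numpy()
            use = b
            if b not in self.gamma_star_:
                test_mean = V[mask].mean(axis=0)
                nearest = int(
                    np.argmin(((train_mat - test_mean) ** 2).sum(axis=1))
                )
                use = self.batches_[nearest]
                warnings.warn(
                    f"batch {b!r} unseen in training; using nearest batch {use!r}"
                )
            out[mask] = (
                self.sigma_
                * (Z[mask] - self.gamma_star_[use])
                / np.sqrt(self.delta_star_[use])
                + self.alpha_
            )
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def fit_apply_batch_adjust(
    train: pd.DataFrame,
    test: pd.DataFrame,
    batch: pd.Series,
    shrink: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, BatchAdjustModel]:
    model = BatchAdjustModel(shrink=shrink).fit(train, batch)
    return model.transform(train, batch), model.transform(test, batch), model


# ---------------------------------------------------------------------------
# train-fitted scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalerModel:
    mean_: pd.Series = field(default=None, init=False)
    sd_: pd.Series = field(default=None, init=False)

    def fit(self, train: pd.DataFrame) -> "ScalerModel":
        self.mean_ = train.mean(axis=0)
        sd = train.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            warnings.warn(f"dropping {int(zero.sum())} zero-variance gene(s)")
        self.sd_ = sd[~zero]
        self.mean_ = self.mean_[~zero]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.mean_.index] - self.mean_) / self.sd_


def fit_apply_zscore(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, ScalerModel]:
    model = ScalerModel().fit(train)
    return model.transform(train), model.transform(test), model


# ---------------------------------------------------------------------------
# six selectors
# ---------------------------------------------------------------------------

def _balanced_sample_weight(y: np.ndarray) -> np.ndarray:
    n = len(y)
    w = np.empty(n)
    for c in np.unique(y):
        mask = y == c
        w[mask] = n / (2.0 * mask.sum())
    return w


def _select_rf(X, y, seed, n_trees=100, n_null=5, percentile=95.0):
    rng = np.random.default_rng(seed)
    rf = RandomForestClassifier(
        n_estimators=n_trees, class_weight="balanced", random_state=seed, n_jobs=1
    ).fit(X, y)
    null_imp = []
    for _ in range(n_null):
        y_perm = rng.permutation(y)
        if len(np.unique(y_perm)) < 2:
            continue
        null = RandomForestClassifier(
            n_estimators=n_trees, class_weight="balanced",
            random_state=seed, n_jobs=1,
        ).fit(X, y_perm)
        null_imp.append(null.feature_importances_)
    thr = np.percentile(np.concatenate(null_imp), percentile)
    return set(np.where(rf.feature_importances_ > thr)[0])


def _select_gbt_a(X, y, seed):
    from xgboost import XGBClassifier

    pos = max(int(y.sum()), 1)
    neg = max(len(y) - pos, 1)
    clf = XGBClassifier(
        max_depth=3, learning_rate=0.1, n_estimators=100, reg_lambda=1.0,
        subsample=1.0, scale_pos_weight=neg / pos, random_state=seed,
        n_jobs=1, tree_method="hist", eval_metric="logloss", verbosity=0,
    ).fit(X, y)
    return set(np.where(clf.feature_importances_ > 0)[0])


def _select_gbt_b(X, y, seed):
    clf = GradientBoostingClassifier(
        max_depth=2, learning_rate=0.05, n_estimators=100, subsample=0.8,
        random_state=seed,
    ).fit(X, y, sample_weight=_balanced_sample_weight(y))
    return set(np.where(clf.feature_importances_ > 0)[0])


def _select_l1(X, y, seed):
    clf = LogisticRegressionCV(
        l1_ratios=(1.0,), solver="liblinear", Cs=10, cv=3,
        scoring="accuracy", class_weight="balanced", random_state=seed,
        max_iter=500,
    ).fit(X, y)
    return set(np.where(np.abs(clf.coef_).ravel() > 1e-10)[0])


def _select_boruta(X, y, seed, max_iter=25, n_trees=50, alpha=0.05):
    """Shadow-feature confirmation: a feature is confirmed when it beats the
    best shuffled copy significantly more often than chance (binomial test),
    rejected when significantly less often."""
    rng = np.random.default_rng(seed)
    n_feat = X.shape[1]
    confirmed = np.zeros(n_feat, dtype=bool)
    rejected = np.zeros(n_feat, dtype=bool)
    hits = np.zeros(n_feat, dtype=int)
    trials = np.zeros(n_feat, dtype=int)
    for it in range(max_iter):
        active = np.where(~rejected)[0]
        if active.size == 0:
            break
        Xa = X[:, active]
        shadow = Xa.copy()
        for j in range(shadow.shape[1]):
            shadow[:, j] = rng.permutation(shadow[:, j])
        rf = RandomForestClassifier(
            n_estimators=n_trees, class_weight="balanced",
            random_state=seed + it, n_jobs=1,
        ).fit(np.hstack([Xa, shadow]), y)
        imp = rf.feature_importances_
        shadow_max = imp[Xa.shape[1]:].max()
        hits[active] += imp[: Xa.shape[1]] > shadow_max
        trials[active] += 1
        undecided = ~confirmed & ~rejected
        t, h = trials[undecided], hits[undecided]
        p_hit = stats.binom.sf(h - 1, t, 0.5)
        p_miss = stats.binom.cdf(h, t, 0.5)
        conf = np.where(undecided)[0][p_hit < alpha]
        rej = np.where(undecided)[0][p_miss < alpha]
        confirmed[conf] = True
        rejected[rej] = True
        if not (~confirmed & ~rejected).any():
            break
    return set(np.where(confirmed)[0])


def _select_tree(X, y, seed, max_depth=5):
    clf = DecisionTreeClassifier(
        max_depth=max_depth, class_weight="balanced", random_state=seed
    ).fit(X, y)
    return set(np.where(clf.feature_importances_ > 0)[0])


_SELECTORS = {
    "rf": _select_rf,
    "gbt_a": _select_gbt_a,
    "gbt_b": _select_gbt_b,
    "l1_logistic": _select_l1,
    "boruta": _select_boruta,
    "tree": _select_tree,
}


def run_selector(
    algorithm: str, X: pd.DataFrame, y: np.ndarray, seed: int = 0
) -> set[str]:
    """Run one selector on a fold; returns the selected gene names."""
    if algorithm not in _SELECTORS:
        raise InvalidConfigError(f"unknown algorithm {algorithm!r}")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        warnings.warn(f"degenerate fold for {algorithm}: single class")
        return set()
    idx = _SELECTORS[algorithm](X.to_numpy(dtype=float), y, seed)
    return {X.columns[i] for i in idx}


# ---------------------------------------------------------------------------
# nested CV, permutation null, consensus
# ---------------------------------------------------------------------------

@dataclass
class SelectorResult:
    algorithm: str
    fold_sets: list[set[str]]
    frequency: pd.Series  # per-gene fraction of folds selecting it


def nested_cv_select(
    X: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int = 5,
    n_folds: int = 10,
    seed: int = 0,
    algorithms: tuple[str, ...] = ALGORITHMS,
) -> dict[str, SelectorResult]:
    """Repeated stratified CV; per-algorithm per-gene fold frequencies.

    Each repeat reshuffles a stratified k-fold partition; every selector is
    run on each fold's training portion, and a gene's frequency is the
    fraction of all ``n_repeats * n_folds`` folds in which it was selected.
    """
    y = np.asarray(y)
    min_class = min(np.bincount(y))
    folds = n_folds
    if min_class < n_folds:
        folds = max(2, min_class)
        warnings.warn(f"reducing folds from {n_folds} to {folds} (small class)")
    fold_train_indices = []
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for train_idx, _ in skf.split(X, y):
            fold_train_indices.append(train_idx)
    results = {}
    for alg in algorithms:
        fold_sets = []
        for f, train_idx in enumerate(fold_train_indices):
            fold_sets.append(
                run_selector(
                    alg, X.iloc[train_idx], y[train_idx],
                    seed=seed * 1000 + f,
                )
            )
        counts = pd.Series(0.0, index=X.columns)
        for s in fold_sets:
            counts[list(s)] += 1.0
        results[alg] = SelectorResult(
            algorithm=alg, fold_sets=fold_sets,
            frequency=counts / len(fold_sets),
        )
    return results


def permutation_null(
    X: pd.DataFrame,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    pool: bool = True,
) -> pd.DataFrame:
    """Permutation p/q per gene on the absolute point-biserial association.

    The statistic is algorithm-agnostic so a single label permutation null
    serves all selectors.  With ``pool=False`` each gene is compared to its
    own ``n_perm`` permuted statistics, p = (1 + #{perm >= obs}) /
    (n_perm + 1).  With ``pool=True`` (default) the null statistics of all
    genes are pooled before computing p — since genes enter standardized,
    their permutation nulls are exchangeable, and pooling gives the
    resolution (floor ~ 1/(G * n_perm)) that the BH correction needs when
    only a handful of genes carry signal among many.  BH q-values are
    computed across genes either way.
    """
    if n_perm < 1:
        raise InvalidConfigError("n_perm must be at least 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    sx = Xc.std(axis=0)
    sx = np.where(sx == 0, 1.0, sx)
    yc = y - y.mean()
    sy = yc.std()
    if sy == 0:
        raise DegenerateDataError("labels are constant")
    n = len(y)
    obs = np.abs(Xc.T @ yc) / (n * sx * sy)
    perms = np.stack([rng.permutation(yc) for _ in range(n_perm)], axis=1)
    null = np.abs(Xc.T @ perms) / (n * sx[:, None] * sy)
    if pool:
        flat = np.sort(null.ravel())
        ge = flat.size - np.searchsorted(flat, obs - 1e-15, side="left")
        p = (1 + ge) / (flat.size + 1)
    else:
        p = (1 + (null >= obs[:, None] - 1e-15).sum(axis=1)) / (n_perm + 1)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"statistic": obs, "p_value": p, "q_value": q}, index=X.columns
    )


@dataclass
class ConsensusReport:
    table: pd.DataFrame        # per-gene evidence
    consensus: list[str]       # genes meeting all three criteria
    thresholds: dict

    def selected_sizes(self) -> dict[str, int]:
        cols = [c for c in self.table.columns if c.startswith("freq_")]
        return {c[5:]: int((self.table[c] > 0).sum()) for c in cols}


def consensus_genes(
    results: dict[str, SelectorResult],
    perm: pd.DataFrame,
    min_algos: int = 4,
    min_fold_frac: float = 0.5,
    q_max: float = 0.05,
) -> ConsensusReport:
    """Apply the three-part consensus rule.

    A gene is a consensus biomarker when (i) at least ``min_algos`` of the
    six algorithms selected it in some fold, (ii) at least one of those
    algorithms selected it in more than ``min_fold_frac`` of its folds, and
    (iii) its permutation BH q-value is below ``q_max``.
    """
    genes = perm.index
    freq = pd.DataFrame(
        {alg: res.frequency.reindex(genes).fillna(0.0)
         for alg, res in results.items()}
    )
    n_algos = (freq > 0).sum(axis=1)
    max_freq = freq.max(axis=1)
    in_consensus = (
        (n_algos >= min_algos)
        & (max_freq > min_fold_frac)
        & (perm["q_value"] < q_max)
    )
    table = pd.DataFrame(
        {
            "n_algorithms": n_algos,
            "max_fold_frequency": max_freq,
            "statistic": perm["statistic"],
            "p_value": perm["p_value"],
            "q_value": perm["q_value"],
            "consensus": in_consensus,
        }
    )
    for alg in results:
        table[f"freq_{alg}"] = freq[alg]
    return ConsensusReport(
        table=table.sort_values(
            ["consensus", "n_algorithms", "max_fold_frequency"], ascending=False
        ),
        consensus=sorted(genes[in_consensus]),
        thresholds={
            "min_algos": min_algos,
            "min_fold_frac": min_fold_frac,
            "q_max": q_max,
        },
    )


# ---------------------------------------------------------------------------
# held-out ROC
# ---------------------------------------------------------------------------

def _delong_auc(cases: np.ndarray, controls: np.ndarray):
    """AUC with DeLong variance via midrank placements."""
    m, n = len(cases), len(controls)
    allv = np.concatenate([cases, controls])
    ranks = stats.rankdata(allv)
    rc = stats.rankdata(cases)
    rk = stats.rankdata(controls)
    v10 = (ranks[:m] - rc) / n                # placement of each case
    v01 = 1.0 - (ranks[m:] - rk) / m          # placement of each control
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return auc, var


def evaluate_auc(
    X_test: pd.DataFrame, y_test: np.ndarray, genes: list[str]
) -> pd.DataFrame:
    """Per-gene Mann-Whitney AUC on held-out data with DeLong 95% CI.

    The two-sided p-value tests AUC = 0.5 by the normal approximation on
    the DeLong variance; perfectly separating genes get a degenerate CI at
    the point estimate.
    """
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise DegenerateDataError("held-out set must contain both classes")
    columns = ["gene", "auc", "ci_low", "ci_high", "p_value"]
    if not genes:
        return pd.DataFrame(columns=columns).set_index("gene")
    rows = []
    for g in genes:
        x = X_test[g].to_numpy(dtype=float)
        auc, var = _delong_auc(x[y_test == 1], x[y_test == 0])
        se = np.sqrt(var)
        if se == 0:
            p = 1.0 if auc == 0.5 else 0.0
            lo = hi = auc
        else:
            z = (auc - 0.5) / se
            p = float(2 * stats.norm.sf(abs(z)))
            lo = max(0.0, auc - 1.959963984540054 * se)
            hi = min(1.0, auc + 1.959963984540054 * se)
        rows.append(
            {"gene": g, "auc": float(auc), "ci_low": lo, "ci_high": hi,
             "p_value": p}
        )
    return pd.DataFrame(rows).set_index("gene")
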