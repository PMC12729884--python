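"""Consensus biomarker framework: split, batch adjust, selectors, rules, ROC."""

import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_combat_noshrink
from oxstrata.consensus import (
    ALGORITHMS,
    BatchAdjustModel,
    SelectorResult,
    SplitSpec,
    consensus_genes,
    evaluate_auc,
    fit_apply_zscore,
    nested_cv_select,
    permutation_null,
    run_selector,
    stratified_split,
)
from oxstrata.exceptions import DegenerateDataError, InvalidConfigError
from oxstrata.simulate import BulkSimConfig, SyntheticBulkCohort, generate_bulk


class TestSplit:
    def test_default_split_counts(self, small_bulk_cohort):
        train, test = stratified_split(small_bulk_cohort, SplitSpec(84, 36))
        y = pd.Series(small_bulk_cohort.y, index=small_bulk_cohort.expr.index)
        assert len(train) == 84 and len(test) == 36
        assert y.loc[train].sum() == 49
        assert y.loc[test].sum() == 21

    def test_deterministic(self, small_bulk_cohort):
        a = stratified_split(small_bulk_cohort, SplitSpec(84, 36, seed=7))
        b = stratified_split(small_bulk_cohort, SplitSpec(84, 36, seed=7))
        assert list(a[0]) == list(b[0])

    def test_single_class_rejected(self):
        cohort = generate_bulk(BulkSimConfig(seed=0))
        cohort.label[:] = "case"
        with pytest.raises(DegenerateDataError):
            stratified_split(cohort, SplitSpec(84, 36))

    def test_size_mismatch_rejected(self, small_bulk_cohort):
        with pytest.raises(InvalidConfigError):
            stratified_split(small_bulk_cohort, SplitSpec(80, 36))


class TestBatchAdjust:
    def _shifted(self, per_gene_shift, n=40, g=12, seed=0, in_z_units=True):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1.0, (n, g))
        batch = pd.Series(np.repeat([1, 2], n // 2),
                          index=[f"S{i}" for i in range(n)])
        X[n // 2:] += per_gene_shift
        return (
            pd.DataFrame(X, index=batch.index,
                         columns=[f"G{j}" for j in range(g)]),
            batch,
        )

    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10, 4)),
                         index=[f"S{i}" for i in range(10)])
        batch = pd.Series(1, index=X.index)
        model = BatchAdjustModel().fit(X, batch)
        out = model.transform(X, batch)
        assert np.allclose(out.to_numpy(), X.to_numpy(), atol=1e-9)

    def test_location_shift_removed_exactly_without_shrinkage(self):
        shift = np.linspace(-2, 2, 12)
        X, batch = self._shifted(shift)
        model = BatchAdjustModel(shrink=False).fit(X, batch)
        out = model.transform(X, batch)
        means = out.groupby(batch).mean()
        assert np.abs(means.iloc[0] - means.iloc[1]).max() < 1e-6

    def test_eb_shrinkage_reduces_batch_separation(self):
        shift = np.linspace(-2, 2, 12)
        X, batch = self._shifted(shift, seed=2)
        before = (X.groupby(batch).mean().diff().iloc[1]).abs().mean()
        out = BatchAdjustModel(shrink=True).fit(X, batch).transform(X, batch)
        after = (out.groupby(batch).mean().diff().iloc[1]).abs().mean()
        assert after < 0.2 * before

    def test_matches_noshrink_oracle(self):
        """Location/scale standardization agrees with a loop-based oracle."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(2.0, 1.5, (30, 8)),
                         index=[f"S{i}" for i in range(30)],
                         columns=[f"G{j}" for j in range(8)])
        X.iloc[15:] += rng.normal(0, 1.0, 8)
        batch = pd.Series(np.repeat(["a", "b"], 15), index=X.index)
        out = BatchAdjustModel(shrink=False).fit(X, batch).transform(X, batch)
        ref = oracle_combat_noshrink(X.to_numpy(), list(batch))
        assert np.allclose(out.to_numpy(), ref, atol=1e-6)

    def test_refit_is_deterministic_and_label_free(self):
        X, batch = self._shifted(np.ones(12), seed=4)
        m1 = BatchAdjustModel().fit(X, batch)
        m2 = BatchAdjustModel().fit(X, batch)
        for b in m1.batches_:
            assert np.allclose(m1.gamma_star_[b], m2.gamma_star_[b])
            assert np.allclose(m1.delta_star_[b], m2.delta_star_[b])

    def test_unseen_batch_falls_back_to_nearest(self):
        X, batch = self._shifted(np.full(12, 3.0), seed=5)
        model = BatchAdjustModel().fit(X, batch)
        X_new = X.iloc[:5] + 0.1
        X_new.index = [f"T{i}" for i in range(5)]
        new_batch = pd.Series(99, index=X_new.index)
        with pytest.warns(UserWarning):
            out = model.transform(X_new, new_batch)
        assert out.shape == X_new.shape

    def test_small_batch_rejected(self):
        X, batch = self._shifted(np.ones(12), seed=6)
        batch.iloc[-1] = 3  # singleton batch
        with pytest.raises(DegenerateDataError):
            BatchAdjustModel().fit(X, batch)


class TestScaler:
    def test_train_scaled_to_standard(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame(rng.normal(3, 2, (50, 6)))
        z_train, z_test, _ = fit_apply_zscore(train, train.copy())
        assert np.allclose(z_train.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z_train.std(axis=0, ddof=0), 1, atol=1e-12)
        assert np.allclose(z_train.to_numpy(), z_test.to_numpy())

    def test_shifted_test_set_arithmetic(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame(rng.normal(0, 1, (100, 4)))
        z_train, z_test, model = fit_apply_zscore(train, train + 1.0)
        expected = z_train.mean(axis=0) + 1.0 / model.sd_
        assert np.allclose(z_test.mean(axis=0), expected, atol=1e-12)

    def test_zero_variance_gene_dropped(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            z_train, _, _ = fit_apply_zscore(train, train.copy())
        assert list(z_train.columns) == ["a"]


class TestSelectors:
    def _separable(self, seed=0, n=60, g=20):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, g))
        X[:, 3] = y * 4.0 + rng.normal(0, 0.05, n)  # near-perfect separator
        return pd.DataFrame(X, columns=[f"G{j}" for j in range(g)]), y

    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_every_algorithm_finds_the_separating_gene(self, alg):
        X, y = self._separable()
        assert "G3" in run_selector(alg, X, y, seed=1)

    def test_degenerate_fold_returns_empty(self):
        X, _ = self._separable()
        with pytest.warns(UserWarning):
            assert run_selector("tree", X, np.zeros(len(X), dtype=int)) == set()

    def test_unknown_algorithm(self):
        X, y = self._separable()
        with pytest.raises(InvalidConfigError):
            run_selector("svm", X, y)

    def test_small_class_reduces_fold_count_with_warning(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(12, 5)),
                         columns=[f"G{j}" for j in range(5)])
        y = np.array([0] * 9 + [1] * 3)
        with pytest.warns(UserWarning, match="reducing folds"):
            res = nested_cv_select(X, y, n_repeats=1, n_folds=10, seed=0,
                                   algorithms=("tree",))
        assert len(res["tree"].fold_sets) == 3

    def test_nested_cv_frequencies_bounded_and_deterministic(self):
        X, y = self._separable(seed=2)
        res1 = nested_cv_select(X, y, n_repeats=1, n_folds=3, seed=5,
                                algorithms=("tree", "l1_logistic"))
        res2 = nested_cv_select(X, y, n_repeats=1, n_folds=3, seed=5,
                                algorithms=("tree", "l1_logistic"))
        for alg in ("tree", "l1_logistic"):
            f = res1[alg].frequency
            assert ((f >= 0) & (f <= 1)).all()
            assert f.equals(res2[alg].frequency)
            assert f["G3"] == 1.0  # separator picked in every fold


class TestPermutationNull:
    def _data(self, seed=0, n=40, g=10):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(0, 1, (n, g)),
                         columns=[f"G{j}" for j in range(g)])
        y = rng.integers(0, 2, n)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, n)
        return X, y

    def test_perfect_association_hits_floor(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 30)
        X = pd.DataFrame({"G0": y.astype(float)})
        out = permutation_null(X, y, n_perm=100, seed=0, pool=False)
        assert out.loc["G0", "p_value"] == pytest.approx(1 / 101)

    def test_constant_gene_gets_p_one(self):
        y = np.repeat([0, 1], 10)
        X = pd.DataFrame({"G0": np.ones(20), "G1": y.astype(float)})
        out = permutation_null(X, y, n_perm=50, seed=0, pool=False)
        assert out.loc["G0", "p_value"] == 1.0

    def test_null_p_values_roughly_uniform(self):
        from scipy.stats import kstest

        X, y = self._data(seed=3, n=60, g=500)
        out = permutation_null(X, y, n_perm=200, seed=1, pool=False)
        assert kstest(out["p_value"], "uniform").pvalue > 0.01

    def test_pooling_sharpens_resolution(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 30)
        X = pd.DataFrame(rng.normal(0, 1, (60, 50)),
                         columns=[f"G{j}" for j in range(50)])
        X["G0"] = y * 3.0 + rng.normal(0, 0.2, 60)
        pooled = permutation_null(X, y, n_perm=100, seed=2, pool=True)
        assert pooled.loc["G0", "p_value"] < 1 / 101


class TestConsensusRule:
    def _results(self, freq_by_alg):
        genes = pd.Index(["G0", "G1", "G2"])
        out = {}
        for alg, freqs in freq_by_alg.items():
            f = pd.Series(freqs, index=genes, dtype=float)
            out[alg] = SelectorResult(algorithm=alg, fold_sets=[], frequency=f)
        return out

    def _perm(self, q):
        return pd.DataFrame(
            {"statistic": 1.0, "p_value": q, "q_value": q},
            index=pd.Index(["G0", "G1", "G2"]),
        )

    def test_unanimous_gene_in_consensus(self):
        results = self._results(
            {a: [1.0, 0.0, 0.0] for a in ALGORITHMS}
        )
        rep = consensus_genes(results, self._perm([0.001, 1.0, 1.0]))
        assert rep.consensus == ["G0"]

    def test_three_of_six_excluded(self):
        freqs = {a: [1.0, 0.0, 0.0] for a in ALGORITHMS[:3]}
        freqs.update({a: [0.0, 0.0, 0.0] for a in ALGORITHMS[3:]})
        rep = consensus_genes(self._results(freqs), self._perm([0.001, 1, 1]))
        assert rep.consensus == []

    def test_fold_frequency_any_of_rule(self):
        # 4 algorithms pick G0 but none in >50% of folds -> excluded;
        # raising one algorithm's frequency above 0.5 admits it
        low = {a: [0.4, 0, 0] for a in ALGORITHMS[:4]}
        low.update({a: [0.0, 0, 0] for a in ALGORITHMS[4:]})
        rep = consensus_genes(self._results(low), self._perm([0.001, 1, 1]))
        assert rep.consensus == []
        low[ALGORITHMS[0]] = [0.6, 0, 0]
        rep2 = consensus_genes(self._results(low), self._perm([0.001, 1, 1]))
        assert rep2.consensus == ["G0"]

    def test_q_value_gate(self):
        results = self._results({a: [1.0, 1.0, 0.0] for a in ALGORITHMS})
        rep = consensus_genes(results, self._perm([0.001, 0.2, 1.0]))
        assert rep.consensus == ["G0"]

    def test_monotone_in_added_algorithm(self):
        """Adding an algorithm that selects a gene never removes it."""
        base = {a: [1.0, 0, 0] for a in ALGORITHMS[:4]}
        base.update({a: [0.0, 0, 0] for a in ALGORITHMS[4:5]})
        rep1 = consensus_genes(self._results(base), self._perm([0.01, 1, 1]))
        richer = dict(base)
        richer[ALGORITHMS[5]] = [1.0, 0, 0]
        rep2 = consensus_genes(self._results(richer), self._perm([0.01, 1, 1]))
        assert set(rep1.consensus) <= set(rep2.consensus)


class TestROC:
    def test_known_auc_three_quarters(self):
        X = pd.DataFrame({"G0": [0.1, 0.4, 0.35, 0.8]})
        out = evaluate_auc(X, np.array([0, 0, 1, 1]), ["G0"])
        assert out.loc["G0", "auc"] == pytest.approx(0.75)

    def test_perfect_separator(self):
        X = pd.DataFrame({"G0": [1.0, 2.0, 10.0, 11.0]})
        out = evaluate_auc(X, np.array([0, 0, 1, 1]), ["G0"])
        assert out.loc["G0", "auc"] == 1.0
        assert out.loc["G0", "p_value"] == 0.0

    def test_constant_score_is_chance(self):
        X = pd.DataFrame({"G0": np.ones(10)})
        out = evaluate_auc(X, np.repeat([0, 1], 5), ["G0"])
        assert out.loc["G0", "auc"] == pytest.approx(0.5)
        assert out.loc["G0", "p_value"] == 1.0

    def test_single_class_rejected(self):
        X = pd.DataFrame({"G0": np.arange(4.0)})
        with pytest.raises(DegenerateDataError):
            evaluate_auc(X, np.zeros(4, dtype=int), ["G0"])

    def test_ci_bounds_and_large_sample_power(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 50)
        X = pd.DataFrame({"G0": y + rng.normal(0, 1, 100)})
        out = evaluate_auc(X, y, ["G0"])
        row = out.loc["G0"]
        assert 0 <= row.ci_low <= row.auc <= row.ci_high <= 1
        assert row.p_value < 0.001
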