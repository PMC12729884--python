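"""Gene-set scorers against brute-force oracles, and composite integration."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (
    oracle_aucell,
    oracle_module_avg,
    oracle_singscore,
    oracle_ssgsea,
    oracle_ucell,
)
from conftest import make_adata, make_expr
from oxstrata.exceptions import DegenerateDataError, EmptyGeneSetError, InvalidConfigError
from oxstrata.scoring import (
    alternative_composites,
    integrate_composite,
    inverse_variance_weights,
    normalize_expression,
    score_aucell,
    score_module_avg,
    score_singscore,
    score_ssgsea,
    score_ucell,
)


def genes(*idx):
    return [f"G{i:05d}" for i in idx]


class TestNormalize:
    def test_depth_already_at_scale(self):
        ad = make_adata(np.array([[10.0, 90.0]]))
        expr = normalize_expression(ad, scale=100)
        assert np.allclose(expr.X, np.log1p([10.0, 90.0]))

    def test_all_zero_gene_stays_zero(self):
        ad = make_adata(np.array([[5.0, 0.0], [3.0, 0.0]]))
        expr = normalize_expression(ad)
        assert (expr.X[:, 1] == 0).all()

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(0)
        ad = make_adata(rng.poisson(3.0, (20, 15)) + 1.0)
        expr = normalize_expression(ad, scale=1e4)
        assert np.allclose(np.expm1(expr.X).sum(axis=1), 1e4)

    def test_zero_cell_warns(self):
        ad = make_adata(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.warns(UserWarning):
            expr = normalize_expression(ad)
        assert (expr.X[0] == 0).all()


class TestScorerExamples:
    def test_module_avg_constant_matrix_scores_zero(self):
        expr = make_expr(np.full((4, 12), 2.5))
        s = score_module_avg(expr, genes(0, 3), seed=0)
        assert np.allclose(s, 0.0)

    def test_module_avg_closed_form_single_cell(self):
        # one set gene at m=5, nine control genes all at c=2 -> m - c
        row = np.full(10, 2.0)
        row[0] = 5.0
        expr = make_expr(row[None, :])
        s = score_module_avg(expr, genes(0), n_bins=1, n_ctrl=50, seed=1)
        assert np.allclose(s, 3.0)

    def test_module_avg_random_set_is_unbiased(self):
        rng = np.random.default_rng(2)
        expr = make_expr(rng.gamma(2.0, 1.0, (1000, 60)))
        s = score_module_avg(expr, genes(*rng.choice(60, 8, replace=False)),
                             seed=3)
        assert abs(s.mean()) < 0.05

    def test_ucell_top_ranked_set_scores_one(self):
        X = np.tile(np.arange(20, 0, -1.0), (3, 1))  # G0 highest ... G19 lowest
        expr = make_expr(X)
        assert np.allclose(score_ucell(expr, genes(0, 1, 2), max_rank=10), 1.0)

    def test_ucell_fully_clamped_set_scores_zero(self):
        X = np.tile(np.arange(20, 0, -1.0), (2, 1))
        expr = make_expr(X)
        s = score_ucell(expr, genes(18, 19), max_rank=5)
        assert np.allclose(s, 0.0)

    def test_ucell_hand_computed_case(self):
        # 10 genes in descending order; set at ranks {2, 5}, max_rank 8:
        # U' = (2+5) - 3 = 4, U'max = 2*9 - 3 = 15 -> score 11/15
        X = np.arange(10, 0, -1.0)[None, :]
        expr = make_expr(X)
        s = score_ucell(expr, genes(1, 4), max_rank=8)
        assert np.allclose(s, 11.0 / 15.0)

    def test_ucell_set_larger_than_max_rank(self):
        expr = make_expr(np.ones((1, 10)))
        with pytest.raises(InvalidConfigError):
            score_ucell(expr, genes(*range(6)), max_rank=5)

    def test_aucell_prefix_set_scores_one(self):
        X = np.arange(20, 0, -1.0)[None, :]
        expr = make_expr(X)
        assert np.allclose(score_aucell(expr, genes(0, 1, 2), top_frac=0.25), 1.0)

    def test_aucell_set_outside_window_scores_zero(self):
        X = np.arange(20, 0, -1.0)[None, :]
        expr = make_expr(X)
        assert np.allclose(score_aucell(expr, genes(18, 19), top_frac=0.25), 0.0)

    def test_aucell_window_too_small(self):
        expr = make_expr(np.ones((1, 10)))
        with pytest.raises(InvalidConfigError):
            score_aucell(expr, genes(0), top_frac=0.0)

    def test_singscore_extremes(self):
        X = np.arange(1.0, 11.0)[None, :]  # G9 highest
        expr = make_expr(X)
        assert np.allclose(score_singscore(expr, genes(8, 9)), 1.0)
        assert np.allclose(score_singscore(expr, genes(0, 1)), 0.0)

    def test_ssgsea_identical_cells_identical_scores(self):
        X = np.tile(np.arange(8.0), (3, 1))
        expr = make_expr(X)
        s = score_ssgsea(expr, genes(2, 5))
        assert np.allclose(s, s[0])

    def test_empty_after_intersection_raises(self):
        expr = make_expr(np.ones((2, 5)))
        with pytest.warns(UserWarning):
            with pytest.raises(EmptyGeneSetError):
                score_ucell(expr, ["NOT_A_GENE"])


@pytest.mark.parametrize("trial", range(40))
def test_scorers_match_bruteforce_oracles(trial):
    """All five scorers agree with loop-based oracles on random matrices,
    including tied values, to 1e-9 (the full 1000-trial sweep runs in the
    acceptance suite)."""
    rng = np.random.default_rng(trial)
    X = (
        rng.integers(0, 4, (5, 10)).astype(float)
        if trial % 2
        else rng.uniform(0, 5, (5, 10))
    )
    expr = make_expr(X)
    set_idx = sorted(rng.choice(10, rng.integers(1, 5), replace=False))
    gs = genes(*set_idx)
    assert np.allclose(score_ucell(expr, gs, max_rank=7),
                       oracle_ucell(X, set_idx, 7), atol=1e-9)
    assert np.allclose(score_aucell(expr, gs, top_frac=0.3),
                       oracle_aucell(X, set_idx, 0.3), atol=1e-9)
    assert np.allclose(score_singscore(expr, gs),
                       oracle_singscore(X, set_idx), atol=1e-9)
    assert np.allclose(score_ssgsea(expr, gs, alpha=0.25),
                       oracle_ssgsea(X, set_idx, 0.25), atol=1e-9)
    assert np.allclose(score_ssgsea(expr, gs, alpha=0.0),
                       oracle_ssgsea(X, set_idx, 0.0), atol=1e-9)
    assert np.allclose(
        score_module_avg(expr, gs, n_bins=3, n_ctrl=20, seed=trial),
        oracle_module_avg(X, set_idx, 3, 20, trial), atol=1e-9,
    )


def test_rank_scorers_invariant_to_monotone_transform():
    rng = np.random.default_rng(9)
    X = rng.uniform(0.1, 4.0, (30, 25))
    gs = genes(2, 7, 11)
    for f in (np.exp, np.sqrt, lambda v: v**3):
        a, b = make_expr(X), make_expr(f(X))
        assert np.allclose(score_ucell(a, gs), score_ucell(b, gs))
        assert np.allclose(score_aucell(a, gs), score_aucell(b, gs))
        assert np.allclose(score_singscore(a, gs), score_singscore(b, gs))


class TestComposite:
    def _frame(self, arrays):
        cols = pd.MultiIndex.from_tuples(
            [("m", f"s{i}") for i in range(len(arrays))], names=["method", "set"]
        )
        return pd.DataFrame(dict(zip(cols, arrays)))

    def test_inverse_variance_weights(self):
        w = inverse_variance_weights(pd.Series([1.0, 4.0]))
        assert np.allclose(w.to_numpy(), [0.8, 0.2])

    def test_identical_columns_give_common_zscore(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        scores = self._frame([x, x.copy(), x.copy()])
        _, composite = integrate_composite(scores)
        z = (x - x.mean()) / x.std()
        assert np.allclose(composite.to_numpy(), z)

    def test_composite_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        scores = self._frame([rng.normal(size=500), rng.uniform(size=500),
                              rng.gamma(2, 1, 500)])
        _, composite = integrate_composite(scores)
        assert abs(composite.mean()) < 1e-6
        assert abs(composite.std(ddof=0) - 1) < 1e-6

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        scores = self._frame([rng.normal(size=50), np.full(50, 2.0),
                              rng.normal(size=50)])
        with pytest.warns(UserWarning):
            weights, _ = integrate_composite(scores)
        assert len(weights.per_column) == 2
        assert abs(weights.per_column.sum() - 1) < 1e-9

    def test_single_column_rejected(self):
        with pytest.raises(DegenerateDataError):
            integrate_composite(self._frame([np.arange(10.0)]))

    def test_affine_invariance(self):
        """Min-max rescaling absorbs any positive affine map of a method's
        raw scores, leaving the composite unchanged."""
        rng = np.random.default_rng(4)
        arrays = [rng.normal(size=300), rng.uniform(size=300),
                  rng.gamma(3, 2, 300)]
        base = self._frame(arrays)
        warped = self._frame(
            [3.7 * arrays[0] - 2.0, arrays[1], 0.2 * arrays[2] + 11.0]
        )
        _, c1 = integrate_composite(base)
        _, c2 = integrate_composite(warped)
        assert np.allclose(c1.to_numpy(), c2.to_numpy())

    def test_equal_weights_make_weighted_equal_zscore_avg(self):
        # two columns with identical min-max variance -> weights 1/2 each
        x = np.linspace(0, 1, 100)
        scores = self._frame([x, 1.0 - x])
        comp = alternative_composites(scores)
        r = np.corrcoef(comp.alternatives["Weighted_Avg"],
                        comp.alternatives["ZScore_Avg"])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-12

    def test_identical_columns_full_concordance(self):
        # equally spaced values make ranks affine in values, so the
        # rank-based composite coincides with the value-based ones exactly
        x = np.random.default_rng(5).permutation(np.linspace(0.0, 1.0, 80))
        comp = alternative_composites(self._frame([x, x.copy()]))
        assert np.allclose(comp.concordance.to_numpy(), 1.0)

    def test_concordance_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(6)
        comp = alternative_composites(
            self._frame([rng.normal(size=200) for _ in range(4)])
        )
        C = comp.concordance.to_numpy()
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)

    def test_per_source_weights_sum_to_one(self):
        rng = np.random.default_rng(7)
        cols = pd.MultiIndex.from_tuples(
            [(m, s) for m in ("ucell", "aucell") for s in ("A", "B")],
            names=["method", "set"],
        )
        scores = pd.DataFrame(
            {c: rng.normal(size=100) for c in cols}
        )
        weights, _ = integrate_composite(
            scores, sources={"A": "HALLMARK", "B": "KEGG"}
        )
        assert abs(weights.per_source.sum() - 1) < 1e-9
        assert set(weights.per_source.index) == {"HALLMARK", "KEGG"}
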