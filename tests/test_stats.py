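"""Statistical kernels against hand-computed and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from sclerolink import stats
from sclerolink.errors import (
    DegenerateGroupError,
    DegenerateInputError,
    SingularDesignError,
    UndefinedCorrelationError,
)


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3, 4), (10, 20, 30, 40), 1.0),
            ((1, 2, 3, 4), (4, 3, 2, 1), -1.0),
            # rank-formula oracle: d = (-1, 1, -1, 1, 0), sum d^2 = 4,
            # rho = 1 - 6*4 / (5*24) = 0.8
            ((1, 2, 3, 4, 5), (2, 1, 4, 3, 5), 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        res = stats.spearman(x, y)
        assert res.rho == pytest.approx(expected, abs=1e-12)
        assert 0 <= res.p <= 1
        assert res.method == "spearman"

    def test_pairwise_complete_removes_missing_positions(self):
        x = [1, 2, np.nan, 3, 4, 5]
        y = [2, 1, 7.0, 4, 3, np.nan]
        res = stats.spearman(x, y)
        ref = stats.spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.n == 4
        assert res.rho == pytest.approx(ref.rho)

    def test_too_few_observations_raises(self):
        with pytest.raises(DegenerateInputError):
            stats.spearman([1, 2], [3, 4])
        with pytest.raises(DegenerateInputError):
            stats.spearman([1, 2, np.nan, np.nan], [1, np.nan, 2, 3])

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            stats.spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(-1000, 1000), min_size=5, max_size=20, unique=True),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_invariant_under_strictly_monotone_transform(self, xs, transform):
        xs = [float(v) for v in xs]
        rng = np.random.default_rng(7)
        y = rng.normal(size=len(xs))
        fn = {"exp": lambda v: np.exp(v / 25), "cube": lambda v: v**3 + v,
              "affine": lambda v: 3 * v + 2}[transform]
        base = stats.spearman(xs, y).rho
        moved = stats.spearman(fn(np.asarray(xs)), y).rho
        assert moved == pytest.approx(base, abs=1e-12)


class TestCorMatrix:
    @pytest.mark.parametrize("method", ["spearman", "pearson"])
    def test_matches_scalar_routines(self, rng, method):
        a = rng.normal(size=(4, 15))
        b = rng.normal(size=(3, 15))
        rho, p = stats.cor_matrix(a, b, method=method)
        for i in range(4):
            for j in range(3):
                ref = stats.correlate(a[i], b[j], method=method)
                assert rho[i, j] == pytest.approx(ref.rho, abs=1e-10)
                assert p[i, j] == pytest.approx(ref.p, abs=1e-10, rel=1e-6)

    def test_constant_row_gives_nan(self, rng):
        a = np.vstack([np.ones(10), rng.normal(size=10)])
        rho, p = stats.cor_matrix(a)
        assert np.isnan(rho[0, 1]) and np.isnan(p[0, 1])


class TestBhFdr:
    @pytest.mark.parametrize(
        "p_in, expected",
        [
            # step-up by hand: 0.01*3/1, 0.02*3/2, 0.03*3/3 -> all 0.03
            ((0.01, 0.02, 0.03), (0.03, 0.03, 0.03)),
            ((0.5,), (0.5,)),
            ((0.04, 0.9), (0.08, 0.9)),
        ],
    )
    def test_hand_computed_step_up(self, p_in, expected):
        np.testing.assert_allclose(stats.bh_fdr(p_in), expected, atol=1e-12)

    def test_nan_propagates_and_is_excluded_from_ranking(self):
        out = stats.bh_fdr([0.01, np.nan, 0.02, 0.03])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2, 3]], [0.03, 0.03, 0.03], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjustment_bounds_and_monotone_on_rerun(self, ps):
        adj = stats.bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1 + 1e-15)
        again = stats.bh_fdr(adj)
        assert np.all(again >= adj - 1e-12)


class TestAnovaTukey:
    def test_no_between_group_variance(self):
        res = stats.anova_tukey([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.f_stat == 0.0
        assert res.p == 1.0

    def test_separated_means_highly_significant(self):
        values = [0, 0.01, -0.01, 10, 10.01, 9.99]
        res = stats.anova_tukey(values, ["a"] * 3 + ["b"] * 3)
        assert res.p < 1e-6

    def test_f_matches_sums_of_squares_oracle(self):
        # 3-group fixture with hand-computable sums of squares
        groups = ["a"] * 3 + ["b"] * 4 + ["c"] * 3
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 2.0, 4.0, 6.0])
        labels = np.array(groups)
        grand = values.mean()
        ssb = sum(
            (values[labels == g]).size * (values[labels == g].mean() - grand) ** 2
            for g in "abc"
        )
        ssw = sum(((values[labels == g] - values[labels == g].mean()) ** 2).sum() for g in "abc")
        f_oracle = (ssb / 2) / (ssw / 7)
        res = stats.anova_tukey(values, groups)
        assert res.f_stat == pytest.approx(f_oracle, rel=1e-12)

    def test_pairwise_covers_all_pairs_with_valid_p(self, rng):
        values = rng.normal(size=12)
        groups = ["a", "b", "c"] * 4
        res = stats.anova_tukey(values, groups)
        pairs = {frozenset((a, b)) for a, b, _ in res.pairwise}
        assert pairs == {frozenset(p) for p in (("a", "b"), ("a", "c"), ("b", "c"))}
        assert all(0 <= p <= 1 for *_, p in res.pairwise)

    def test_two_groups_equals_pooled_t_test(self, rng):
        a, b = rng.normal(size=8), rng.normal(loc=0.8, size=5)
        res = stats.anova_tukey(np.concatenate([a, b]), ["a"] * 8 + ["b"] * 5)
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_small_group_raises(self):
        with pytest.raises(DegenerateGroupError):
            stats.anova_tukey([1, 2, 3], ["a", "a", "b"])


class TestOls:
    def test_exact_line(self):
        x = np.arange(10.0)
        intercept, coef, r, p = stats.ols_fit(x[:, None], 2 * x + 1)
        assert intercept == pytest.approx(1.0, abs=1e-10)
        assert coef[0] == pytest.approx(2.0, abs=1e-10)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_orthogonal_response_gives_null_slope(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # cor(x, y) = 0
        _, coef, _, p = stats.ols_fit(x[:, None], y)
        assert coef[0] == pytest.approx(0.0, abs=1e-12)
        assert p > 0.5

    def test_matches_pseudoinverse_oracle(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        design = np.column_stack([np.ones(20), X])
        beta_oracle = np.linalg.pinv(design) @ y
        intercept, coef, _, _ = stats.ols_fit(X, y)
        np.testing.assert_allclose([intercept, *coef], beta_oracle, atol=1e-8)

    def test_rank_deficient_design_raises(self):
        x = np.arange(8.0)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(SingularDesignError):
            stats.ols_fit(X, x)


class TestBlandAltman:
    def test_perfect_agreement(self):
        res = stats.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == res.loa_low == res.loa_high == 0.0

    def test_hand_sd_oracle(self):
        # differences (-1, 1): bias 0, SD = sqrt(2)
        res = stats.bland_altman([0.0, 2.0], [1.0, 1.0])
        assert res.bias == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(2.0))

    def test_constant_offset(self):
        res = stats.bland_altman([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert res.bias == pytest.approx(3.0)
        assert res.loa_low == res.loa_high == pytest.approx(3.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20))
    def test_limits_symmetric_about_bias(self, diffs):
        pred = np.asarray(diffs)
        res = stats.bland_altman(pred, np.zeros_like(pred))
        assert res.loa_high - res.bias == pytest.approx(res.bias - res.loa_low, abs=1e-9)

    def test_single_pair_raises(self):
        with pytest.raises(DegenerateInputError):
            stats.bland_altman([1.0], [2.0])
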