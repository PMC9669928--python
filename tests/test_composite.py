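"""LASSO composite model: closed-form oracles, prediction, evaluation."""

import numpy as np
import pandas as pd
import pytest

from sclerolink import PUBLISHED_COMPOSITE, predict_mrss
from sclerolink.composite import (
    CompositeModel,
    evaluate_model,
    lasso_fit,
    lasso_support_path,
)
from sclerolink.errors import DegenerateResponseError, MissingInputError


def orthonormal_design(rng, n=24, p=4):
    """Columns exactly orthogonal, mean 0, sd (ddof=1) 1."""
    m = rng.normal(size=(n, p))
    m = m - m.mean(0)
    q, _ = np.linalg.qr(m)
    q = q - q.mean(0)
    q = q / q.std(0, ddof=1)
    return pd.DataFrame(q, columns=[f"x{j}" for j in range(p)])


class TestLassoFit:
    def test_zero_penalty_equals_ols(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = rng.normal(size=30)
        m = lasso_fit(X, y, lambda_grid=[0.0])
        design = np.column_stack([np.ones(30), X.to_numpy()])
        beta = np.linalg.pinv(design) @ y
        assert m.intercept == pytest.approx(beta[0], abs=1e-6)
        for j, c in enumerate("abc"):
            assert m.coefficients.get(c, 0.0) == pytest.approx(beta[j + 1], abs=1e-6)

    @pytest.mark.parametrize("alpha", [0.1, 0.4, 1.0])
    def test_orthonormal_design_soft_threshold_closed_form(self, rng, alpha):
        X = orthonormal_design(rng)
        n = len(X)
        y = rng.normal(size=n) * 2 + X.to_numpy() @ np.array([1.5, -0.8, 0.0, 0.3])
        m = lasso_fit(X, y, lambda_grid=[alpha])
        rho = X.to_numpy().T @ y / (n - 1)
        thr = n * alpha / (n - 1)
        oracle = np.sign(rho) * np.maximum(np.abs(rho) - thr, 0.0)
        for j, c in enumerate(X.columns):
            assert m.coefficients.get(c, 0.0) == pytest.approx(oracle[j], abs=1e-6)

    def test_support_size_monotone_along_grid(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        X.columns = [f"x{j}" for j in range(6)]
        y = X.to_numpy() @ rng.normal(size=6) + rng.normal(size=40)
        grid = np.geomspace(1e-3, 5.0, 25)
        sizes = lasso_support_path(X, y, grid)  # decreasing penalty order
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_heavy_penalty_gives_empty_model_status(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = rng.normal(size=20)
        m = lasso_fit(X, y, lambda_grid=[1e6])
        assert m.status == "empty"
        assert m.coefficients == {}
        # prediction falls back to the intercept for every sample
        pred = predict_mrss(m, X)
        assert np.allclose(pred, m.intercept)

    def test_constant_response_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 2)), columns=list("ab"))
        with pytest.raises(DegenerateResponseError):
            lasso_fit(X, np.ones(15))

    def test_back_transformed_predictions_match_standardised_space(self, rng):
        X = pd.DataFrame(rng.normal(loc=10, scale=4, size=(30, 3)), columns=list("abc"))
        y = rng.normal(size=30)
        m = lasso_fit(X, y, lambda_grid=[0.2])
        pred = predict_mrss(m, X)
        # standardised-space equivalent prediction
        mu_sd = m.standardization
        zs = pd.DataFrame({c: (X[c] - mu_sd[c][0]) / mu_sd[c][1] for c in X.columns})
        coef_std = {c: m.coefficients.get(c, 0.0) * mu_sd[c][1] for c in X.columns}
        b0_std = m.intercept + sum(m.coefficients.get(c, 0.0) * mu_sd[c][0] for c in X.columns)
        pred_std = b0_std + sum(coef_std[c] * zs[c] for c in X.columns)
        np.testing.assert_allclose(pred, pred_std, atol=1e-10)

    def test_json_round_trip(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = rng.normal(size=20)
        m = lasso_fit(X, y, lambda_grid=[0.1])
        m2 = CompositeModel.from_json(m.to_json())
        assert m2.coefficients == m.coefficients
        assert m2.intercept == m.intercept
        assert m2.standardization == m.standardization


class TestPredictMrss:
    def test_published_equation_worked_example(self):
        zero = {a: 0.0 for a in ("TNC", "COMP", "COL4A1", "SPON1")}
        assert predict_mrss(PUBLISHED_COMPOSITE, zero) == pytest.approx(-25.898)
        ones = {a: 1.0 for a in zero}
        assert predict_mrss(PUBLISHED_COMPOSITE, ones) == pytest.approx(-19.1736)

    def test_unit_increments_recover_each_coefficient(self):
        base = {a: 0.0 for a in PUBLISHED_COMPOSITE.analytes}
        p0 = predict_mrss(PUBLISHED_COMPOSITE, base)
        for analyte, coef in PUBLISHED_COMPOSITE.coefficients.items():
            bumped = dict(base, **{analyte: 1.0})
            assert predict_mrss(PUBLISHED_COMPOSITE, bumped) - p0 == pytest.approx(coef)

    def test_missing_analyte_named_in_error(self):
        with pytest.raises(MissingInputError, match="SPON1"):
            predict_mrss(PUBLISHED_COMPOSITE, {"TNC": 1, "COMP": 1, "COL4A1": 1})

    def test_prediction_is_affine(self, rng):
        a = {k: float(v) for k, v in zip(PUBLISHED_COMPOSITE.analytes, rng.normal(size=4))}
        b = {k: float(v) for k, v in zip(PUBLISHED_COMPOSITE.analytes, rng.normal(size=4))}
        for w in (0.0, 0.3, 0.8, 1.0):
            mix = {k: w * a[k] + (1 - w) * b[k] for k in a}
            expect = w * predict_mrss(PUBLISHED_COMPOSITE, a) + (1 - w) * predict_mrss(PUBLISHED_COMPOSITE, b)
            assert predict_mrss(PUBLISHED_COMPOSITE, mix) == pytest.approx(expect, abs=1e-10)

    def test_clamp_flag(self):
        low = {a: -100.0 for a in PUBLISHED_COMPOSITE.analytes}
        assert predict_mrss(PUBLISHED_COMPOSITE, low, clamp=True) == 0.0


class TestEvaluateModel:
    def identity_model(self):
        return CompositeModel(intercept=0.0, coefficients={"x": 1.0})

    def test_perfect_predictions(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        ev = evaluate_model(self.identity_model(), X, np.arange(10.0))
        assert ev.r_pred_actual == pytest.approx(1.0)
        assert ev.bland_altman.bias == pytest.approx(0.0)

    def test_shuffled_predictions_near_zero(self):
        local = np.random.default_rng(77)
        y = np.arange(40.0)
        X = pd.DataFrame({"x": local.permutation(y)})
        ev = evaluate_model(self.identity_model(), X, y)
        assert abs(ev.r_pred_actual) < 0.35
        assert ev.p > 0.05

    def test_subgroup_anova_runs(self, rng):
        X = pd.DataFrame({"x": np.concatenate([rng.normal(5, 1, 10), rng.normal(0, 1, 10)])})
        y = X["x"].to_numpy() + rng.normal(scale=0.1, size=20)
        groups = ["early"] * 10 + ["hc"] * 10
        ev = evaluate_model(self.identity_model(), X, y, groups=groups)
        assert ev.subgroup_anova is not None
        assert ev.subgroup_anova.p < 0.01

    def test_single_subgroup_skips_anova_with_status(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=8)})
        ev = evaluate_model(self.identity_model(), X, rng.normal(size=8), groups=["a"] * 8)
        assert ev.subgroup_anova is None
        assert "skipped" in ev.anova_status
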