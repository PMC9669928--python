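"""Plasma composite mRSS surrogate.

LASSO regression of mRSS on plasma NPX values of the shared hub analytes
(fit on standardised predictors over a log-spaced penalty grid with
k-fold cross-validated penalty choice), coefficients back-transformed to
the original NPX scale, plus model evaluation: predicted-vs-actual OLS,
Bland-Altman agreement, and subgroup ANOVA of predicted mRSS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .errors import (
    DegenerateGroupError,
    DegenerateInputError,
    DegenerateResponseError,
    MissingInputError,
)
from .stats import AnovaResult, BlandAltmanResult, anova_tukey, bland_altman, ols_fit

__all__ = [
    "CompositeModel",
    "ModelEvaluation",
    "lasso_fit",
    "lasso_support_path",
    "predict_mrss",
    "evaluate_model",
]


@dataclass
class CompositeModel:
    """Sparse linear plasma model for mRSS on the original NPX scale.

    ``coefficients`` holds only the analytes with non-zero weight (mRSS
    units per NPX); ``standardization`` records the per-analyte (mean,
    sd) used during the standardised fit so that predictions on the
    original scale are exactly equivalent.  ``status`` is ``"empty"``
    when the penalty shrank every coefficient to zero.
    """

    intercept: float
    coefficients: dict[str, float]
    lambda_: float = 0.0
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int | None = None
    status: str = "ok"

    @property
    def analytes(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "lambda": self.lambda_,
                "standardization": {k: list(v) for k, v in self.standardization.items()},
                "seed": self.seed,
                "status": self.status,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CompositeModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            lambda_=d["lambda"],
            standardization={k: tuple(v) for k, v in d["standardization"].items()},
            seed=d.get("seed"),
            status=d.get("status", "ok"),
        )


@dataclass
class ModelEvaluation:
    """Predicted-vs-actual fit, agreement limits and subgroup contrast."""

    r_pred_actual: float
    p: float
    bland_altman: BlandAltmanResult
    subgroup_anova: AnovaResult | None = None
    anova_status: str = "ok"


def _prepare(X: pd.DataFrame, y) -> tuple[pd.DataFrame, pd.Series]:
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    complete = X.notna().all(axis=1) & y.notna()
    return X.loc[complete], y.loc[complete]


def lasso_fit(
    X: pd.DataFrame,
    y,
    lambda_grid=None,
    cv_folds: int = 10,
    seed: int = 0,
    max_iter: int = 100_000,
) -> CompositeModel:
    """L1-penalised regression of mRSS on plasma NPX values.

    Predictors are standardised before fitting.  With ``lambda_grid``
    unset, a log-spaced grid is generated and the penalty chosen by
    ``cv_folds``-fold cross-validated mean squared error (minimum rule);
    a single-element grid fixes the penalty (``0`` gives the unpenalised
    least-squares limit).  Coefficients and intercept are back-transformed
    to the original NPX scale; analytes shrunk to zero are excluded from
    the coefficient map, and an all-zero fit returns ``status="empty"``
    rather than raising.
    """
    if X.shape[1] < 2:
        raise DegenerateInputError("need at least 2 candidate analytes")
    X, y = _prepare(X, y)
    n = len(y)
    if y.nunique() <= 1:
        raise DegenerateResponseError("response is constant")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1).replace(0.0, 1.0)
    Xs = ((X - mean) / sd).to_numpy()
    yv = y.to_numpy()

    single = lambda_grid is not None and len(lambda_grid) == 1
    if single:
        alpha = float(lambda_grid[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # alpha=0 coordinate-descent warning
            model = Lasso(alpha=alpha, max_iter=max_iter, tol=1e-10).fit(Xs, yv)
        chosen = alpha
    else:
        if n <= cv_folds:
            raise DegenerateInputError(f"need n > cv_folds ({n} <= {cv_folds})")
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        kwargs = {"alphas": np.asarray(lambda_grid, dtype=float) if lambda_grid is not None else 100}
        model = LassoCV(cv=cv, max_iter=max_iter, tol=1e-8, **kwargs).fit(Xs, yv)
        chosen = float(model.alpha_)

    coef_std = np.asarray(model.coef_)
    coef_orig = coef_std / sd.to_numpy()
    intercept = float(model.intercept_ - (coef_std * (mean / sd).to_numpy()).sum())
    coefficients = {
        a: float(co) for a, cs, co in zip(X.columns, coef_std, coef_orig) if cs != 0.0
    }
    standardization = {a: (float(m), float(s)) for a, m, s in zip(X.columns, mean, sd)}
    status = "ok" if coefficients else "empty"
    return CompositeModel(
        intercept=intercept,
        coefficients=coefficients,
        lambda_=chosen,
        standardization=standardization,
        seed=seed,
        status=status,
    )


def lasso_support_path(X: pd.DataFrame, y, lambda_grid) -> list[int]:
    """Support size at each penalty of a decreasing-penalty grid
    (standardised predictors); used to check shrinkage monotonicity."""
    X, y = _prepare(X, y)
    mean, sd = X.mean(axis=0), X.std(axis=0, ddof=1).replace(0.0, 1.0)
    Xs = ((X - mean) / sd).to_numpy()
    sizes = []
    for alpha in sorted(lambda_grid, reverse=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = Lasso(alpha=float(alpha), max_iter=100_000, tol=1e-10).fit(Xs, y.to_numpy())
        sizes.append(int((m.coef_ != 0).sum()))
    return sizes


def predict_mrss(model: CompositeModel, npx, clamp: bool = False):
    """Linear score ``intercept + sum(coef * NPX)``.

    ``npx`` may be a mapping / Series (one sample) or a DataFrame
    (samples x analytes).  Raw scores are not clipped to the mRSS range
    unless ``clamp=True``.  Missing model analytes raise, naming them.
    """
    if isinstance(npx, pd.DataFrame):
        absent = [a for a in model.analytes if a not in npx.columns]
        if absent:
            raise MissingInputError(f"missing analyte(s): {absent}")
        pred = pd.Series(model.intercept, index=npx.index, dtype=float)
        for a, c in model.coefficients.items():
            pred = pred + c * npx[a].astype(float)
        return pred.clip(0, 51) if clamp else pred
    mapping = dict(npx) if not isinstance(npx, dict) else npx
    absent = [a for a in model.analytes if a not in mapping]
    if absent:
        raise MissingInputError(f"missing analyte(s): {absent}")
    value = model.intercept + sum(c * float(mapping[a]) for a, c in model.coefficients.items())
    return float(np.clip(value, 0, 51)) if clamp else float(value)


def evaluate_model(
    model: CompositeModel,
    X: pd.DataFrame,
    y,
    groups=None,
) -> ModelEvaluation:
    """Predicted-vs-actual OLS (r, p), Bland-Altman limits, and one-way
    ANOVA + Tukey of predicted mRSS across subgroups.

    Evaluation uses only samples with complete prediction inputs and an
    observed mRSS; healthy controls enter the subgroup ANOVA only when a
    ``groups`` vector is supplied covering them.
    """
    X, y = _prepare(X, y)
    predicted = predict_mrss(model, X)
    _, _, r, p = ols_fit(predicted.to_numpy()[:, None], y.to_numpy())
    ba = bland_altman(predicted.to_numpy(), y.to_numpy())
    anova, status = None, "ok"
    if groups is not None:
        g = pd.Series(groups).loc[X.index] if isinstance(groups, pd.Series) else pd.Series(groups, index=X.index)
        try:
            anova = anova_tukey(predicted.to_numpy(), g.to_numpy())
        except DegenerateGroupError as exc:
            status = f"anova skipped: {exc}"
    else:
        status = "anova skipped: no groups supplied"
    return ModelEvaluation(
        r_pred_actual=r, p=p, bland_altman=ba, subgroup_anova=anova, anova_status=status
    )
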