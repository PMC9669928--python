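"""Statistical kernels used by every downstream stage.

Correlations with p-values (Spearman by default, following the study-wide
convention for trait and cross-compartment associations; Pearson available
everywhere), Benjamini-Hochberg multiplicity correction, one-way ANOVA with
Tukey(-Kramer) post-hoc comparisons, ordinary least squares, and
Bland-Altman agreement statistics.

Missing values are handled pairwise-complete for correlations and listwise
for regression, which maximises use of samples when compartments have
unequal availability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateGroupError,
    DegenerateInputError,
    SingularDesignError,
    UndefinedCorrelationError,
)

__all__ = [
    "CorrelationResult",
    "AnovaResult",
    "BlandAltmanResult",
    "spearman",
    "pearson",
    "correlate",
    "cor_matrix",
    "bh_fdr",
    "anova_tukey",
    "ols_fit",
    "bland_altman",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A single correlation with its two-sided p-value.

    ``rho`` lies in [-1, 1]; ``p`` comes from the t-approximation on
    ``rho`` with ``n - 2`` degrees of freedom; ``n`` is the number of
    pairwise-complete observations actually used.
    """

    rho: float
    p: float
    n: int
    method: str


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA F/p plus Tukey HSD adjusted p per group pair."""

    f_stat: float
    p: float
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 1.96*SD limits of agreement for predicted - actual."""

    bias: float
    loa_low: float
    loa_high: float


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DegenerateInputError(
            f"length mismatch: {x.shape[0]} vs {y.shape[0]}"
        )
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise DegenerateInputError(
            f"need at least 3 pairwise-complete observations, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    return x, y


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with t-approximation p-value.

    Ties receive average ranks; positions where either value is missing
    are removed before ranking.
    """
    x, y = _pairwise_complete(x, y)
    res = sps.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), x.size, "spearman")


def pearson(x, y) -> CorrelationResult:
    x, y = _pairwise_complete(x, y)
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), x.size, "pearson")


def correlate(x, y, method: str = "spearman") -> CorrelationResult:
    """Dispatch on ``method`` in {'spearman', 'pearson'}."""
    if method == "spearman":
        return spearman(x, y)
    if method == "pearson":
        return pearson(x, y)
    raise ValueError(f"unknown correlation method: {method!r}")


def cor_matrix(
    a: np.ndarray,
    b: np.ndarray | None = None,
    method: str = "spearman",
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise correlations between rows of ``a`` and rows of ``b``.

    Parameters
    ----------
    a, b
        variable x sample arrays with identical sample columns; ``b``
        defaults to ``a``.  Rows must be complete (no NaN) -- callers with
        missing data should fall back to the scalar functions.

    Returns
    -------
    (rho, p)
        ``rho[i, j]`` correlates ``a[i]`` with ``b[j]``; p-values use the
        t-approximation with ``n - 2`` df.  Rows with zero variance give
        NaN in both outputs.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method: {method!r}")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = a if b is None else np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise DegenerateInputError("sample dimensions differ")
    n = a.shape[1]
    if n < 3:
        raise DegenerateInputError(f"need at least 3 samples, got {n}")

    def _standardise(m: np.ndarray) -> np.ndarray:
        if method == "spearman":
            m = sps.rankdata(m, axis=1)
        m = m - m.mean(axis=1, keepdims=True)
        sd = np.sqrt((m**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = m / sd[:, None]
        out[sd == 0] = np.nan
        return out

    za, zb = _standardise(a), _standardise(b)
    rho = np.clip(za @ zb.T, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df=n - 2))
    p = np.where(np.isnan(rho), np.nan, p)
    return rho, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries propagate as NaN and are excluded from the ranking; the
    input order is preserved.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum() > 0:
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def anova_tukey(values, groups) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc comparisons.

    Unequal group sizes use the Tukey-Kramer generalisation (via the
    studentized-range distribution).  Requires >= 2 groups each with
    >= 2 observations.
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    if values.shape != groups.shape:
        raise DegenerateInputError("values and groups differ in length")
    labels = [g for g in dict.fromkeys(groups)]  # stable unique order
    if len(labels) < 2:
        raise DegenerateGroupError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if s.size < 2:
            raise DegenerateGroupError(f"group {g!r} has fewer than 2 observations")

    grand = values.mean()
    ssb = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssb == 0:
        # no between-group variance: F = 0 by convention, p = 1
        f_stat, p = 0.0, 1.0
    elif ssw == 0:
        f_stat, p = float("inf"), 0.0
    else:
        res = sps.f_oneway(*samples)
        f_stat, p = float(res.statistic), float(res.pvalue)

    pairwise: list[tuple[str, str, float]] = []
    if ssw > 0:
        hsd = sps.tukey_hsd(*samples)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                pairwise.append(
                    (str(labels[i]), str(labels[j]), float(np.clip(hsd.pvalue[i, j], 0, 1)))
                )
    else:
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                same = samples[i].mean() == samples[j].mean()
                pairwise.append((str(labels[i]), str(labels[j]), 1.0 if same else 0.0))
    return AnovaResult(f_stat=f_stat, p=p, pairwise=pairwise)


def ols_fit(X, y) -> tuple[float, np.ndarray, float, float]:
    """Ordinary least squares of ``y`` on columns of ``X``.

    Returns ``(intercept, coefficients, r, p)`` where ``r`` is the Pearson
    correlation between fitted and observed responses and ``p`` the global
    F-test p-value.  Missing values are not allowed (listwise handling is
    the caller's responsibility).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.size != n:
        raise DegenerateInputError("X and y differ in sample count")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DegenerateInputError("missing values are not allowed in OLS")
    if n <= k + 1:
        raise DegenerateInputError(f"need n > predictors + 1 ({n} <= {k + 1})")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    ss_res = ((y - fitted) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        r, p = 0.0, 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0:
            r, p = 1.0, 0.0
        else:
            r = float(np.corrcoef(fitted, y)[0, 1])
            f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
            p = float(sps.f.sf(f, k, n - k - 1))
    return float(beta[0]), beta[1:].copy(), float(r), float(p)


def bland_altman(predicted, actual) -> BlandAltmanResult:
    """Bias and limits of agreement of predicted vs actual.

    ``bias = mean(predicted - actual)``; limits are ``bias +/- 1.96 * SD``
    of the differences (SD with denominator n - 1).
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if predicted.shape != actual.shape:
        raise DegenerateInputError("length mismatch")
    if predicted.size < 2:
        raise DegenerateInputError("need at least 2 paired observations")
    diff = predicted - actual
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)
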