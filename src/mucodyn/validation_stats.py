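"""Model-vs-observation regression statistics.

Ordinary least squares of observed on predicted composition (both
fourth-root transformed by the caller), a joint Wald F-test of
(slope, intercept) = (1, 0), and a Shapiro-Wilk normality check.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionFit",
    "WaldResult",
    "fit_regression",
    "wald_slope_intercept_test",
    "normality_check",
]


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    residuals: np.ndarray
    n: int
    slope_se: float
    intercept_se: float
    _sm_results: object = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_sm_results")
        d["residuals"] = list(self.residuals)
        return d


@dataclass
class WaldResult:
    f_statistic: float
    p_value: float
    df_num: int
    df_denom: int


def fit_regression(observed: np.ndarray, predicted: np.ndarray) -> RegressionFit:
    """OLS of observed (y) on predicted (x).

    R-squared equals the squared Pearson correlation of the simple
    regression. The reported p-value is the F-test of the overall fit.
    """
    y = np.asarray(observed, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if y.size < 3:
        raise ValueError(f"need >= 3 points, got {y.size}")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance; regression undefined")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.f_pvalue),
        residuals=np.asarray(res.resid),
        n=int(y.size),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        _sm_results=res,
    )


def wald_slope_intercept_test(
    fit: RegressionFit, slope0: float = 1.0, intercept0: float = 0.0
) -> WaldResult:
    """Joint Wald F-test of (slope, intercept) = (slope0, intercept0).

    Uses 2 and n-2 degrees of freedom; n = 2 is saturated and rejected.
    A large p-value means the fit is statistically indistinguishable
    from the identity line.
    """
    if fit.n < 3:
        raise ValueError("Wald test needs >= 3 points (model is saturated at n = 2)")
    res = fit._sm_results
    deviation = np.array([fit.intercept - intercept0, fit.slope - slope0])
    if np.max(np.abs(deviation)) < 1e-12:
        # exact null: the covariance quadratic form would be 0/0 on a
        # perfect fit, so short-circuit to F = 0
        return WaldResult(f_statistic=0.0, p_value=1.0, df_num=2, df_denom=fit.n - 2)
    # restriction: [const, slope] = [intercept0, slope0]
    ftest = res.f_test((np.eye(2), np.array([intercept0, slope0])))
    return WaldResult(
        f_statistic=float(ftest.fvalue),
        p_value=float(ftest.pvalue),
        df_num=int(ftest.df_num),
        df_denom=int(ftest.df_denom),
    )


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (informational, never gating)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs >= 3 values")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    stat, p = stats.shapiro(v)
    return float(stat), float(p)
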