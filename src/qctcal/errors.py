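"""Accuracy of asynchronous calibration against in-scan ground truth.

The central statistic is the relative BMD error

    d = (BMD_asyn − BMD_inscan) / BMD_inscan

stored as a dimensionless fraction and reported in per cent at the
presentation layer. Cohort summaries give the mean, sample SD, maximal
absolute error and the R² between the two BMD series; covariate effects
(notably body weight) are quantified by OLS regression of d (%) on the
covariate, and paired differences are tested with Student's paired
t-test. No multiple-testing correction is applied; p-values are reported
per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ErrorRecord",
    "ErrorSummary",
    "RegressionResult",
    "bmd_error",
    "summarize_errors",
    "fit_error_regression",
    "paired_difference_test",
    "regression_root",
]


@dataclass(frozen=True)
class ErrorRecord:
    """One case's paired BMD measurements and covariates."""

    case_id: str
    bmd_inscan: float
    bmd_asyn: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bmd_inscan <= 0:
            raise ValueError("invalid ground truth: bmd_inscan must be positive")

    @property
    def d(self) -> float:
        """Relative BMD error of the asynchronous calibration (fraction)."""
        return bmd_error(self.bmd_asyn, self.bmd_inscan)


@dataclass(frozen=True)
class ErrorSummary:
    """Cohort-level error summary, all error fields in per cent."""

    mean_pct: float
    sd_pct: float
    abs_max_pct: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """OLS of BMD error (%) on a covariate: d ≈ a·x + b."""

    slope: float  # % per covariate unit
    intercept: float  # %
    r_squared: float
    p_value: float
    n: int
    slope_se: float = float("nan")
    intercept_se: float = float("nan")


def bmd_error(bmd_asyn: float, bmd_inscan: float) -> float:
    """Relative BMD error d, with in-scan calibration as ground truth."""
    if bmd_inscan <= 0:
        raise ValueError("invalid ground truth: bmd_inscan must be positive")
    return (bmd_asyn - bmd_inscan) / bmd_inscan


def _as_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["bmd_asyn"].to_numpy(float), records["bmd_inscan"].to_numpy(float)
    asyn = np.array([r.bmd_asyn for r in records], dtype=float)
    inscan = np.array([r.bmd_inscan for r in records], dtype=float)
    return asyn, inscan


def summarize_errors(records) -> ErrorSummary:
    """Mean, sample SD (n−1), max |d| and inter-series R², in per cent.

    Accepts a list of :class:`ErrorRecord` or a cohort DataFrame with
    ``bmd_asyn``/``bmd_inscan`` columns.
    """
    asyn, inscan = _as_arrays(records)
    if asyn.size < 2:
        raise ValueError("insufficient records: need >= 2 for an SD")
    d_pct = 100.0 * (asyn - inscan) / inscan
    if np.ptp(inscan) > 0 and np.ptp(asyn) > 0:
        r2 = float(stats.pearsonr(inscan, asyn)[0] ** 2)
    else:
        r2 = 1.0 if np.allclose(asyn, inscan) else 0.0
    return ErrorSummary(
        mean_pct=float(d_pct.mean()),
        sd_pct=float(d_pct.std(ddof=1)),
        abs_max_pct=float(np.abs(d_pct).max()),
        r_squared=r2,
        n=int(asyn.size),
    )


def fit_error_regression(covariate, d_pct) -> RegressionResult:
    """OLS of BMD error (in %) on a covariate, with two-sided slope p."""
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(d_pct, dtype=float)
    if x.size != y.size:
        raise ValueError("covariate and error lengths differ")
    if x.size < 3:
        raise ValueError("need >= 3 pairs for regression inference")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: zero covariate variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


def paired_difference_test(series_a, series_b):
    """Student's t-test for paired samples; two-sided p.

    Returns ``(t, df, p, mean_difference)``. When every difference is
    identical the t statistic is undefined (zero variance); it is
    reported as 0 with p = 1 and flagged by ``numpy.nan`` degrees of
    freedom left intact — callers should treat a zero-variance pairing
    as "no detectable difference".
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("need >= 2 pairs")
    diff = a - b
    df = a.size - 1
    if np.ptp(diff) == 0:
        return 0.0, df, 1.0, float(diff.mean())
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p), float(diff.mean())


def regression_root(result: RegressionResult | tuple[float, float]) -> float:
    """Covariate value at which the predicted BMD error crosses zero.

    For d = a·x + b this is −b/a; accepts a fitted
    :class:`RegressionResult` or a bare ``(a, b)`` pair.
    """
    if isinstance(result, RegressionResult):
        a, b = result.slope, result.intercept
    else:
        a, b = result
    if a == 0:
        raise ValueError("no root: zero slope")
    return -b / a
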