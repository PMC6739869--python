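"""Microdialysis normalization and dopamine-behavior coupling.

Dialysate is collected in 5-min fractions around a conditioning session: six
baseline fractions, five post-injection fractions before the session, and
seven fractions during the session. Analyte concentrations are normalized as
percent change from the mean of the baseline block,

    pct_change_i = 100 * (conc_i - baseline_mean) / baseline_mean,

so baseline fractions average to zero by construction and the series is
invariant under rescaling all concentrations (probe-recovery differences
between rats drop out). The dopamine-behavior relationship is quantified by
an ordinary least-squares regression of the PavCA index on the session-mean
dopamine percent change.

Incomplete series (missed fractions) are usable down to 4 baseline and 5
session fractions; anything sparser is rejected so a percent change is never
computed from an unstable denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SCHEDULE",
    "MIN_BASELINE_FRACTIONS",
    "MIN_SESSION_FRACTIONS",
    "baseline_mean",
    "percent_change",
    "session_average_change",
    "validate_series",
    "regress_behavior_on_da",
    "RegressionResult",
]

#: complete series: fractions per phase (5-min bins)
SCHEDULE = {"baseline": 6, "pre": 5, "session": 7}
MIN_BASELINE_FRACTIONS = 4
MIN_SESSION_FRACTIONS = 5

_REQUIRED_COLS = {"fraction", "phase", "conc_nM"}


def _check_series(series: pd.DataFrame) -> None:
    missing = _REQUIRED_COLS - set(series.columns)
    if missing:
        raise ValueError(f"series table missing columns {sorted(missing)}")
    if (series["conc_nM"] < 0).any():
        raise ValueError("concentrations must be non-negative")


def validate_series(series: pd.DataFrame) -> bool:
    """True when a single-analyte series is complete enough to normalize.

    Requires >= 4 baseline and >= 5 session fractions (a complete series has
    6 and 7); sparser series are excluded rather than normalized.
    """
    _check_series(series)
    n_base = int((series["phase"] == "baseline").sum())
    n_sess = int((series["phase"] == "session").sum())
    return n_base >= MIN_BASELINE_FRACTIONS and n_sess >= MIN_SESSION_FRACTIONS


def baseline_mean(series: pd.DataFrame) -> float:
    """Arithmetic mean concentration over the baseline-phase fractions."""
    _check_series(series)
    base = series.loc[series["phase"] == "baseline", "conc_nM"]
    if base.empty:
        raise ValueError("series has no baseline fractions")
    mean = float(base.mean())
    if mean <= 0:
        raise ValueError("baseline mean is zero; percent change undefined")
    return mean


def percent_change(series: pd.DataFrame) -> pd.DataFrame:
    """Per-fraction percent change from the baseline mean, all phases included.

    Returns the series with a ``pct_change`` column; baseline fractions
    average to 0 exactly.
    """
    bm = baseline_mean(series)
    out = series.copy()
    out["pct_change"] = 100.0 * (out["conc_nM"] - bm) / bm
    return out


def session_average_change(series: pd.DataFrame) -> float:
    """Mean percent change over the in-session fractions."""
    pct = percent_change(series)
    sess = pct.loc[pct["phase"] == "session", "pct_change"]
    if sess.empty:
        raise ValueError("series has no session fractions")
    return float(sess.mean())


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of behavior on dopamine change, with its F test."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    n: int


def regress_behavior_on_da(
    pct_da: "np.ndarray | list[float]", index: "np.ndarray | list[float]"
) -> RegressionResult:
    """Regress the PavCA index on the session-mean dopamine percent change.

    Ordinary least squares with percent change as the predictor; r-squared is
    the squared Pearson correlation and ``F = r2 (n-2) / (1 - r2)`` on
    (1, n-2) degrees of freedom.
    """
    x = np.asarray(pct_da, dtype=float)
    y = np.asarray(index, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pct_da and index must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    df = (1, n - 2)
    if r2 >= 1.0:
        f_stat = float("inf")
        p = 0.0
    else:
        f_stat = r2 * df[1] / (1.0 - r2)
        p = float(stats.f.sf(f_stat, *df))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        f_statistic=float(f_stat),
        df=df,
        p_value=p,
        n=n,
    )
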