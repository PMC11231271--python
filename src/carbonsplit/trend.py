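"""Long-run linear trend removal and pre-pandemic baseline anomalies.

The secular trend of a (normalized) pollutant series is an ordinary
least-squares fit of value on days elapsed; its slope is conventionally
quoted per decade (× 3652.5 days). Anomalies are either the OLS residuals
(detrended series) or departures from the per-calendar-month mean of the
designated baseline periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import PeriodDefinition
from .errors import DegenerateInputError, InsufficientDataError, MissingBaselineError

__all__ = [
    "DAYS_PER_DECADE",
    "TrendFit",
    "fit_linear_trend",
    "detrend",
    "compute_baseline",
    "baseline_anomaly",
    "monthly_mean",
    "weekly_mean",
]

DAYS_PER_DECADE = 3652.5
MIN_TREND_POINTS = 24


@dataclass(frozen=True)
class TrendFit:
    """OLS trend: slope per day (and per decade), intercept, R², slope p-value."""

    slope_per_day: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    origin: pd.Timestamp
    slope_se: float

    @property
    def slope_per_decade(self) -> float:
        return self.slope_per_day * DAYS_PER_DECADE

    def ci_per_decade(self, z: float = 1.96) -> tuple[float, float]:
        half = z * self.slope_se * DAYS_PER_DECADE
        return (self.slope_per_decade - half, self.slope_per_decade + half)

    def predict(self, dates: pd.DatetimeIndex) -> np.ndarray:
        days = (pd.DatetimeIndex(dates) - self.origin).days.astype(float)
        return self.intercept + self.slope_per_day * days


def monthly_mean(series: pd.Series) -> pd.Series:
    s = series.copy()
    s.index = pd.DatetimeIndex(s.index)
    return s.resample("MS").mean().dropna()


def weekly_mean(series: pd.Series) -> pd.Series:
    s = series.copy()
    s.index = pd.DatetimeIndex(s.index)
    return s.resample("W").mean().dropna()


def fit_linear_trend(series: pd.Series, hac_lags: int | None = None) -> TrendFit:
    """OLS of a date-indexed series on days elapsed since its first point.

    ``hac_lags`` switches the slope's standard error to the Newey–West
    (HAC) estimator — appropriate when residuals are serially correlated,
    as monthly means of emission series typically are; the point estimates
    are unchanged.
    """
    s = series.dropna()
    if len(s) < MIN_TREND_POINTS:
        raise InsufficientDataError(
            f"trend fit needs >= {MIN_TREND_POINTS} points, got {len(s)}"
        )
    idx = pd.DatetimeIndex(s.index)
    origin = idx[0]
    days = (idx - origin).days.astype(float)
    if np.ptp(days) == 0:
        raise DegenerateInputError("constant time axis")
    X = sm.add_constant(days)
    if hac_lags is None:
        fit = sm.OLS(s.to_numpy(), X).fit()
    else:
        fit = sm.OLS(s.to_numpy(), X).fit(
            cov_type="HAC", cov_kwds={"maxlags": int(hac_lags)}
        )
    if np.ptp(s.to_numpy()) == 0.0:  # constant target: define R² = 0, p = 1
        return TrendFit(
            slope_per_day=0.0, intercept=float(s.iloc[0]), r_squared=0.0,
            p_value=1.0, n=int(len(s)), origin=origin, slope_se=0.0,
        )
    return TrendFit(
        slope_per_day=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=int(len(s)),
        origin=origin,
        slope_se=float(fit.bse[1]),
    )


def detrend(series: pd.Series, recenter: bool = False) -> tuple[pd.Series, TrendFit]:
    """Subtract the OLS trend line; optionally add back the series mean.

    The plain anomaly has mean ~0 (an OLS residual property); the recentered
    variant keeps the series' overall level, which keeps downstream level
    analyses (e.g. source attribution inputs) nonnegative.
    """
    s = series.dropna()
    fit = fit_linear_trend(s)
    anomaly = s - fit.predict(pd.DatetimeIndex(s.index))
    if recenter:
        anomaly = anomaly + s.mean()
    return anomaly.rename(series.name), fit


def compute_baseline(
    series: pd.Series, periods: list[PeriodDefinition]
) -> tuple[pd.Series, float]:
    """Per-calendar-month baseline means over the baseline-flagged periods.

    Returns (12-slot monthly baseline, whole-baseline mean). Calendar months
    absent from the baseline data are left missing with a warning.
    """
    baseline_periods = [p for p in periods if p.baseline]
    if not baseline_periods:
        raise MissingBaselineError("no baseline-flagged periods")
    s = series.dropna()
    idx = pd.DatetimeIndex(s.index)
    mask = np.zeros(len(s), dtype=bool)
    for p in baseline_periods:
        mask |= (idx.date >= p.start) & (idx.date <= p.end)
    base = s[mask]
    if base.empty:
        raise MissingBaselineError("baseline periods contain no observations")
    if pd.DatetimeIndex(base.index).month.nunique() < 12:
        import logging

        logging.getLogger(__name__).warning(
            "baseline covers only %d calendar months",
            pd.DatetimeIndex(base.index).month.nunique(),
        )
    by_month = base.groupby(pd.DatetimeIndex(base.index).month).mean()
    monthly = by_month.reindex(range(1, 13))
    monthly.index.name = "calendar_month"
    return monthly, float(base.mean())


def baseline_anomaly(
    series: pd.Series, monthly_baseline: pd.Series
) -> pd.Series:
    """value − matched-calendar-month baseline, per observation."""
    s = series.dropna()
    months = pd.DatetimeIndex(s.index).month
    base_vals = monthly_baseline.reindex(months).to_numpy()
    return pd.Series(s.to_numpy() - base_vals, index=s.index, name=series.name)
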