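"""Transport-volume statistics: day-of-week table, outbreak percent changes,
and regime-wise public-vs-private regressions.

Conventions pinned here (they are the only ones that reproduce the published
day-of-week table from its printed weekly values): arithmetic means,
*population* (n-denominator) standard deviations, rounding half away from
zero at two decimals, and a two-sided Welch t-test for the workday/weekend
comparison.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import PeriodDefinition
from .errors import InsufficientDataError, MissingBaselineError

log = logging.getLogger(__name__)

__all__ = [
    "DayOfWeekStats",
    "SegmentRegression",
    "PercentChange",
    "round2",
    "day_of_week_stats",
    "percent_change",
    "segment_regression",
    "assign_months_to_periods",
]

WEEKDAY_NAMES = [
    "Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday",
]


def round2(x: float, dp: int = 2) -> float:
    """Round half away from zero (the convention of the published table)."""
    q = Decimal(10) ** -dp
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DayOfWeekStats:
    """Per-weekday and pooled workday/weekend metro-volume statistics."""

    per_day: pd.DataFrame  # index weekday name; columns mean, std, n
    workday_mean: float
    workday_std: float
    workday_n: int
    weekend_mean: float
    weekend_std: float
    weekend_n: int
    t_statistic: float
    p_value: float

    def rounded(self, dp: int = 2) -> pd.DataFrame:
        out = self.per_day.copy()
        out["mean"] = out["mean"].map(lambda v: round2(v, dp))
        out["std"] = out["std"].map(lambda v: round2(v, dp))
        return out

    def to_dict(self) -> dict:
        return {
            "per_day": {
                day: {
                    "mean": round2(row["mean"]),
                    "std": round2(row["std"]),
                    "n": int(row["n"]),
                }
                for day, row in self.per_day.iterrows()
            },
            "workday": {
                "mean": round2(self.workday_mean),
                "std": round2(self.workday_std),
                "n": self.workday_n,
            },
            "weekend": {
                "mean": round2(self.weekend_mean),
                "std": round2(self.weekend_std),
                "n": self.weekend_n,
            },
            "welch_t": self.t_statistic,
            "welch_p": self.p_value,
        }


def day_of_week_stats(daily: pd.DataFrame) -> DayOfWeekStats:
    """Day-of-week means/STDs and the Welch workday-vs-weekend test.

    ``daily`` needs columns date, volume; missing volumes are excluded,
    never imputed.
    """
    df = daily.dropna(subset=["volume"]).copy()
    dow = pd.DatetimeIndex(df["date"]).dayofweek
    vols = df["volume"].to_numpy(dtype=float)
    rows = {}
    for d, name in enumerate(WEEKDAY_NAMES):
        v = vols[dow == d]
        if len(v) == 0:
            rows[name] = {"mean": np.nan, "std": np.nan, "n": 0}
        else:
            rows[name] = {"mean": v.mean(), "std": v.std(ddof=0), "n": len(v)}
    work = vols[dow <= 4]
    wend = vols[dow >= 5]
    if len(work) < 2 or len(wend) < 2:
        raise InsufficientDataError("need >= 2 observations in each compared group")
    if work.std() == 0.0 and wend.std() == 0.0 and work.mean() == wend.mean():
        t, p = 0.0, 1.0  # identical groups: no evidence of a difference
    else:
        t, p = stats.ttest_ind(work, wend, equal_var=False)
    per_day = pd.DataFrame(rows).T
    per_day.index.name = "weekday"
    return DayOfWeekStats(
        per_day=per_day,
        workday_mean=float(work.mean()),
        workday_std=float(work.std(ddof=0)),
        workday_n=int(len(work)),
        weekend_mean=float(wend.mean()),
        weekend_std=float(wend.std(ddof=0)),
        weekend_n=int(len(wend)),
        t_statistic=float(t),
        p_value=float(p),
    )


@dataclass(frozen=True)
class PercentChange:
    period: str
    mode: str
    percent: float  # signed; negative means decrease
    n_months: int


@dataclass(frozen=True)
class SegmentRegression:
    period: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_se: float

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        tcrit = stats.t.ppf(1 - alpha / 2, df=max(self.n - 2, 1))
        return (self.slope - tcrit * self.slope_se, self.slope + tcrit * self.slope_se)


def assign_months_to_periods(
    months: pd.DatetimeIndex,
    periods: list[PeriodDefinition],
    min_overlap_days: int = 15,
    overrides: dict | None = None,
) -> pd.Series:
    """Map each month-start timestamp to a period name (or None).

    A month belongs to a period when at least ``min_overlap_days`` of its
    days fall inside it. ``overrides`` ({'YYYY-MM': period_name}) lets
    regime-ambiguous months be pinned explicitly.
    """
    overrides = overrides or {}
    out = {}
    for m in months:
        key = m.strftime("%Y-%m")
        if key in overrides:
            out[m] = overrides[key]
            continue
        month_start = m.date()
        month_end = (m + pd.offsets.MonthEnd(0)).date()
        assigned = None
        for p in periods:
            lo = max(month_start, p.start)
            hi = min(month_end, p.end)
            overlap = (hi - lo).days + 1 if hi >= lo else 0
            if overlap >= min_overlap_days:
                assigned = p.name
                break
        out[m] = assigned
    return pd.Series(out, name="period")


def percent_change(
    volumes: pd.Series,
    periods: list[PeriodDefinition],
    baseline: pd.Series,
    mode: str = "volume",
    min_overlap_days: int = 15,
) -> list[PercentChange]:
    """Percent change of outbreak-period volumes vs the matched-calendar-month
    baseline: 100 × (mean over outbreak months of volume/baseline − 1)."""
    assignment = assign_months_to_periods(
        pd.DatetimeIndex(volumes.index), periods, min_overlap_days
    )
    out = []
    for p in periods:
        if p.baseline:
            continue
        months = assignment[assignment == p.name].index
        if len(months) == 0:
            continue
        ratios = []
        for m in months:
            base = baseline.get(m.month, np.nan)
            if pd.isna(base):
                raise MissingBaselineError(
                    f"no baseline value for calendar month {m.month}"
                )
            ratios.append(volumes.loc[m] / base)
        out.append(
            PercentChange(
                period=p.name,
                mode=mode,
                percent=float(100.0 * (np.mean(ratios) - 1.0)),
                n_months=len(months),
            )
        )
    return out


def segment_regression(
    private_bc: pd.Series,
    public_volume: pd.Series,
    periods: list[PeriodDefinition],
    min_overlap_days: int = 15,
    overrides: dict | None = None,
) -> list[SegmentRegression]:
    """Per-period OLS of monthly private BC on monthly public volume.

    Months are assigned to periods by calendar overlap (never pooled across
    period boundaries); segments with fewer than 3 aligned months are skipped
    with a warning.
    """
    df = pd.concat({"bc": private_bc, "vol": public_volume}, axis=1, join="inner").dropna()
    assignment = assign_months_to_periods(
        pd.DatetimeIndex(df.index), periods, min_overlap_days, overrides
    )
    out = []
    for p in periods:
        seg = df.loc[assignment[assignment == p.name].index.intersection(df.index)]
        if len(seg) < 3:
            if len(seg) > 0:
                log.warning("segment '%s': only %d months, skipped", p.name, len(seg))
            continue
        X = sm.add_constant(seg["vol"].to_numpy())
        fit = sm.OLS(seg["bc"].to_numpy(), X).fit()
        out.append(
            SegmentRegression(
                period=p.name,
                slope=float(fit.params[1]),
                intercept=float(fit.params[0]),
                r_squared=float(fit.rsquared),
                p_value=float(fit.pvalues[1]),
                n=int(len(seg)),
                slope_se=float(fit.bse[1]),
            )
        )
    return out
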