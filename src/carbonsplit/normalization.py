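"""Random-forest weather normalization of daily pollutant series.

A regression forest learns ``pollutant = f(year, month, whole, meteorology)``
where ``whole`` is the number of days since the first observation (a
continuous local-emission trend term). The normalized series is the mean of
the model's predictions when the meteorology block of each day is replaced,
many times over, by complete meteorology rows drawn uniformly with
replacement from the full record — time features stay at their observed
values, so emission structure is preserved while weather-driven variability
averages out. Meteorology rows are resampled jointly (the whole row) to
preserve the covariance between wind, boundary-layer height, temperature and
the rest; resampling columns independently would create weather that never
occurs.

The spread of the resampled predictions (``mc_sd``) is the per-day Monte
Carlo uncertainty; :func:`normalization_uncertainty` adds the across-refit
envelope shown alongside normalized trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import FeatureError, InsufficientDataError
from .synthetic import MET_COLUMNS

__all__ = [
    "TIME_FEATURES",
    "MetModel",
    "build_features",
    "fit_met_model",
    "normalize",
    "normalization_uncertainty",
]

TIME_FEATURES = ["year", "month", "whole"]
MIN_TRAINING_ROWS = 365


def build_features(
    dates: pd.DatetimeIndex, origin: pd.Timestamp | None = None, day_of_week: bool = False
) -> pd.DataFrame:
    """Time features: calendar year, month, and days elapsed since ``origin``."""
    dates = pd.DatetimeIndex(dates)
    if origin is None:
        origin = dates[0]
    out = pd.DataFrame(
        {
            "year": dates.year,
            "month": dates.month,
            "whole": (dates - origin).days.astype(float),
        },
        index=dates,
    )
    if day_of_week:
        out["day_of_week"] = dates.dayofweek
    return out


@dataclass
class MetModel:
    """A fitted weather-normalization forest and its out-of-bag diagnostics."""

    model: RandomForestRegressor
    features: list[str]
    met_features: list[str]
    origin: pd.Timestamp
    oob_r2: float
    oob_rmse: float
    seed: int
    day_of_week: bool = False
    training_met: pd.DataFrame = field(repr=False, default=None)


def _aligned_frame(
    pollutant: pd.Series, met: pd.DataFrame, day_of_week: bool
) -> tuple[pd.DataFrame, pd.Timestamp]:
    """Join target and meteorology by date; drop incomplete rows."""
    met = met.set_index(pd.DatetimeIndex(met["date"]))[MET_COLUMNS]
    y = pollutant.copy()
    y.index = pd.DatetimeIndex(y.index)
    df = met.join(y.rename("__target__"), how="inner").dropna()
    origin = df.index[0] if len(df) else pd.Timestamp("1970-01-01")
    feats = build_features(df.index, origin=origin, day_of_week=day_of_week)
    return pd.concat([feats, df], axis=1), origin


def fit_met_model(
    pollutant: pd.Series,
    met: pd.DataFrame,
    seed: int,
    n_estimators: int = 300,
    min_samples_leaf: int = 5,
    max_features: float = 1.0 / 3.0,
    day_of_week: bool = False,
) -> MetModel:
    """Fit the normalization forest for one pollutant.

    ``pollutant`` is a date-indexed daily series (µg m⁻³); rows with missing
    target or meteorology are dropped; at least 365 complete rows required.
    """
    df, origin = _aligned_frame(pollutant, met, day_of_week)
    if len(df) < MIN_TRAINING_ROWS:
        raise InsufficientDataError(
            f"need >= {MIN_TRAINING_ROWS} complete rows, got {len(df)}"
        )
    features = TIME_FEATURES + (["day_of_week"] if day_of_week else []) + MET_COLUMNS
    rf = RandomForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        max_features=max_features,  # mtry = p/3, the regression-forest default
        oob_score=True,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    y = df["__target__"].to_numpy()
    rf.fit(df[features].to_numpy(), y)
    oob_rmse = float(np.sqrt(np.mean((rf.oob_prediction_ - y) ** 2)))
    return MetModel(
        model=rf,
        features=features,
        met_features=list(MET_COLUMNS),
        origin=origin,
        oob_r2=float(rf.oob_score_),
        oob_rmse=oob_rmse,
        seed=int(seed),
        day_of_week=day_of_week,
        training_met=df[MET_COLUMNS].copy(),
    )


def normalize(
    model: MetModel,
    data: pd.DataFrame,
    n_samples: int = 200,
    seed: int = 0,
    pollutant: str | None = None,
) -> pd.DataFrame:
    """Meteorology-normalize a pollutant series with ``n_samples`` resamples.

    ``data`` must carry ``date`` plus the eight meteorology columns and, when
    ``pollutant`` names a column, the observed concentrations. Returns a
    table with date / observed / normalized / mc_sd / n_samples.
    """
    if n_samples < 1:
        raise FeatureError("n_samples must be >= 1")
    missing = [c for c in model.met_features if c not in data.columns]
    if missing:
        raise FeatureError(f"data lacks meteorology column(s) {missing}")
    dates = pd.DatetimeIndex(data["date"])
    feats = build_features(dates, origin=model.origin, day_of_week=model.day_of_week)
    time_cols = [c for c in model.features if c not in model.met_features]
    time_block = feats[time_cols].to_numpy()

    pool = model.training_met.to_numpy()
    rng = np.random.default_rng(int(seed))
    n_days = len(dates)
    preds = np.empty((n_samples, n_days))
    for s in range(n_samples):
        rows = rng.integers(0, len(pool), size=n_days)
        X = np.column_stack([time_block, pool[rows]])
        preds[s] = model.model.predict(X)
    normalized = np.maximum(preds.mean(axis=0), 0.0)
    mc_sd = preds.std(axis=0, ddof=0)
    observed = (
        pd.to_numeric(data[pollutant], errors="coerce").to_numpy()
        if pollutant is not None and pollutant in data.columns
        else np.full(n_days, np.nan)
    )
    return pd.DataFrame(
        {
            "date": dates,
            "observed": observed,
            "normalized": normalized,
            "mc_sd": mc_sd,
            "n_samples": n_samples,
        }
    )


def normalization_uncertainty(
    pollutant: pd.Series,
    met: pd.DataFrame,
    n_repeats: int = 10,
    n_samples: int = 200,
    seed: int = 0,
    seeds=None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Across-refit envelope: refit + renormalize with ``n_repeats`` seeds.

    Returns per-date min / max / sd of the normalized series over repeats.
    ``seeds`` overrides the default distinct seeds (useful to demonstrate the
    zero-width envelope under equal seeds).
    """
    if n_repeats < 2:
        raise InsufficientDataError("n_repeats must be >= 2")
    if seeds is None:
        seeds = [int(seed) + 1000 * r for r in range(n_repeats)]
    runs = []
    for s in seeds:
        m = fit_met_model(pollutant, met, seed=s, **fit_kwargs)
        res = normalize(m, met, n_samples=n_samples, seed=s)
        runs.append(res.set_index("date")["normalized"])
    stack = pd.concat(runs, axis=1)
    return pd.DataFrame(
        {
            "date": stack.index,
            "min": stack.min(axis=1).to_numpy(),
            "max": stack.max(axis=1).to_numpy(),
            "sd": stack.std(axis=1, ddof=0).to_numpy(),
        }
    )
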