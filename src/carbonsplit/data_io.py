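"""Reading, validation and persistence of the pipeline's tabular inputs.

All tables use an ISO-8601 ``date`` column; joins downstream are always by
calendar date, never by row position, so every reader *rejects* out-of-order
or duplicated dates instead of silently reordering them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PeriodDefinition, default_periods, validate_periods
from .errors import (
    IntegrityError,
    SchemaError,
    SpatialSelectionError,
)

log = logging.getLogger(__name__)

__all__ = [
    "TransportVolumes",
    "read_pollutants",
    "write_pollutants",
    "read_meteorology",
    "write_meteorology",
    "read_epidemic",
    "read_transport_volumes",
    "load_periods",
    "write_json",
    "read_json",
]

POLLUTANT_COLUMNS = ["BC", "NO3", "SO4"]
MET_COLUMNS = ["U10", "V10", "D2M", "T2M", "BLH", "MBLD", "SP", "TP"]


@dataclass
class TransportVolumes:
    """Monthly per-mode passenger volumes plus a daily metro series.

    ``monthly``: year, month, bus_volume, metro_volume, taxi_volume
    (million passengers per month); ``daily_metro``: date, volume
    (million passengers per day).
    """

    monthly: pd.DataFrame
    daily_metro: pd.DataFrame

    def __post_init__(self):
        keys = self.monthly[["year", "month"]].apply(tuple, axis=1)
        if keys.duplicated().any():
            raise IntegrityError("duplicate (year, month) keys in monthly volumes")
        vols = self.monthly.drop(columns=["year", "month"])
        if (vols.to_numpy(dtype=float) < 0).any():
            raise IntegrityError("negative monthly volumes")

    def monthly_series(self, mode: str) -> pd.Series:
        """One mode's monthly volumes indexed by month start timestamp."""
        col = f"{mode}_volume"
        if col not in self.monthly.columns:
            raise SchemaError(f"unknown transport mode '{mode}'")
        idx = pd.DatetimeIndex(
            pd.to_datetime(
                {"year": self.monthly["year"], "month": self.monthly["month"], "day": 1}
            )
        )
        return pd.Series(self.monthly[col].to_numpy(), index=idx, name=col)

    def public_series(self) -> pd.Series:
        return (self.monthly_series("bus") + self.monthly_series("metro")).rename(
            "public_volume"
        )


def _check_dates(dates: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(dates, format="ISO8601", errors="raise")
    if parsed.duplicated().any():
        dup = parsed[parsed.duplicated()].iloc[0]
        raise IntegrityError(f"{what}: duplicate date {dup.date()}")
    if not parsed.is_monotonic_increasing:
        raise IntegrityError(f"{what}: dates are not strictly increasing")
    return parsed


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_pollutants(path) -> pd.DataFrame:
    """Read and validate a daily pollutant table (date, BC, NO3, SO4).

    Unparseable or negative concentration cells become missing; their count
    is logged. Duplicate or unordered dates are rejected.
    """
    df = pd.read_csv(path)
    _require(df, ["date"] + POLLUTANT_COLUMNS, "pollutant table")
    df["date"] = _check_dates(df["date"], "pollutant table")
    n_bad = 0
    for col in POLLUTANT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & (vals < 0) | (df[col].notna() & vals.isna())
        n_bad += int(bad.sum())
        vals[vals < 0] = np.nan
        df[col] = vals
    if n_bad:
        log.warning("pollutant table %s: %d cells set to missing", path, n_bad)
    return df[["date"] + POLLUTANT_COLUMNS]


def write_pollutants(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_meteorology(path, variant: str = "csv", bbox=None) -> pd.DataFrame:
    """Read daily meteorology from CSV or from a CF-style lon/lat/time NetCDF.

    For the gridded variant the eight variables are averaged per day over the
    bounding box ``(lon_min, lon_max, lat_min, lat_max)`` (whole grid when
    ``bbox`` is None).
    """
    if variant == "csv":
        df = pd.read_csv(path)
        _require(df, ["date"] + MET_COLUMNS, "meteorology table")
        df["date"] = _check_dates(df["date"], "meteorology table")
        if (df["BLH"] <= 0).any() or (df["SP"] <= 0).any() or (df["TP"] < 0).any():
            raise IntegrityError("meteorology table: BLH/SP must be > 0 and TP >= 0")
        return df[["date"] + MET_COLUMNS]
    if variant != "netcdf":
        raise SchemaError(f"unknown meteorology variant '{variant}'")

    import xarray as xr

    with xr.open_dataset(path) as ds:
        missing = [v for v in MET_COLUMNS if v not in ds]
        if missing:
            raise SchemaError(f"meteorology NetCDF: missing variable(s) {missing}")
        if bbox is not None:
            lon_min, lon_max, lat_min, lat_max = bbox
            lon = ds["lon"]
            lat = ds["lat"]
            sel = ds.sel(
                lon=lon[(lon >= lon_min) & (lon <= lon_max)],
                lat=lat[(lat >= lat_min) & (lat <= lat_max)],
            )
            if sel.sizes.get("lon", 0) == 0 or sel.sizes.get("lat", 0) == 0:
                raise SpatialSelectionError(
                    f"bounding box {bbox} selects no grid cells"
                )
        else:
            sel = ds
        daily = sel[MET_COLUMNS].mean(dim=["lon", "lat"]).to_dataframe().reset_index()
    daily = daily.rename(columns={"time": "date"})
    daily["date"] = _check_dates(daily["date"], "meteorology NetCDF")
    return daily[["date"] + MET_COLUMNS]


def write_meteorology(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_epidemic(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _require(df, ["date", "cases", "transmission", "fatality", "period"], "epidemic table")
    df["date"] = _check_dates(df["date"], "epidemic table")
    if (df["cases"] < 0).any():
        raise IntegrityError("epidemic table: negative case counts")
    if "variant" not in df.columns:
        df["variant"] = ""
    df["variant"] = df["variant"].fillna("")
    return df[["date", "cases", "transmission", "fatality", "period", "variant"]]


def read_transport_volumes(monthly_path, daily_path=None) -> TransportVolumes:
    monthly = pd.read_csv(monthly_path)
    _require(
        monthly,
        ["year", "month", "bus_volume", "metro_volume", "taxi_volume"],
        "monthly volumes",
    )
    if daily_path is not None:
        daily = pd.read_csv(daily_path)
        _require(daily, ["date", "volume"], "daily metro volumes")
        daily["date"] = _check_dates(daily["date"], "daily metro volumes")
    else:
        daily = pd.DataFrame({"date": pd.DatetimeIndex([]), "volume": []})
    return TransportVolumes(monthly=monthly, daily_metro=daily)


def load_periods(config=None) -> list[PeriodDefinition]:
    """Build the validated, ordered period list from structured config.

    ``config`` may be None (defaults), a list of mappings, or a list of
    :class:`PeriodDefinition`.
    """
    if config is None:
        return validate_periods(default_periods())
    periods = []
    for item in config:
        if isinstance(item, PeriodDefinition):
            periods.append(item)
        else:
            periods.append(
                PeriodDefinition(
                    name=item["name"],
                    start=item["start"],
                    end=item["end"],
                    baseline=bool(item.get("baseline", False)),
                )
            )
    return validate_periods(periods)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (pd.Timestamp,)):
        return obj.strftime("%Y-%m-%d")
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    return obj


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_to_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
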