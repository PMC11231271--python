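"""Configuration objects: synthetic-scenario parameters, analysis periods, seeds.

The default :class:`SyntheticConfig` *is* the study scenario the rest of the
package is tested against: a six-year daily record (2018-01-01 onward) of an
eastern-Chinese city with

* a factory emission component declining by 73.2 % of its initial level per
  decade (2.5 µg m⁻³ × 0.732 ≈ −1.83 µg m⁻³ per decade),
* a transport emission component of 2.0 µg m⁻³ with a ±15 % weekly cycle,
* three epidemic outbreak windows during which public-transport usage is
  suppressed by 16 %, 30 % and 49 % while private-transport emission shifts
  upward, and
* a regime-dependent coupling between monthly public-transport volume and
  private-transport emission: +0.03 µg m⁻³ per million monthly passengers in
  normal regimes, −0.17 during outbreak months.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ConfigError

__all__ = [
    "OutbreakWindow",
    "SyntheticConfig",
    "PeriodDefinition",
    "default_config",
    "default_periods",
    "load_config",
    "substream_seed",
]

PERIOD_NAMES = ("pre", "alpha", "delta", "omicron", "recovery", "post")

#: Named RNG substreams; each generator / stage draws from its own stream so
#: that toggling one stage never shifts another stage's randomness.
_STREAMS = {
    "meteorology": 11,
    "truth": 13,
    "observations": 17,
    "epidemic": 19,
    "volumes": 23,
    "normalize.BC": 29,
    "normalize.NO3": 31,
    "normalize.SO4": 37,
    "attribute": 41,
    "respond": 43,
}


def substream_seed(master_seed: int, stream: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from one master seed."""
    if stream not in _STREAMS:
        raise ConfigError(f"unknown RNG stream '{stream}'")
    ss = np.random.SeedSequence([int(master_seed), _STREAMS[stream]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return dt.date.fromisoformat(str(x))


@dataclass(frozen=True)
class OutbreakWindow:
    """One epidemic outbreak: dates, behavioural forcing, and virus encoding."""

    start: dt.date
    end: dt.date
    suppression: float  # fractional drop of public-transport volume in [0, 1]
    private_shift: float  # fractional rise of private-transport emission in [0, 1]
    transmission: int = 1  # ordinal transmission rank
    fatality: int = 1  # ordinal fatality rank
    case_total: float = 100.0  # expected positive cases over the window
    variant: str = "outbreak"

    def __post_init__(self):
        object.__setattr__(self, "start", _as_date(self.start))
        object.__setattr__(self, "end", _as_date(self.end))
        if self.end < self.start:
            raise ConfigError(f"window '{self.variant}': end before start")
        if not (0.0 <= self.suppression <= 1.0 and 0.0 <= self.private_shift <= 1.0):
            raise ConfigError(
                f"window '{self.variant}': suppression and private_shift must lie in [0, 1]"
            )
        if self.transmission < 1 or self.fatality < 1:
            raise ConfigError(f"window '{self.variant}': ranks must be positive integers")
        if self.case_total < 0:
            raise ConfigError(f"window '{self.variant}': case_total must be >= 0")


def _default_windows() -> tuple[OutbreakWindow, ...]:
    return (
        OutbreakWindow(dt.date(2020, 2, 12), dt.date(2020, 5, 8), 0.16, 0.10, 1, 3, 93.0, "alpha"),
        OutbreakWindow(dt.date(2021, 7, 20), dt.date(2021, 8, 26), 0.30, 0.15, 2, 2, 235.0, "delta"),
        OutbreakWindow(dt.date(2022, 11, 1), dt.date(2022, 12, 31), 0.49, 0.25, 1, 3, 20000.0, "omicron"),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the synthetic emission–dispersion scenario."""

    n_days: int = 2192
    start_date: dt.date = dt.date(2018, 1, 1)
    seed: int = 0

    # emission components, concentration-equivalent µg m^-3
    factory_level: float = 2.5
    factory_trend: float = 0.732  # fraction of factory_level lost per decade
    transport_level: float = 2.0
    weekly_amplitude: float = 0.15
    biomass_spike_rate: float = 12.0  # expected spike events per year
    biomass_spike_mean: float = 2.0  # mean spike magnitude, µg m^-3

    outbreak_windows: tuple[OutbreakWindow, ...] = field(default_factory=_default_windows)

    noise_sd: float = 0.3  # observation noise, µg m^-3
    dispersion_strength: tuple[float, float] = (0.25, 0.35)  # (k_wind, k_blh)
    tracer_gains: tuple[float, float] = (4.0, 3.0)  # (a_no3, b_so4)
    chem_seasonal_amplitude: float = 0.05  # winter-peaking nitrate partitioning

    # meteorology process
    met_ar_coef: float = 0.7
    met_amplitude_scale: float = 1.0
    met_noise_scale: float = 1.0  # scales every AR innovation sd

    # transport volumes (million passengers per day) and coupling
    metro_base: float = 1.5
    bus_base: float = 1.8
    taxi_base: float = 0.6
    volume_monthly_sd: float = 0.025  # stationary sd of the monthly log-level AR(1)
    volume_ar_coef: float = 0.6
    volume_daily_noise: float = 0.02
    coupling_pre: float = 0.03  # µg m^-3 per million monthly passengers
    coupling_pandemic: float = -0.17
    coupling_noise_sd: float = 0.15  # stationary sd of the monthly demand drift
    coupling_noise_ar: float = 0.9  # AR(1) coefficient of the demand drift
    post_start: dt.date = dt.date(2023, 1, 1)

    # holiday calendar: (month, first day, last day), every year
    holidays: tuple[tuple[int, int, int], ...] = ((2, 1, 10),)

    def __post_init__(self):
        object.__setattr__(self, "start_date", _as_date(self.start_date))
        object.__setattr__(self, "post_start", _as_date(self.post_start))
        object.__setattr__(self, "outbreak_windows", tuple(self.outbreak_windows))
        if self.n_days < 1:
            raise ConfigError("n_days must be positive")
        for name in ("factory_level", "transport_level", "noise_sd", "biomass_spike_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        last = self.start_date + dt.timedelta(days=self.n_days - 1)
        for w in self.outbreak_windows:
            if w.start < self.start_date or w.end > last:
                raise ConfigError(
                    f"outbreak window '{w.variant}' ({w.start}..{w.end}) lies outside "
                    f"the date range {self.start_date}..{last}"
                )

    @property
    def end_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=self.n_days - 1)

    def validate_for_analysis(self) -> None:
        """Stricter check used by the pipeline (trend work needs >= 2 years)."""
        if self.n_days < 730:
            raise ConfigError("analysis scenarios require n_days >= 730")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PeriodDefinition:
    """A named analysis period; baseline periods define 'normal' behaviour."""

    name: str
    start: dt.date
    end: dt.date
    baseline: bool = False

    def __post_init__(self):
        object.__setattr__(self, "start", _as_date(self.start))
        object.__setattr__(self, "end", _as_date(self.end))
        if self.end < self.start:
            raise ConfigError(f"period '{self.name}': start must be <= end")

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


def default_periods() -> list[PeriodDefinition]:
    """The default analysis periods: 2018–2019 baseline, three outbreaks,
    an inter-outbreak recovery window and the post-deregulation year."""
    return [
        PeriodDefinition("pre", dt.date(2018, 1, 1), dt.date(2019, 12, 31), baseline=True),
        PeriodDefinition("alpha", dt.date(2020, 2, 12), dt.date(2020, 5, 8)),
        PeriodDefinition("recovery", dt.date(2020, 5, 9), dt.date(2021, 7, 19)),
        PeriodDefinition("delta", dt.date(2021, 7, 20), dt.date(2021, 8, 26)),
        PeriodDefinition("omicron", dt.date(2022, 11, 1), dt.date(2022, 12, 31)),
        PeriodDefinition("post", dt.date(2023, 1, 1), dt.date(2023, 12, 31)),
    ]


def validate_periods(periods: list[PeriodDefinition]) -> list[PeriodDefinition]:
    names = [p.name for p in periods]
    if len(set(names)) != len(names):
        raise ConfigError("period names must be unique")
    unknown = set(names) - set(PERIOD_NAMES)
    if unknown:
        raise ConfigError(f"unknown period names: {sorted(unknown)}")
    if not any(p.baseline for p in periods):
        raise ConfigError("at least one baseline period is required")
    ordered = sorted(periods, key=lambda p: p.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ConfigError(f"periods '{a.name}' and '{b.name}' overlap")
    return ordered


def default_config() -> SyntheticConfig:
    return SyntheticConfig()


def _windows_from_items(items) -> tuple[OutbreakWindow, ...]:
    out = []
    for item in items:
        out.append(
            OutbreakWindow(
                start=item["start"],
                end=item["end"],
                suppression=float(item.get("suppression", 0.0)),
                private_shift=float(item.get("private_shift", 0.0)),
                transmission=int(item.get("transmission", 1)),
                fatality=int(item.get("fatality", 1)),
                case_total=float(item.get("case_total", 100.0)),
                variant=str(item.get("variant", "outbreak")),
            )
        )
    return tuple(out)


def load_config(path) -> dict:
    """Load a YAML config file with [simulate], [periods], [normalization],
    [attribution], [response] sections; absent sections get defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    out: dict = {}

    sim = dict(raw.get("simulate", {}))
    if "outbreak_windows" in sim:
        sim["outbreak_windows"] = _windows_from_items(sim["outbreak_windows"])
    if "dispersion_strength" in sim:
        sim["dispersion_strength"] = tuple(sim["dispersion_strength"])
    if "tracer_gains" in sim:
        sim["tracer_gains"] = tuple(sim["tracer_gains"])
    if "holidays" in sim:
        sim["holidays"] = tuple(tuple(h) for h in sim["holidays"])
    try:
        out["simulate"] = SyntheticConfig(**sim)
    except TypeError as exc:
        raise ConfigError(f"bad [simulate] section: {exc}") from exc

    if "periods" in raw:
        periods = [
            PeriodDefinition(
                name=item["name"],
                start=item["start"],
                end=item["end"],
                baseline=bool(item.get("baseline", False)),
            )
            for item in raw["periods"]
        ]
    else:
        periods = default_periods()
    out["periods"] = validate_periods(periods)

    out["normalization"] = {
        "n_samples": 200, "n_estimators": 300, "min_samples_leaf": 5,
        "use_day_of_week": False,
        **dict(raw.get("normalization", {})),
    }
    out["attribution"] = {
        "reference_quantile": 0.05, "n_estimators": 300, "min_samples_leaf": 25,
        "detrend_before_attribution": False,
        **dict(raw.get("attribution", {})),
    }
    out["response"] = {
        "n_estimators": 200, "min_samples_leaf": 2, "n_grid": 20,
        "n_permutations": 199,
        **dict(raw.get("response", {})),
    }
    out["seed"] = int(raw.get("seed", out["simulate"].seed))
    out["stages"] = raw.get("stages")  # None means every stage
    return out


def default_run_config() -> dict:
    """The in-memory equivalent of loading an empty YAML config file."""
    return {
        "simulate": SyntheticConfig(),
        "periods": validate_periods(default_periods()),
        "normalization": {
            "n_samples": 200, "n_estimators": 300, "min_samples_leaf": 5,
            "use_day_of_week": False,
        },
        "attribution": {
            "reference_quantile": 0.05, "n_estimators": 300, "min_samples_leaf": 25,
            "detrend_before_attribution": False,
        },
        "response": {
            "n_estimators": 200, "min_samples_leaf": 2, "n_grid": 20,
            "n_permutations": 199,
        },
        "seed": 0,
        "stages": None,
    }
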