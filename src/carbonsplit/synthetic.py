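"""Synthetic emission–dispersion scenario generator.

The generator produces every table the analysis chain consumes — daily
meteorology, ground-truth emission components, noisy pollutant observations,
epidemic covariates, and transport volumes — with the statistical structure
the inference assumes:

* ambient concentration = (transport + factory + biomass emission) ×
  multiplicative meteorological dispersion + observation noise;
* nitrate is co-emitted with transport, sulfate with factory sources;
* transport emission carries a weekly cycle, outbreak-window shifts toward
  private transport, and a regime-dependent coupling to public-transport
  volume;
* biomass-burning spikes are more likely on dry days, so weather
  normalization can remove them along with dispersion.

Everything is driven by named substreams of one integer seed: calling any
generator twice with the same :class:`~carbonsplit.config.SyntheticConfig`
returns identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import SyntheticConfig, substream_seed
from .errors import AlignmentError, ConfigError

__all__ = [
    "MET_COLUMNS",
    "SyntheticTruth",
    "SimulationResult",
    "generate_meteorology",
    "generate_truth",
    "generate_observations",
    "generate_epidemic",
    "generate_transport_volumes",
    "simulate",
]

MET_COLUMNS = ["U10", "V10", "D2M", "T2M", "BLH", "MBLD", "SP", "TP"]

# mean, seasonal amplitude, day-of-year of the seasonal peak, AR(1) innovation sd
_MET_PROCESS = {
    "U10": (2.0, 1.0, 15, 0.8),
    "V10": (1.0, 0.8, 200, 0.8),
    "T2M": (289.0, 12.0, 197, 1.5),
    "_DEP": (3.0, 1.5, 15, 1.0),  # dewpoint depression T2M - D2M, kept >= 0
    "BLH": (600.0, 200.0, 197, 80.0),
    "MBLD": (0.4, 0.15, 197, 0.08),
    "SP": (101325.0, 600.0, 15, 250.0),
    "TP": (0.004, 0.003, 197, 0.002),
}

# zero-mean weekly pattern for road-traffic emission, Monday..Sunday
_WEEKLY_PATTERN = np.array([0.4, 0.4, 0.4, 0.4, 0.4, -1.0, -1.0])


def _ar1(rng: np.random.Generator, n: int, coef: float, innov_sd: float) -> np.ndarray:
    """Stationary AR(1) path; coef == 0 degenerates to white noise."""
    x = np.empty(n)
    if innov_sd == 0.0:
        return np.zeros(n)
    stat_sd = innov_sd / np.sqrt(1.0 - coef**2) if abs(coef) < 1 else innov_sd
    x[0] = rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = coef * x[t - 1] + eps[t]
    return x


def _dates(config: SyntheticConfig) -> pd.DatetimeIndex:
    return pd.date_range(config.start_date, periods=config.n_days, freq="D")


def generate_meteorology(config: SyntheticConfig) -> pd.DataFrame:
    """Daily meteorology: seasonal sinusoid + AR(1) perturbation per variable.

    Guarantees D2M <= T2M, BLH > 0 and TP >= 0 on every day.
    """
    if config.n_days < 1:
        raise ConfigError("n_days must be positive")
    rng = np.random.default_rng(substream_seed(config.seed, "meteorology"))
    dates = _dates(config)
    doy = dates.dayofyear.to_numpy()
    out = {"date": dates}
    raw = {}
    for name, (mean, amp, peak, sd) in _MET_PROCESS.items():
        seasonal = config.met_amplitude_scale * amp * np.cos(
            2 * np.pi * (doy - peak) / 365.25
        )
        raw[name] = mean + seasonal + _ar1(
            rng, config.n_days, config.met_ar_coef, config.met_noise_scale * sd
        )
    out["U10"] = raw["U10"]
    out["V10"] = raw["V10"]
    out["T2M"] = raw["T2M"]
    out["D2M"] = raw["T2M"] - np.maximum(raw["_DEP"], 0.0)
    out["BLH"] = np.maximum(raw["BLH"], 50.0)
    out["MBLD"] = np.maximum(raw["MBLD"], 0.01)
    out["SP"] = raw["SP"]
    out["TP"] = np.maximum(raw["TP"], 0.0)
    return pd.DataFrame(out)[["date"] + MET_COLUMNS]


def _window_masks(config: SyntheticConfig, dates: pd.DatetimeIndex):
    """Per-day suppression / private-shift vectors and window membership."""
    d = dates.date
    suppression = np.zeros(len(dates))
    shift = np.zeros(len(dates))
    in_window = np.zeros(len(dates), dtype=bool)
    forcing = np.zeros(len(dates), dtype=bool)
    for w in config.outbreak_windows:
        mask = (d >= w.start) & (d <= w.end)
        suppression[mask] = w.suppression
        shift[mask] = w.private_shift
        in_window |= mask
        if w.suppression > 0 or w.private_shift > 0:
            forcing |= mask
    return suppression, shift, in_window, forcing


def _month_regimes(config: SyntheticConfig, dates: pd.DatetimeIndex, forcing: np.ndarray):
    """Label each calendar month: pre / pandemic / recovery / post.

    A month is 'pandemic' when at least 15 of its days fall inside an
    outbreak window — the same overlap rule the segment regressions use, so
    regime-dependent coupling and regime assignment never disagree.
    """
    months = dates.to_period("M")
    days_in = pd.Series(forcing, index=months).groupby(level=0).sum()
    first_start = min((w.start for w in config.outbreak_windows), default=None)
    regimes = {}
    for m, n_in in days_in.items():
        if n_in >= 15:
            regimes[m] = "pandemic"
        elif m.start_time.date() >= config.post_start:
            regimes[m] = "post"
        elif first_start is None or m.end_time.date() < first_start:
            regimes[m] = "pre"
        else:
            regimes[m] = "recovery"
    return months, regimes


@dataclass
class SyntheticTruth:
    """Ground-truth daily components and the config that produced them.

    ``table`` columns: date, E_transport, E_factory, E_biomass,
    dispersion_factor, metro_volume, bus_volume, taxi_volume, public_volume
    (all volumes in million passengers/day), regime, suppression,
    private_shift, in_window.
    """

    table: pd.DataFrame
    config: SyntheticConfig

    def monthly(self) -> pd.DataFrame:
        """Monthly aggregates: mean emissions, volume × 30 days/month."""
        t = self.table.set_index("date")
        g = t.resample("MS")
        out = g[["E_transport", "E_factory", "E_biomass", "dispersion_factor"]].mean()
        for col in ("metro_volume", "bus_volume", "taxi_volume", "public_volume"):
            out[col] = g[col].mean() * 30.0
        out["regime"] = g["regime"].first()
        return out


def generate_truth(config: SyntheticConfig, met: pd.DataFrame) -> SyntheticTruth:
    """Ground-truth emissions, dispersion, and transport volumes.

    Transport volumes share one citywide monthly AR(1) activity level; the
    private-transport emission responds to the *deviation* of realized public
    volume from its expected (suppression-adjusted) level with a slope that
    switches sign between normal and pandemic regimes.
    """
    dates = _dates(config)
    met_dates = pd.DatetimeIndex(met["date"])
    if len(met_dates) < len(dates) or not dates.isin(met_dates).all():
        raise AlignmentError("meteorology table does not cover the configured date range")
    met = met.set_index("date").loc[dates]

    rng = np.random.default_rng(substream_seed(config.seed, "truth"))
    n = config.n_days
    suppression, shift, in_window, forcing = _window_masks(config, dates)
    # only windows that actually force behaviour (suppression or shift > 0)
    # define the pandemic coupling regime; a null window composes to the null
    months, regimes = _month_regimes(config, dates, forcing)
    month_list = months.unique()

    # --- transport volumes -------------------------------------------------
    innov = config.volume_monthly_sd * np.sqrt(1 - config.volume_ar_coef**2)
    s_m = pd.Series(
        _ar1(rng, len(month_list), config.volume_ar_coef, innov), index=month_list
    )
    s_d = s_m.reindex(months).to_numpy()
    base = {"metro": config.metro_base, "bus": config.bus_base, "taxi": config.taxi_base}
    vols = {}
    for mode, level in base.items():
        noise = rng.normal(0.0, config.volume_daily_noise, size=n)
        vols[mode] = np.maximum(
            level * np.exp(s_d) * (1.0 - suppression) * (1.0 + noise), 0.0
        )
    public = vols["metro"] + vols["bus"]

    # realized vs expected monthly public volume (million passengers/month)
    pub_s = pd.Series(public, index=months)
    p_m = pub_s.groupby(level=0).mean() * 30.0
    expected_daily = (config.metro_base + config.bus_base) * (1.0 - suppression)
    p_hat = pd.Series(expected_daily, index=months).groupby(level=0).mean() * 30.0
    # Coupling reference: a month's own expected volume in normal regimes, but
    # the *window mean* of the expected volumes across a window's pandemic
    # months — so within one outbreak the months line up on the coupling
    # slope (public drops further -> private rises further) while the jump
    # between windows of different severity carries no coupling response.
    reference = p_hat.copy()
    d = dates.date
    for w in config.outbreak_windows:
        overlap = pd.Series((d >= w.start) & (d <= w.end), index=months).groupby(level=0).sum()
        w_months = [
            m for m, n_in in overlap.items()
            if n_in >= 15 and regimes.get(m) == "pandemic"
        ]
        if w_months:
            reference.loc[w_months] = p_hat.loc[w_months].mean()
    deviation = (p_m - reference).reindex(months).to_numpy()

    # --- transport emission ------------------------------------------------
    beta = np.array(
        [config.coupling_pandemic if regimes[m] == "pandemic" else config.coupling_pre
         for m in month_list]
    )
    beta_d = pd.Series(beta, index=month_list).reindex(months).to_numpy()
    # slowly drifting transport demand: AR(1) at monthly resolution, so the
    # emission signal is smooth enough for time features to identify it
    drift_innov = config.coupling_noise_sd * np.sqrt(1 - config.coupling_noise_ar**2)
    eps_m = pd.Series(
        _ar1(rng, len(month_list), config.coupling_noise_ar, drift_innov),
        index=month_list,
    ).reindex(months).to_numpy()
    weekly = 1.0 + config.weekly_amplitude * _WEEKLY_PATTERN[dates.dayofweek]
    e_transport = np.maximum(
        config.transport_level * weekly * (1.0 + shift) + beta_d * deviation + eps_m,
        0.0,
    )

    # --- factory emission: slow secular decline ----------------------------
    years = np.arange(n) / 365.25
    e_factory = np.maximum(
        config.factory_level * (1.0 - config.factory_trend * years / 10.0), 0.0
    )

    # --- biomass burning: sparse spikes, more likely when precipitation is low
    tp = met["TP"].to_numpy()
    p_base = config.biomass_spike_rate / 365.25
    dry = tp < np.quantile(tp, 0.3)
    p_spike = np.where(dry, 3.0 * p_base, (1.0 - 3.0 * 0.3) / 0.7 * p_base)
    spike = rng.random(n) < p_spike
    e_biomass = np.where(spike, rng.exponential(config.biomass_spike_mean, size=n), 0.0)

    # --- multiplicative dispersion -----------------------------------------
    k_w, k_b = config.dispersion_strength
    wind = np.hypot(met["U10"].to_numpy(), met["V10"].to_numpy())
    blh = met["BLH"].to_numpy()

    def _z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    dispersion = np.exp(-k_w * _z(wind) - k_b * _z(blh))

    regime_d = np.array([regimes[m] for m in months])
    table = pd.DataFrame(
        {
            "date": dates,
            "E_transport": e_transport,
            "E_factory": e_factory,
            "E_biomass": e_biomass,
            "dispersion_factor": dispersion,
            "metro_volume": vols["metro"],
            "bus_volume": vols["bus"],
            "taxi_volume": vols["taxi"],
            "public_volume": public,
            "regime": regime_d,
            "suppression": suppression,
            "private_shift": shift,
            "in_window": in_window,
        }
    )
    return SyntheticTruth(table=table, config=config)


def generate_observations(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Noisy pollutant observations from the ground truth.

    BC observes the total emission through the dispersion factor; NO3 and SO4
    are tracer species proportional to the transport and factory components.
    Nitrate additionally carries a winter-peaking gas–particle partitioning
    factor that meteorological normalization does not remove.
    """
    t = truth.table
    dates = pd.DatetimeIndex(t["date"])
    if len(dates) != config.n_days or dates[0].date() != config.start_date:
        raise AlignmentError("truth table is not aligned with the configuration dates")
    rng = np.random.default_rng(substream_seed(config.seed, "observations"))
    disp = t["dispersion_factor"].to_numpy()
    total = (t["E_transport"] + t["E_factory"] + t["E_biomass"]).to_numpy()
    a_no3, b_so4 = config.tracer_gains
    doy = dates.dayofyear.to_numpy()
    chem = 1.0 + config.chem_seasonal_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)

    n = len(dates)
    bc = total * disp + rng.normal(0.0, config.noise_sd, size=n)
    no3 = a_no3 * t["E_transport"].to_numpy() * disp * chem + rng.normal(
        0.0, config.noise_sd, size=n
    )
    so4 = b_so4 * t["E_factory"].to_numpy() * disp + rng.normal(
        0.0, config.noise_sd, size=n
    )
    return pd.DataFrame(
        {
            "date": dates,
            "BC": np.maximum(bc, 0.0),
            "NO3": np.maximum(no3, 0.0),
            "SO4": np.maximum(so4, 0.0),
        }
    )


def _holiday_mask(config: SyntheticConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    mask = np.zeros(len(dates), dtype=bool)
    month = dates.month.to_numpy()
    day = dates.day.to_numpy()
    for m, d0, d1 in config.holidays:
        mask |= (month == m) & (day >= d0) & (day <= d1)
    return mask


def generate_epidemic(config: SyntheticConfig) -> pd.DataFrame:
    """Daily case counts, ordinal virus ranks, and calendar period flags.

    Cases are zero outside outbreak windows; inside each window they follow a
    seeded log-normal epidemic pulse whose expected total is the window's
    ``case_total`` (Poisson-sampled day by day).
    """
    rng = np.random.default_rng(substream_seed(config.seed, "epidemic"))
    dates = _dates(config)
    d = dates.date
    n = len(dates)
    cases = np.zeros(n, dtype=np.int64)
    transmission = np.zeros(n, dtype=np.int64)
    fatality = np.zeros(n, dtype=np.int64)
    variant = np.array([""] * n, dtype=object)
    for w in config.outbreak_windows:
        mask = (d >= w.start) & (d <= w.end)
        idx = np.flatnonzero(mask)
        length = len(idx)
        if length == 0:
            continue
        day_in = np.arange(1, length + 1)
        shape = stats.lognorm.pdf(day_in, s=0.6, scale=max(length / 3.0, 1.0))
        shape = shape / shape.sum() if shape.sum() > 0 else np.full(length, 1.0 / length)
        cases[idx] = rng.poisson(w.case_total * shape)
        transmission[idx] = w.transmission
        fatality[idx] = w.fatality
        variant[idx] = w.variant
    holiday = _holiday_mask(config, dates)
    weekend = dates.dayofweek >= 5
    period = np.where(holiday, "legal-vacation", np.where(weekend, "weekend", "workday"))
    return pd.DataFrame(
        {
            "date": dates,
            "cases": cases,
            "transmission": transmission,
            "fatality": fatality,
            "period": period,
            "variant": variant,
        }
    )


def generate_transport_volumes(truth: SyntheticTruth):
    """Monthly per-mode volumes (million passengers/month, 30-day months)
    and the daily metro series, as a :class:`~carbonsplit.data_io.TransportVolumes`."""
    from .data_io import TransportVolumes

    t = truth.table.set_index("date")
    g = t.resample("MS")
    monthly = pd.DataFrame(
        {
            "bus_volume": g["bus_volume"].mean() * 30.0,
            "metro_volume": g["metro_volume"].mean() * 30.0,
            "taxi_volume": g["taxi_volume"].mean() * 30.0,
        }
    )
    monthly.insert(0, "month", monthly.index.month)
    monthly.insert(0, "year", monthly.index.year)
    monthly = monthly.reset_index(drop=True)
    daily_metro = truth.table[["date", "metro_volume"]].rename(
        columns={"metro_volume": "volume"}
    )
    return TransportVolumes(monthly=monthly, daily_metro=daily_metro)


@dataclass
class SimulationResult:
    """All generated tables of one scenario run."""

    config: SyntheticConfig
    meteorology: pd.DataFrame
    truth: SyntheticTruth
    pollutants: pd.DataFrame
    epidemic: pd.DataFrame
    volumes: "object"  # TransportVolumes

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iso = lambda df: df.assign(date=pd.DatetimeIndex(df["date"]).strftime("%Y-%m-%d"))
        iso(self.meteorology).to_csv(out / "meteorology.csv", index=False)
        iso(self.truth.table).to_csv(out / "truth.csv", index=False)
        iso(self.pollutants).to_csv(out / "pollutants.csv", index=False)
        iso(self.epidemic).to_csv(out / "epidemic.csv", index=False)
        self.volumes.monthly.to_csv(out / "volumes_monthly.csv", index=False)
        iso(self.volumes.daily_metro).to_csv(out / "metro_daily.csv", index=False)


def simulate(config: SyntheticConfig) -> SimulationResult:
    """Run every generator in dependency order for one scenario."""
    met = generate_meteorology(config)
    truth = generate_truth(config, met)
    pollutants = generate_observations(truth, config)
    epidemic = generate_epidemic(config)
    volumes = generate_transport_volumes(truth)
    return SimulationResult(config, met, truth, pollutants, epidemic, volumes)
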