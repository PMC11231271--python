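"""Generator contracts: determinism, degenerate limits, forcing recovery."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from carbonsplit import default_config, simulate
from carbonsplit.config import OutbreakWindow, SyntheticConfig
from carbonsplit.errors import AlignmentError, ConfigError
from carbonsplit.synthetic import (
    MET_COLUMNS,
    generate_epidemic,
    generate_meteorology,
    generate_observations,
    generate_truth,
)


class TestMeteorology:
    def test_identical_seed_gives_identical_tables(self):
        cfg = default_config().with_(seed=1, n_days=400, outbreak_windows=())
        assert generate_meteorology(cfg).equals(generate_meteorology(cfg))

    def test_degenerate_process_is_constant(self):
        """Zero AR/noise and zero amplitudes leave each column at its mean."""
        cfg = default_config().with_(
            n_days=200, met_ar_coef=0.0, met_amplitude_scale=0.0,
            met_noise_scale=0.0, outbreak_windows=(),
        )
        met = generate_meteorology(cfg)
        from carbonsplit.synthetic import _MET_PROCESS

        for col in MET_COLUMNS:
            if col == "D2M":
                expected = _MET_PROCESS["T2M"][0] - _MET_PROCESS["_DEP"][0]
            else:
                expected = _MET_PROCESS[col][0]
            assert np.allclose(met[col], expected), col

    def test_physical_invariants(self):
        met = generate_meteorology(default_config().with_(n_days=1500, seed=3, outbreak_windows=()))
        assert (met["D2M"] <= met["T2M"]).all()
        assert (met["BLH"] > 0).all()
        assert (met["TP"] >= 0).all()

    def test_lag1_autocorrelation_matches_ar_coefficient(self):
        """Sample ACF of deseasonalized T2M recovers the configured AR coefficient."""
        cfg = default_config().with_(n_days=2192, seed=7)
        met = generate_meteorology(cfg)
        doy = pd.DatetimeIndex(met["date"]).dayofyear.to_numpy()
        seasonal = 12.0 * np.cos(2 * np.pi * (doy - 197) / 365.25)
        resid = met["T2M"].to_numpy() - 289.0 - seasonal
        acf1 = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert abs(acf1 - cfg.met_ar_coef) < 0.1

    def test_invalid_n_days_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_days=0)


class TestTruth:
    def test_null_forcing_equals_no_outbreak_run(self):
        base = default_config().with_(seed=5)
        null_windows = tuple(
            OutbreakWindow(w.start, w.end, 0.0, 0.0, w.transmission, w.fatality,
                           w.case_total, w.variant)
            for w in base.outbreak_windows
        )
        met = generate_meteorology(base)
        t_null = generate_truth(base.with_(outbreak_windows=null_windows), met)
        t_none = generate_truth(base.with_(outbreak_windows=()), met)
        cols = ["E_transport", "E_factory", "E_biomass", "public_volume"]
        pd.testing.assert_frame_equal(t_null.table[cols], t_none.table[cols])

    def test_zero_dispersion_strength_gives_unit_factor(self):
        cfg = default_config().with_(
            dispersion_strength=(0.0, 0.0), n_days=750, outbreak_windows=()
        )
        met = generate_meteorology(cfg)
        truth = generate_truth(cfg, met)
        assert np.allclose(truth.table["dispersion_factor"], 1.0)

    def test_suppression_049_gives_volume_ratio_051(self, default_sim):
        """The omicron window (suppression 0.49) drops public volume to ~51 %
        of the matched-calendar-month baseline."""
        t = default_sim.truth.table.set_index("date")
        win = t.loc["2022-11-01":"2022-12-31", "public_volume"].mean()
        base = t.loc[
            (t.index.month.isin([11, 12])) & (t.index.year.isin([2018, 2019])),
            "public_volume",
        ].mean()
        assert win / base == pytest.approx(0.51, abs=0.02)

    def test_window_outside_range_rejected(self):
        with pytest.raises(ConfigError):
            default_config().with_(n_days=400)  # default windows end in 2022

    def test_within_window_association_is_negative(self, default_sim):
        """Suppression/private-shift induce a negative public-volume vs
        transport-emission association across pandemic months."""
        m = default_sim.truth.monthly()
        pan = m[m["regime"] == "pandemic"]
        r = np.corrcoef(pan["public_volume"], pan["E_transport"])[0, 1]
        assert r < 0

    def test_factory_decline_matches_configured_trend(self):
        cfg = default_config()
        met = generate_meteorology(cfg)
        truth = generate_truth(cfg, met)
        e = truth.table.set_index("date")["E_factory"]
        per_decade = (e.iloc[-1] - e.iloc[0]) / (len(e) - 1) * 3652.5
        assert per_decade == pytest.approx(-cfg.factory_level * cfg.factory_trend, rel=1e-3)

    def test_misaligned_met_rejected(self):
        cfg = default_config().with_(n_days=750, outbreak_windows=())
        met = generate_meteorology(cfg).iloc[:-100]
        with pytest.raises(AlignmentError):
            generate_truth(cfg, met)


class TestObservations:
    def test_zero_noise_identity(self):
        """With no noise, unit dispersion and no biomass, BC equals the sum of
        transport and factory emission exactly."""
        cfg = default_config().with_(
            noise_sd=0.0, dispersion_strength=(0.0, 0.0), biomass_spike_rate=0.0,
        )
        sim = simulate(cfg)
        t = sim.truth.table
        np.testing.assert_allclose(
            sim.pollutants["BC"], t["E_transport"] + t["E_factory"], atol=1e-12
        )

    def test_tracer_proportionality(self):
        cfg = default_config().with_(noise_sd=0.0, factory_level=0.0)
        sim = simulate(cfg)
        assert np.allclose(sim.pollutants["SO4"], 0.0)

    def test_dispersion_degrades_raw_correlation(self, default_sim):
        """Dividing out the true dispersion factor must improve the correlation
        between observed BC and total emission."""
        t = default_sim.truth.table
        total = (t["E_transport"] + t["E_factory"] + t["E_biomass"]).to_numpy()
        bc = default_sim.pollutants["BC"].to_numpy()
        disp = t["dispersion_factor"].to_numpy()
        r_raw = np.corrcoef(bc, total)[0, 1]
        r_corr = np.corrcoef(bc / disp, total)[0, 1]
        assert r_raw < r_corr

    def test_determinism(self):
        cfg = default_config().with_(seed=11, n_days=750, outbreak_windows=())
        a = simulate(cfg).pollutants
        b = simulate(cfg).pollutants
        pd.testing.assert_frame_equal(a, b)


class TestEpidemic:
    def test_no_windows_means_no_cases(self):
        cfg = default_config().with_(outbreak_windows=(), n_days=750)
        epi = generate_epidemic(cfg)
        assert (epi["cases"] == 0).all()

    def test_printed_ordinal_encoding_attached_per_window(self):
        """The default windows carry the published (transmission, fatality)
        ranks: alpha (1,3), delta (2,2), omicron (1,3)."""
        epi = generate_epidemic(default_config())
        by_variant = (
            epi[epi["variant"] != ""]
            .groupby("variant")[["transmission", "fatality"]]
            .agg(["min", "max"])
        )
        assert tuple(by_variant.loc["alpha"].values) == (1, 1, 3, 3)
        assert tuple(by_variant.loc["delta"].values) == (2, 2, 2, 2)
        assert tuple(by_variant.loc["omicron"].values) == (1, 1, 3, 3)

    def test_pulse_total_matches_configuration(self):
        """Summed cases inside a window match its configured total within a
        Poisson-scale bound."""
        epi = generate_epidemic(default_config())
        d = pd.DatetimeIndex(epi["date"]).date
        for w in default_config().outbreak_windows:
            total = epi.loc[(d >= w.start) & (d <= w.end), "cases"].sum()
            assert abs(total - w.case_total) <= 4 * np.sqrt(w.case_total) + 1

    def test_period_flags(self):
        epi = generate_epidemic(default_config().with_(n_days=750, outbreak_windows=()))
        dates = pd.DatetimeIndex(epi["date"])
        feb5 = epi.loc[(dates.month == 2) & (dates.day == 5), "period"]
        assert (feb5 == "legal-vacation").all()
        sundays = epi.loc[(dates.dayofweek == 6) & ~((dates.month == 2) & (dates.day <= 10)), "period"]
        assert (sundays == "weekend").all()


class TestConfigProperties:
    @given(
        supp=st.floats(0, 1),
        shift=st.floats(0, 1),
        seed=st.integers(0, 2**20),
    )
    def test_any_valid_window_produces_nonnegative_emissions(self, supp, shift, seed):
        cfg = default_config().with_(
            n_days=760,
            seed=seed,
            outbreak_windows=(
                OutbreakWindow(dt.date(2019, 3, 1), dt.date(2019, 4, 15), supp, shift),
            ),
        )
        met = generate_meteorology(cfg)
        truth = generate_truth(cfg, met)
        obs = generate_observations(truth, cfg)
        for col in ("E_transport", "E_factory", "E_biomass"):
            assert (truth.table[col] >= 0).all()
        assert (truth.table["dispersion_factor"] > 0).all()
        assert (obs[["BC", "NO3", "SO4"]] >= 0).all().all()

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigError):
            OutbreakWindow(dt.date(2019, 1, 1), dt.date(2019, 2, 1), 1.2, 0.0)
        with pytest.raises(ConfigError):
            OutbreakWindow(dt.date(2019, 1, 1), dt.date(2018, 2, 1), 0.2, 0.0)
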