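"""Monthly-panel response models: aggregation, partial dependence, permutation test."""

import numpy as np
import pandas as pd
import pytest

from carbonsplit.errors import FeatureError, InsufficientDataError
from carbonsplit.response import (
    RESPONSE_FEATURES,
    ResponseModel,
    build_monthly_panel,
    feature_effect_test,
    fit_response_model,
    partial_dependence,
)


class TestBuildMonthlyPanel:
    def test_panel_has_one_row_per_covered_month(self, truth_panel):
        assert len(truth_panel) == 73  # 2192 days span 73 calendar months

    def test_single_month_aggregates_hand_computed(self, default_sim):
        split = default_sim.truth.table[["date", "E_transport"]].rename(
            columns={"E_transport": "bc_transport"}
        )
        panel = build_monthly_panel(
            split, default_sim.volumes, default_sim.meteorology, default_sim.epidemic
        )
        jan = panel.loc[pd.Timestamp("2018-01-01")]
        met_jan = default_sim.meteorology.set_index("date").loc["2018-01"]
        assert jan["T2M"] == pytest.approx(met_jan["T2M"].mean())
        assert jan["TP"] == pytest.approx(met_jan["TP"].sum())
        epi_jan = default_sim.epidemic.set_index("date").loc["2018-01"]
        assert jan["cases"] == epi_jan["cases"].sum()
        truth_jan = default_sim.truth.table.set_index("date").loc["2018-01"]
        assert jan["bc_private"] == pytest.approx(truth_jan["E_transport"].mean())

    def test_outbreak_free_month_has_zero_epidemic_covariates(self, truth_panel):
        row = truth_panel.loc[pd.Timestamp("2019-06-01")]
        assert row["transmission"] == 0 and row["fatality"] == 0 and row["cases"] == 0

    def test_outbreak_month_carries_window_ranks(self, truth_panel):
        row = truth_panel.loc[pd.Timestamp("2021-08-01")]  # delta
        assert row["transmission"] == 2 and row["fatality"] == 2
        assert row["cases"] > 0

    def test_february_vacation_share(self, truth_panel):
        assert truth_panel.loc[pd.Timestamp("2018-02-01"), "vacation_share"] == pytest.approx(10 / 28)


class TestFitResponseModel:
    def test_target_leak_gives_near_perfect_oob(self):
        """With the target smuggled in as a feature, out-of-bag skill is
        near-perfect — the OOB diagnostic would expose such leakage.

        Uses a long outbreak-free scenario so the target's support is dense
        (out-of-bag predictions interpolate between neighbouring leak values;
        isolated outlier months would bound OOB R² away from 1 for any model).
        """
        from carbonsplit import default_config, simulate

        sim = simulate(default_config().with_(n_days=3650, outbreak_windows=(), seed=9))
        split = sim.truth.table[["date", "E_transport"]].rename(
            columns={"E_transport": "bc_transport"}
        )
        panel = build_monthly_panel(
            split, sim.volumes, sim.meteorology, sim.epidemic
        )
        leaky = panel.copy()
        leaky["leak"] = leaky["metro_volume"]
        m = fit_response_model(
            leaky, "metro_volume", seed=1, min_impurity_frac=0.0,
            features=RESPONSE_FEATURES + ["leak"],
        )
        assert m.oob_r2 >= 0.99

    def test_permuted_target_has_no_skill(self, truth_panel):
        rng = np.random.default_rng(4)
        perm = truth_panel.copy()
        perm["metro_volume"] = rng.permutation(perm["metro_volume"].to_numpy())
        m = fit_response_model(perm, "metro_volume", seed=1)
        assert m.oob_r2 <= 0.1

    def test_same_seed_identical_model(self, truth_panel):
        m1 = fit_response_model(truth_panel, "metro_volume", seed=2)
        m2 = fit_response_model(truth_panel, "metro_volume", seed=2)
        X = truth_panel[m1.features].to_numpy()
        np.testing.assert_array_equal(m1.model.predict(X), m2.model.predict(X))

    def test_too_few_rows_rejected(self, truth_panel):
        with pytest.raises(InsufficientDataError):
            fit_response_model(truth_panel.iloc[:20], "metro_volume", seed=1)

    def test_unknown_target_rejected(self, truth_panel):
        with pytest.raises(FeatureError):
            fit_response_model(truth_panel, "nope", seed=1)


def _stub_response(fn, panel, features):
    class _M:
        def predict(self, X):
            return fn(np.asarray(X))

    return ResponseModel(
        model=_M(), features=features, target="stub", oob_r2=np.nan,
        oob_rmse=np.nan, seed=0, panel_features=panel[features],
    )


class TestPartialDependence:
    def test_constant_stub_is_flat(self, truth_panel):
        m = _stub_response(lambda X: np.full(len(X), 2.0), truth_panel, list(RESPONSE_FEATURES))
        c = partial_dependence(m, "T2M")
        assert c["pd"].max() - c["pd"].min() == 0.0

    def test_identity_stub_returns_grid(self, truth_panel):
        j = RESPONSE_FEATURES.index("T2M")
        m = _stub_response(lambda X: X[:, j], truth_panel, list(RESPONSE_FEATURES))
        c = partial_dependence(m, "T2M")
        np.testing.assert_allclose(c["pd"], c["grid"])

    def test_unknown_feature_rejected(self, truth_panel):
        m = fit_response_model(truth_panel, "metro_volume", seed=1)
        with pytest.raises(FeatureError):
            partial_dependence(m, "nope")

    def test_pd_matches_brute_force_enumeration(self, truth_panel):
        """The quantile-grid implementation agrees with a direct double loop
        over (grid value, panel row) pairs."""
        m = fit_response_model(truth_panel, "metro_volume", seed=1)
        c = partial_dependence(m, "cases", n_grid=5)
        X = truth_panel[m.features].to_numpy()
        j = m.features.index("cases")
        for g, val in zip(c["grid"], c["pd"]):
            preds = []
            for row in X:
                r = row.copy()
                r[j] = g
                preds.append(m.model.predict(r.reshape(1, -1))[0])
            assert val == pytest.approx(np.mean(preds), abs=1e-6)


class TestFeatureEffectTest:
    def test_fully_determining_feature_attains_smallest_p(self, truth_panel):
        leaky = truth_panel.copy()
        leaky["leak"] = leaky["metro_volume"]
        res = feature_effect_test(
            leaky, "metro_volume", "leak", n_permutations=99, seed=1,
            n_estimators=100, features=RESPONSE_FEATURES + ["leak"],
        )
        assert res["p_value"] == pytest.approx(1.0 / 100.0)

    def test_too_few_permutations_rejected(self, truth_panel):
        with pytest.raises(InsufficientDataError):
            feature_effect_test(truth_panel, "metro_volume", "cases", n_permutations=10, seed=1)

    def test_noise_feature_is_not_flagged(self, truth_panel):
        rng = np.random.default_rng(6)
        p2 = truth_panel.copy()
        p2["noise_feature"] = rng.normal(size=len(p2))
        res = feature_effect_test(
            p2, "metro_volume", "noise_feature", n_permutations=99, seed=2,
            n_estimators=100, features=RESPONSE_FEATURES + ["noise_feature"],
        )
        assert res["p_value"] >= 0.05
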