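"""Monthly-panel response models: how epidemic covariates moved transport.

A regression forest predicts a monthly target (private-transport BC, bus
volume, or metro volume) from monthly weather summaries, the share of
vacation days, the virus' ordinal transmission/fatality ranks, and the
month's summed case count. Partial-dependence curves summarize each
covariate's marginal association; a permutation test attaches a p-value to
each covariate's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import AlignmentError, FeatureError, InsufficientDataError

__all__ = [
    "MET_SUMMARY_COLUMNS",
    "RESPONSE_FEATURES",
    "ResponseModel",
    "build_monthly_panel",
    "fit_response_model",
    "partial_dependence",
    "feature_effect_test",
]

MET_SUMMARY_COLUMNS = ["U10", "V10", "D2M", "T2M", "BLH", "MBLD", "SP", "TP"]
RESPONSE_FEATURES = MET_SUMMARY_COLUMNS + [
    "vacation_share",
    "transmission",
    "fatality",
    "cases",
]
TARGETS = ("bc_private", "bus_volume", "metro_volume")
MIN_PANEL_ROWS = 36


def build_monthly_panel(
    source_split: pd.DataFrame,
    volumes,
    met: pd.DataFrame,
    epidemic: pd.DataFrame,
) -> pd.DataFrame:
    """One row per month over the shared range of all inputs.

    Aggregation: meteorology by monthly mean except TP (monthly sum —
    precipitation totals, not states, drive behaviour); cases summed;
    transmission/fatality by monthly max (0 outside outbreaks); vacation-day
    share of the month; bc_transport by monthly mean; volumes as reported.
    """
    met_m = met.set_index(pd.DatetimeIndex(met["date"])).resample("MS").agg(
        {c: ("sum" if c == "TP" else "mean") for c in MET_SUMMARY_COLUMNS}
    )

    epi = epidemic.set_index(pd.DatetimeIndex(epidemic["date"]))
    epi_m = pd.DataFrame(
        {
            "cases": epi["cases"].resample("MS").sum(),
            "transmission": epi["transmission"].resample("MS").max(),
            "fatality": epi["fatality"].resample("MS").max(),
            "vacation_share": (epi["period"] == "legal-vacation")
            .astype(float)
            .resample("MS")
            .mean(),
        }
    )

    ss = source_split.set_index(pd.DatetimeIndex(source_split["date"]))
    bc_m = ss["bc_transport"].resample("MS").mean().rename("bc_private")

    vol_bus = volumes.monthly_series("bus").rename("bus_volume")
    vol_metro = volumes.monthly_series("metro").rename("metro_volume")

    panel = pd.concat([met_m, epi_m, bc_m, vol_bus, vol_metro], axis=1, join="inner")
    panel = panel.dropna()
    if panel.empty:
        raise AlignmentError("panel inputs share no complete month")
    panel.index.name = "month"
    return panel


@dataclass
class ResponseModel:
    """Fitted monthly-panel forest with OOB diagnostics."""

    model: object
    features: list[str]
    target: str
    oob_r2: float
    oob_rmse: float
    seed: int
    panel_features: pd.DataFrame  # training feature block, for PD averaging


def fit_response_model(
    panel: pd.DataFrame,
    target: str,
    seed: int,
    n_estimators: int = 200,
    min_samples_leaf: int = 2,
    min_impurity_frac: float = 0.10,
    features: list[str] | None = None,
) -> ResponseModel:
    """Fit one monthly response forest.

    ``features`` defaults to the standard covariate list. With only a few
    dozen panel rows a regression forest happily manufactures splits on
    irrelevant covariates; requiring each split to reduce impurity by at
    least ``min_impurity_frac`` of the target variance suppresses those
    noise splits while keeping the large outbreak-month splits, so partial
    dependence on irrelevant features stays flat without losing power on
    the epidemic covariates.
    """
    if target not in panel.columns:
        raise FeatureError(f"target '{target}' not in panel")
    feats = list(features) if features is not None else list(RESPONSE_FEATURES)
    missing = [f for f in feats if f not in panel.columns]
    if missing:
        raise FeatureError(f"panel lacks feature(s) {missing}")
    if len(panel) < MIN_PANEL_ROWS:
        raise InsufficientDataError(
            f"response model needs >= {MIN_PANEL_ROWS} panel rows, got {len(panel)}"
        )
    y = panel[target].to_numpy()
    rf = RandomForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        min_impurity_decrease=min_impurity_frac * float(np.var(y)),
        oob_score=True,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    rf.fit(panel[feats].to_numpy(), y)
    oob_rmse = float(np.sqrt(np.mean((rf.oob_prediction_ - y) ** 2)))
    return ResponseModel(
        model=rf,
        features=feats,
        target=target,
        oob_r2=float(rf.oob_score_),
        oob_rmse=oob_rmse,
        seed=int(seed),
        panel_features=panel[feats].copy(),
    )


def partial_dependence(
    model: ResponseModel,
    feature: str,
    n_grid: int = 20,
    quantile_range: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Standard partial dependence over a quantile grid of the feature.

    For each grid value v the feature is forced to v on every panel row and
    the model's predictions are averaged. The grid is ``n_grid`` quantiles
    of the observed feature between the 5th and 95th percentile
    (deduplicated) — the customary trimming that keeps the sweep inside the
    well-supported range.
    """
    if feature not in model.features:
        raise FeatureError(f"'{feature}' is not a model feature")
    X = model.panel_features.to_numpy().copy()
    j = model.features.index(feature)
    qlo, qhi = quantile_range
    grid = np.unique(
        np.quantile(
            model.panel_features[feature].to_numpy(), np.linspace(qlo, qhi, n_grid)
        )
    )
    pd_vals = np.empty(len(grid))
    for i, v in enumerate(grid):
        Xv = X.copy()
        Xv[:, j] = v
        pd_vals[i] = model.model.predict(Xv).mean()
    return pd.DataFrame({"feature": feature, "grid": grid, "pd": pd_vals})


def feature_effect_test(
    panel: pd.DataFrame,
    target: str,
    feature: str,
    n_permutations: int = 199,
    seed: int = 0,
    **fit_kwargs,
) -> dict:
    """Permutation test of one covariate's contribution to the forest fit.

    The forest is refit ``n_permutations`` times with the feature's column
    permuted in the training panel; the observed out-of-bag MSE of the intact
    model is compared against the null distribution of OOB MSEs from the
    permuted refits. Under the null (the feature carries no signal) the
    intact fit is exchangeable with the permuted ones, so
    p = (1 + #{null MSE <= observed MSE}) / (1 + n_permutations) is a valid
    one-sided p-value for "permuting this feature increases OOB error".
    """
    if n_permutations < 99:
        raise InsufficientDataError("n_permutations must be >= 99")
    base = fit_response_model(panel, target, seed=seed, **fit_kwargs)
    mse0 = base.oob_rmse**2
    rng = np.random.default_rng(int(seed))
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm_panel = panel.copy()
        perm_panel[feature] = rng.permutation(perm_panel[feature].to_numpy())
        m = fit_response_model(perm_panel, target, seed=seed, **fit_kwargs)
        null[b] = m.oob_rmse**2
    p = (1.0 + np.sum(null <= mse0)) / (1.0 + n_permutations)
    return {
        "feature": feature,
        "target": target,
        "observed_oob_mse": float(mse0),
        "null_mean_oob_mse": float(null.mean()),
        "n_permutations": int(n_permutations),
        "p_value": float(p),
    }
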