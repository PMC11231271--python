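"""Tracer-based source attribution of normalized black carbon.

Normalized NO₃⁻ (a proxy for NOₓ, co-emitted by road transport) and
normalized SO₄²⁻ (a proxy for SO₂, co-emitted by factories) are used to
decompose normalized BC into a transport component (the private-transport
emission proxy) and a factory component.

A regression forest learns g(NO₃, SO₄) → BC. Each component is the
counterfactual difference between the prediction at the observed tracer
values and the prediction with one tracer set to a low reference value
(default: its 5th percentile over the training record; tracers never reach
zero in real records, and zero would be extreme extrapolation for a forest):

    Δ_t = g(no3, so4) − g(r_no3, so4)        transport
    Δ_f = g(no3, so4) − g(no3, r_so4)        factory
    floor = g(r_no3, r_so4)                  both-sources-low baseline

The interaction mass ρ = g − floor − Δ_t − Δ_f is split between the two
components proportionally to |Δ_t| and |Δ_f| (equally when both vanish), so
transport + factory + floor equals the prediction on every row by
construction. Components are clipped at zero for reporting, with the clipped
mass logged; the unclipped values are kept for the additivity contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .errors import DegenerateInputError, InsufficientDataError

log = logging.getLogger(__name__)

__all__ = ["AttributionModel", "fit_attribution_model", "attribute", "evaluate_fit"]

MIN_TRAINING_ROWS = 365


@dataclass
class AttributionModel:
    """Fitted tracer→BC forest, reference tracer values, and fit diagnostics."""

    model: object  # anything with .predict on (n, 2) arrays
    r_no3: float
    r_so4: float
    r_squared: float
    rmse: float
    slope: float
    seed: int
    reference_quantile: float
    no3_range: tuple[float, float] = (-np.inf, np.inf)
    so4_range: tuple[float, float] = (-np.inf, np.inf)


def fit_attribution_model(
    bc_norm: pd.Series,
    no3_norm: pd.Series,
    so4_norm: pd.Series,
    seed: int,
    reference_quantile: float = 0.05,
    n_estimators: int = 300,
    min_samples_leaf: int = 25,
) -> AttributionModel:
    """Fit BC on the two normalized tracer series (aligned by date)."""
    df = pd.concat(
        {"bc": bc_norm, "no3": no3_norm, "so4": so4_norm}, axis=1, join="inner"
    ).dropna()
    if len(df) < MIN_TRAINING_ROWS:
        raise InsufficientDataError(
            f"attribution needs >= {MIN_TRAINING_ROWS} aligned rows, got {len(df)}"
        )
    X = df[["no3", "so4"]].to_numpy()
    y = df["bc"].to_numpy()
    rf = RandomForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        random_state=int(seed),
        n_jobs=1,
    )
    rf.fit(X, y)
    pred = rf.predict(X)
    r2, rmse, slope = evaluate_fit(pred, y)
    return AttributionModel(
        model=rf,
        r_no3=float(df["no3"].quantile(reference_quantile)),
        r_so4=float(df["so4"].quantile(reference_quantile)),
        r_squared=r2,
        rmse=rmse,
        slope=slope,
        seed=int(seed),
        reference_quantile=reference_quantile,
        no3_range=(float(df["no3"].min()), float(df["no3"].max())),
        so4_range=(float(df["so4"].min()), float(df["so4"].max())),
    )


def attribute(model: AttributionModel, data: pd.DataFrame) -> pd.DataFrame:
    """Decompose each row of ``data`` (columns no3, so4, optionally bc).

    Returns a table with bc_predicted, bc_transport, bc_factory (clipped at
    zero), their unclipped counterparts, the baseline floor and, when
    observed BC is available, the unexplained residual observed − predicted.
    """
    for col in ("no3", "so4"):
        if col not in data.columns:
            raise DegenerateInputError(f"attribution input lacks column '{col}'")
    no3 = data["no3"].to_numpy(dtype=float)
    so4 = data["so4"].to_numpy(dtype=float)
    n = len(data)
    outside = (
        (no3 < model.no3_range[0]) | (no3 > model.no3_range[1])
        | (so4 < model.so4_range[0]) | (so4 > model.so4_range[1])
    )
    if outside.any():
        log.warning(
            "%d/%d rows have tracer values outside the training hull (extrapolation)",
            int(outside.sum()), n,
        )
    g = model.model.predict(np.column_stack([no3, so4]))
    g_no3_ref = model.model.predict(np.column_stack([np.full(n, model.r_no3), so4]))
    g_so4_ref = model.model.predict(np.column_stack([no3, np.full(n, model.r_so4)]))
    floor = float(model.model.predict(np.array([[model.r_no3, model.r_so4]]))[0])

    d_t = g - g_no3_ref
    d_f = g - g_so4_ref
    rho = g - floor - d_t - d_f
    denom = np.abs(d_t) + np.abs(d_f)
    w_t = np.where(denom > 0, np.abs(d_t) / np.where(denom > 0, denom, 1.0), 0.5)
    transport_raw = d_t + w_t * rho
    factory_raw = d_f + (1.0 - w_t) * rho

    transport = np.maximum(transport_raw, 0.0)
    factory = np.maximum(factory_raw, 0.0)
    clipped = float(np.sum(transport - transport_raw) + np.sum(factory - factory_raw))
    if clipped > 0:
        log.info("attribution clipped %.4g µg m⁻³·day of negative component mass", clipped)

    out = pd.DataFrame(index=data.index)
    if "date" in data.columns:
        out["date"] = data["date"].to_numpy()
    out["bc_predicted"] = g
    out["bc_transport"] = transport
    out["bc_factory"] = factory
    out["bc_transport_raw"] = transport_raw
    out["bc_factory_raw"] = factory_raw
    out["floor"] = floor
    if "bc" in data.columns:
        out["unexplained"] = data["bc"].to_numpy(dtype=float) - g
    out.attrs["clipped_mass"] = clipped
    return out


def evaluate_fit(predicted, observed) -> tuple[float, float, float]:
    """(R², RMSE, slope) of observed against predicted.

    R² is the squared Pearson correlation; the slope is the OLS regression of
    observed on predicted.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if len(p) != len(o) or len(p) < 3:
        raise DegenerateInputError("evaluate_fit needs equal-length series, n >= 3")
    if np.std(p) == 0 or np.std(o) == 0:
        raise DegenerateInputError("zero variance in predicted or observed series")
    r, _ = stats.pearsonr(p, o)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    slope = float(np.cov(p, o, ddof=0)[0, 1] / np.var(p))
    return float(r**2), rmse, slope
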