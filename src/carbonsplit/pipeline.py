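"""End-to-end orchestration: simulate → normalize ×3 → trend/baseline →
attribute → stats → respond, as one seeded, logged, reproducible run.

One master seed fans out to named substreams (simulate, normalize.BC,
normalize.NO3, normalize.SO4, attribute, respond), so toggling one stage
never shifts another stage's randomness. Per-stage wall times go to the log;
the report itself depends only on the config and seed, so identical runs
produce identical reports.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attr_mod
from . import normalization as norm_mod
from . import response as resp_mod
from . import transport as trans_mod
from . import trend as trend_mod
from .config import default_run_config, load_config, substream_seed
from .data_io import write_json
from .errors import CarbonSplitError, StageError
from .synthetic import simulate

log = logging.getLogger(__name__)

__all__ = ["run_all", "STAGES"]

STAGES = ("simulate", "normalize", "trend", "baseline", "attribute", "stats", "respond")
SPECIES = ("BC", "NO3", "SO4")


def _stage(report, out_dir, name):
    """Context manager recording stage success/failure and wall time (log only)."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt_s = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %-9s finished in %.1f s", name, dt_s)
                return False
            log.error("stage %s FAILED after %.1f s: %s", name, dt_s, exc)
            report["failed_stage"] = name
            report["error"] = str(exc)
            if out_dir is not None:
                (Path(out_dir) / "FAILED").write_text(f"{name}: {exc}\n")
                write_json(report, Path(out_dir) / "report.json")
            if isinstance(exc, CarbonSplitError) and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_all(config=None, out_dir=None) -> dict:
    """Run the configured stages in dependency order; return the run report.

    ``config`` may be a path to a YAML file, a config dict (as produced by
    :func:`carbonsplit.config.load_config`), or None for the default
    six-year synthetic scenario.
    """
    if config is None:
        cfg = default_run_config()
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = config
    stages = set(cfg.get("stages") or STAGES)
    seed = int(cfg["seed"])
    periods = cfg["periods"]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    sim_config = cfg["simulate"].with_(seed=seed)
    sim_config.validate_for_analysis()
    report: dict = {
        "config": {
            "seed": seed,
            "n_days": sim_config.n_days,
            "start_date": str(sim_config.start_date),
            "stages": sorted(stages),
            "periods": [
                {"name": p.name, "start": str(p.start), "end": str(p.end),
                 "baseline": p.baseline}
                for p in periods
            ],
        },
        "provenance": {"package": "carbonsplit", "master_seed": seed},
    }

    # ------------------------------------------------------------------ simulate
    with _stage(report, out, "simulate"):
        sim = simulate(sim_config)
        if out is not None:
            sim.write(out / "tables")
        truth_m = sim.truth.monthly()
        report["simulate"] = {
            "n_days": int(sim_config.n_days),
            "n_windows": len(sim_config.outbreak_windows),
            "mean_BC_obs": float(sim.pollutants["BC"].mean()),
            "mean_E_transport": float(sim.truth.table["E_transport"].mean()),
            "mean_E_factory": float(sim.truth.table["E_factory"].mean()),
        }

    # ----------------------------------------------------------------- normalize
    norm_cfg = cfg["normalization"]
    normalized: dict[str, pd.DataFrame] = {}
    if "normalize" in stages:
        with _stage(report, out, "normalize"):
            block = {}
            merged = sim.meteorology.merge(sim.pollutants, on="date")
            for sp in SPECIES:
                sp_seed = substream_seed(seed, f"normalize.{sp}")
                series = sim.pollutants.set_index("date")[sp]
                model = norm_mod.fit_met_model(
                    series,
                    sim.meteorology,
                    seed=sp_seed,
                    n_estimators=norm_cfg["n_estimators"],
                    min_samples_leaf=norm_cfg["min_samples_leaf"],
                    day_of_week=norm_cfg.get("use_day_of_week", False),
                )
                res = norm_mod.normalize(
                    model, merged, n_samples=norm_cfg["n_samples"],
                    seed=sp_seed, pollutant=sp,
                )
                normalized[sp] = res
                if out is not None:
                    res.assign(
                        date=pd.DatetimeIndex(res["date"]).strftime("%Y-%m-%d")
                    ).to_csv(out / f"normalized_{sp}.csv", index=False)
                block[sp] = {
                    "oob_r2": model.oob_r2,
                    "oob_rmse": model.oob_rmse,
                    "n_samples": norm_cfg["n_samples"],
                    "mean_mc_sd": float(res["mc_sd"].mean()),
                }
            report["normalize"] = block

    # --------------------------------------------------------------------- trend
    bc_norm_daily = None
    trend_norm = None
    if "trend" in stages and "normalize" in stages:
        with _stage(report, out, "trend"):
            bc_norm_daily = normalized["BC"].set_index("date")["normalized"]
            bc_obs_daily = sim.pollutants.set_index("date")["BC"]
            trend_obs = trend_mod.fit_linear_trend(trend_mod.weekly_mean(bc_obs_daily))
            trend_norm = trend_mod.fit_linear_trend(trend_mod.monthly_mean(bc_norm_daily))
            report["trend"] = {
                "observed_weekly": {
                    "slope_per_decade": trend_obs.slope_per_decade,
                    "r_squared": trend_obs.r_squared,
                    "p_value": trend_obs.p_value,
                },
                "normalized_monthly": {
                    "slope_per_decade": trend_norm.slope_per_decade,
                    "r_squared": trend_norm.r_squared,
                    "p_value": trend_norm.p_value,
                    "ci95_per_decade": list(trend_norm.ci_per_decade()),
                },
            }

    # ------------------------------------------------------------------ baseline
    if "baseline" in stages and "normalize" in stages:
        with _stage(report, out, "baseline"):
            bc_norm_monthly = trend_mod.monthly_mean(
                normalized["BC"].set_index("date")["normalized"]
            )
            anomaly, _fit = trend_mod.detrend(bc_norm_monthly)
            monthly_base, overall_base = trend_mod.compute_baseline(
                bc_norm_monthly, periods
            )
            base_anom = trend_mod.baseline_anomaly(bc_norm_monthly, monthly_base)
            if out is not None:
                pd.DataFrame(
                    {
                        "month": bc_norm_monthly.index.strftime("%Y-%m"),
                        "normalized": bc_norm_monthly.to_numpy(),
                        "detrended": anomaly.reindex(bc_norm_monthly.index).to_numpy(),
                        "baseline_anomaly": base_anom.reindex(
                            bc_norm_monthly.index
                        ).to_numpy(),
                    }
                ).to_csv(out / "bc_monthly_anomalies.csv", index=False)
            report["baseline"] = {
                "overall_baseline": overall_base,
                "monthly_baseline": {
                    int(k): (None if pd.isna(v) else float(v))
                    for k, v in monthly_base.items()
                },
                "mean_detrended_anomaly": float(anomaly.mean()),
            }

    # ----------------------------------------------------------------- attribute
    attr_cfg = cfg["attribution"]
    split = None
    if "attribute" in stages and "normalize" in stages:
        with _stage(report, out, "attribute"):
            attr_seed = substream_seed(seed, "attribute")
            bc_in = normalized["BC"].set_index("date")["normalized"]
            if attr_cfg.get("detrend_before_attribution", False):
                bc_in, _ = trend_mod.detrend(bc_in, recenter=True)
            no3_in = normalized["NO3"].set_index("date")["normalized"]
            so4_in = normalized["SO4"].set_index("date")["normalized"]
            model = attr_mod.fit_attribution_model(
                bc_in, no3_in, so4_in,
                seed=attr_seed,
                reference_quantile=attr_cfg["reference_quantile"],
                n_estimators=attr_cfg["n_estimators"],
                min_samples_leaf=attr_cfg["min_samples_leaf"],
            )
            frame = pd.DataFrame(
                {"date": bc_in.index, "bc": bc_in.to_numpy(),
                 "no3": no3_in.reindex(bc_in.index).to_numpy(),
                 "so4": so4_in.reindex(bc_in.index).to_numpy()}
            )
            split = attr_mod.attribute(model, frame)
            if out is not None:
                split.assign(
                    date=pd.DatetimeIndex(split["date"]).strftime("%Y-%m-%d")
                ).to_csv(out / "source_split.csv", index=False)
            report["attribute"] = {
                "r_squared": model.r_squared,
                "rmse": model.rmse,
                "slope": model.slope,
                "r_no3": model.r_no3,
                "r_so4": model.r_so4,
                "floor": float(split["floor"].iloc[0]),
                "clipped_mass": split.attrs.get("clipped_mass", 0.0),
                "mean_bc_transport": float(split["bc_transport"].mean()),
                "mean_bc_factory": float(split["bc_factory"].mean()),
            }

    # --------------------------------------------------------------------- stats
    if "stats" in stages:
        with _stage(report, out, "stats"):
            dow = trans_mod.day_of_week_stats(sim.volumes.daily_metro)
            metro_m = sim.volumes.monthly_series("metro")
            bus_m = sim.volumes.monthly_series("bus")
            base_metro, _ = trend_mod.compute_baseline(metro_m, periods)
            base_bus, _ = trend_mod.compute_baseline(bus_m, periods)
            changes = trans_mod.percent_change(
                metro_m, periods, base_metro, mode="metro"
            ) + trans_mod.percent_change(bus_m, periods, base_bus, mode="bus")
            block = {
                "day_of_week": dow.to_dict(),
                "percent_change": [
                    {"period": c.period, "mode": c.mode, "percent": c.percent,
                     "n_months": c.n_months}
                    for c in changes
                ],
            }
            if split is not None:
                bc_t_monthly = trend_mod.monthly_mean(
                    split.set_index("date")["bc_transport"]
                )
                segs = trans_mod.segment_regression(
                    bc_t_monthly, sim.volumes.public_series(), periods
                )
                block["segment_regression"] = [
                    {"period": s.period, "slope": s.slope, "intercept": s.intercept,
                     "r_squared": s.r_squared, "p_value": s.p_value, "n": s.n,
                     "ci95": list(s.ci())}
                    for s in segs
                ]
            report["stats"] = block

    # ------------------------------------------------------------------- respond
    if "respond" in stages:
        with _stage(report, out, "respond"):
            if split is None:
                raise StageError(
                    "respond",
                    CarbonSplitError(
                        "the response stage needs 'bc_transport' from the "
                        "attribute stage; enable attribution"
                    ),
                )
            resp_cfg = cfg["response"]
            resp_seed = substream_seed(seed, "respond")
            panel = resp_mod.build_monthly_panel(
                split, sim.volumes, sim.meteorology, sim.epidemic
            )
            if out is not None:
                panel.reset_index().assign(
                    month=lambda d: pd.DatetimeIndex(d["month"]).strftime("%Y-%m")
                ).to_csv(out / "monthly_panel.csv", index=False)
            block = {"n_months": int(len(panel)), "targets": {}}
            for target in ("bc_private", "bus_volume", "metro_volume"):
                m = resp_mod.fit_response_model(
                    panel, target, seed=resp_seed,
                    n_estimators=resp_cfg["n_estimators"],
                    min_samples_leaf=resp_cfg["min_samples_leaf"],
                )
                pds = {}
                for feat in ("cases", "transmission", "fatality"):
                    curve = resp_mod.partial_dependence(
                        m, feat, n_grid=resp_cfg["n_grid"]
                    )
                    pds[feat] = {
                        "grid": curve["grid"].tolist(),
                        "pd": curve["pd"].tolist(),
                    }
                test = resp_mod.feature_effect_test(
                    panel, target, "cases",
                    n_permutations=resp_cfg["n_permutations"],
                    seed=resp_seed,
                    n_estimators=resp_cfg["n_estimators"],
                    min_samples_leaf=resp_cfg["min_samples_leaf"],
                )
                block["targets"][target] = {
                    "oob_r2": m.oob_r2,
                    "oob_rmse": m.oob_rmse,
                    "partial_dependence": pds,
                    "cases_effect_p": test["p_value"],
                }
            report["respond"] = block

    if out is not None:
        write_json(report, out / "report.json")
    return report
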