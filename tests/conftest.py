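"""Shared fixtures: scenario simulations and one full pipeline run.

Everything is generated at test time from seeds; expensive artifacts
(the default-scenario pipeline run, the dispersion-free simulation) are
session-scoped so every test that needs them shares one computation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from carbonsplit import default_config, run_all, simulate
from carbonsplit.config import default_run_config
from carbonsplit.response import build_monthly_panel

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """The default six-year scenario at seed 0."""
    return simulate(default_config())


@pytest.fixture(scope="session")
def dispersion_free_sim():
    """Default scenario with the dispersion factor forced to 1."""
    return simulate(default_config().with_(dispersion_strength=(0.0, 0.0)))


@pytest.fixture(scope="session")
def truth_panel(default_sim):
    """Monthly panel built from the ground-truth transport emission."""
    split = default_sim.truth.table[["date", "E_transport"]].rename(
        columns={"E_transport": "bc_transport"}
    )
    return build_monthly_panel(
        split, default_sim.volumes, default_sim.meteorology, default_sim.epidemic
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-scenario pipeline run (report + persisted tables)."""
    out = tmp_path_factory.mktemp("pipeline")
    report = run_all(default_run_config(), out_dir=out)
    return report, out


@pytest.fixture(scope="session")
def small_run_config():
    """A fast scenario for determinism checks: ~26 months, light sampling."""
    import datetime as dt

    from carbonsplit.config import OutbreakWindow

    cfg = default_run_config()
    cfg["simulate"] = default_config().with_(
        n_days=800,
        outbreak_windows=(
            OutbreakWindow(
                dt.date(2019, 6, 1), dt.date(2019, 7, 15), 0.3, 0.2, 1, 2, 200.0, "test"
            ),
        ),
    )
    cfg["normalization"] = {**cfg["normalization"], "n_samples": 20}
    cfg["stages"] = ["simulate", "normalize", "trend", "baseline", "attribute", "stats"]
    return cfg


def monthly(series: pd.Series) -> pd.Series:
    s = series.copy()
    s.index = pd.DatetimeIndex(s.index)
    return s.resample("MS").mean()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
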