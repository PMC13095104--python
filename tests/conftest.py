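"""Shared fixtures.

Expensive full-scale simulations are run once per session and reused by
several tests: the trend suite (evoked runs across FFI-sharing conditions)
and the calibration-state runs.  Unit tests use a miniature striatal
network (60 MSNs, 10 FSIs, scaled indegrees) that keeps every mechanism
active at a fraction of the cost.
"""

from __future__ import annotations

import pandas as pd
import pytest

from striatumffi import (
    ConnectionRule,
    ExperimentConfig,
    PopulationLayout,
    SimConfig,
    Simulation,
    build_striatum,
)
from striatumffi.experiments import run_condition

# input settings exercised by the trend checks: the extremes of the
# reduced sharing grid (weakly and strongly shared cortical drive)
TREND_SETTINGS = [(0.05, 0.1), (0.25, 0.9)]
TREND_N_FSI = (0, 25, 250)
TREND_SEEDS = (101, 202)
TREND_N_TRIALS = 10


def small_layout() -> PopulationLayout:
    return PopulationLayout(n_msn=60, n_fsi=10)


def small_rules() -> dict[str, ConnectionRule]:
    return {
        "msn_msn": ConnectionRule(
            source="MSN", target="MSN", indegree=12, weight_mean=0.03,
            delay_mean=2.0, allow_autapse=True,
        ),
        "fsi_msn": ConnectionRule(
            source="FSI", target="MSN", indegree=3, weight_mean=0.5, delay_mean=2.0,
        ),
    }


@pytest.fixture(scope="session")
def small_network():
    return build_striatum(small_layout(), small_rules(), seed=42)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(t_total=800.0, t_warmup=200.0, n_trials=3, master_seed=7)


@pytest.fixture(scope="session")
def small_trialset(small_network, small_config):
    return Simulation(small_network, small_config).run_trials()


def _trend_rows(master_seed: int, heterogeneous: bool, n_trials: int) -> list[dict]:
    rows = []
    for w_in, b_in in TREND_SETTINGS:
        cfg_ds = ExperimentConfig(
            name="downstream",
            n_trials=n_trials,
            master_seed=master_seed,
            heterogeneous=heterogeneous,
            pair_budget=2000,
        )
        gpe_weight = None
        for n_fsi in (250, 25):  # baseline first: it calibrates the GPe weight
            row = run_condition(cfg_ds, w_in, b_in, n_fsi, gpe_background_weight=gpe_weight)
            gpe_weight = row["gpe_background_weight"]
            row["master_seed"] = master_seed
            rows.append(row)
        cfg_corr = ExperimentConfig(
            name="correlation",
            n_trials=n_trials,
            master_seed=master_seed,
            heterogeneous=heterogeneous,
            pair_budget=2000,
        )
        row = run_condition(cfg_corr, w_in, b_in, 0)
        row["master_seed"] = master_seed
        rows.append(row)
    return rows


@pytest.fixture(scope="session")
def trend_results() -> pd.DataFrame:
    """Evoked runs for the FFI-sharing trend checks (homogeneous neurons).

    Full-size network and trial duration; reduced trial and seed counts keep
    the suite tractable (see docs/methods.md on problem sizes).
    """
    rows = []
    for seed in TREND_SEEDS:
        rows += _trend_rows(seed, heterogeneous=False, n_trials=TREND_N_TRIALS)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def trend_results_het() -> pd.DataFrame:
    """Heterogeneous-neuron replication of the trend runs (one seed)."""
    return pd.DataFrame(_trend_rows(TREND_SEEDS[0], heterogeneous=True, n_trials=TREND_N_TRIALS))
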