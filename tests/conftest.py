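import numpy as np
import pandas as pd
import pytest

from gonogo.behavior import filter_rts
from gonogo.lba import LBAParams
from gonogo.synth import (CohortConfig, default_group_means,
                          generate_cohort, generate_schedule,
                          simulate_session)


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(1)


@pytest.fixture(scope="session")
def base_params() -> LBAParams:
    return default_group_means()["noSE-like"]


@pytest.fixture(scope="session")
def filtered_session(schedule, base_params) -> pd.DataFrame:
    """One simulated, RT-filtered session at the baseline parameters."""
    trials = simulate_session(schedule, base_params, rng_seed=3)
    filtered, _, _ = filter_rts(trials)
    return filtered


@pytest.fixture(scope="session")
def long_session(base_params) -> pd.DataFrame:
    """2 250 trials (ten schedules) at baseline parameters, filtered."""
    frames = [
        simulate_session(generate_schedule(k), base_params, rng_seed=100 + k)
        for k in range(10)
    ]
    filtered, _, _ = filter_rts(pd.concat(frames, ignore_index=True))
    return filtered


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = CohortConfig(n_participants=12, seed=5)
    return cfg, generate_cohort(cfg)


def make_session(n_targets=144, n_identity=36, n_location=45,
                 target_responses=None, identity_responses=0,
                 location_responses=0, rt=0.5):
    """Hand-built session table with exact response counts."""
    if target_responses is None:
        target_responses = n_targets
    rows = []
    for i in range(n_targets):
        rows.append(("target", "X", "upper", i < target_responses))
    for i in range(n_identity):
        rows.append(("identity_foil", "Y", "upper", i < identity_responses))
    for i in range(n_location):
        rows.append(("location_foil", "X", "lower", i < location_responses))
    df = pd.DataFrame(rows, columns=["stim_class", "letter", "row", "responded"])
    df["trial_index"] = np.arange(len(df))
    df["position"] = 1
    df["rt"] = np.where(df["responded"], rt, np.nan)
    return df
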