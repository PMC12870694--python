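import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from overdx import datasets

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from overdx.lifetable import make_gompertz_lifetable
from overdx.simulate import TrialSimConfig, simulate_trial


@pytest.fixture(scope="session")
def cap():
    return datasets.cap_trial_summary()


@pytest.fixture(scope="session")
def synthetic_lt():
    """Cause-deleted synthetic English-male life table."""
    return datasets.synthetic_other_cause_lifetable()


@pytest.fixture(scope="session")
def gompertz_lt():
    return make_gompertz_lifetable(b=0.0008, g=0.095, age_min=50, age_max=110)


@pytest.fixture(scope="session")
def screening_sim(gompertz_lt):
    """Moderate-size one-off-screen simulation with oracle fields."""
    cfg = TrialSimConfig(
        n_screen=60_000,
        n_control=60_000,
        incidence_hazard=0.005,
        mortality=gompertz_lt,
        seed=20260929,
        attendance=1.0,
        lead_time_mean=10.0,
        entry_age_dist=70,
        followup_max=16.0,
    )
    return cfg, simulate_trial(cfg)


@pytest.fixture()
def hand_records():
    """5 subjects: events at 1, 2; censorings at 1.5, 2.5, 3."""
    return pd.DataFrame(
        {
            "arm": ["screen"] * 5,
            "entry_age": [60] * 5,
            "observed_time": [1.0, 2.0, 1.5, 2.5, 3.0],
            "observed_event": ["cancer", "cancer", "censored", "death", "censored"],
            "screen_detected": [False] * 5,
        }
    )


def km_curve_pair_from(records):
    from overdx.netrisk import kaplan_meier_net_risk

    return (
        kaplan_meier_net_risk(records, "screen"),
        kaplan_meier_net_risk(records, "control"),
    )
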