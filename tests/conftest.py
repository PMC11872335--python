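import warnings

import numpy as np
import pytest
from hypothesis import settings

import proimpute as pi

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

# statsmodels emits convergence chatter on deliberately tiny fits
warnings.filterwarnings("ignore", category=RuntimeWarning, module="statsmodels")


SHORT_SCHEDULE = pi.Schedule(tuple(range(1, 11)) + (12, 14, 16, 18, 20))


@pytest.fixture(scope="session")
def sim_config():
    """Default-conditions trial truncated at cycle 20 (test-sized)."""
    return pi.SimConfig(n_patients=200, schedule=SHORT_SCHEDULE,
                        admin_censor_time=20.0, seed=42)


@pytest.fixture(scope="session")
def complete_trial(sim_config):
    return pi.simulate_trial(sim_config)


@pytest.fixture(scope="session")
def observed_trial(sim_config, complete_trial):
    return pi.apply_missingness(complete_trial, sim_config.missingness, seed=43)


@pytest.fixture()
def toy_patients():
    """Four hand-built patients covering death, censoring, PD and TD."""
    return [
        pi.PatientRecord("a", death_ind=1, surv_time=7, pd_ind=1, pd_time=4,
                         td_ind=1, td_time=6, age=61, sex="F", ecog=1),
        pi.PatientRecord("b", death_ind=0, surv_time=12, pd_ind=0, pd_time=12,
                         td_ind=1, td_time=10, age=55, sex="M", ecog=0),
        pi.PatientRecord("c", death_ind=1, surv_time=3.5, pd_ind=1, pd_time=2,
                         td_ind=1, td_time=3, age=70, sex="M", ecog=2),
        pi.PatientRecord("d", death_ind=0, surv_time=20, pd_ind=1, pd_time=9,
                         td_ind=1, td_time=15, age=48, sex="F", ecog=1),
    ]
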