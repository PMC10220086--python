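import numpy as np
import pytest

from dualcontrol.simulate import (
    CohortConfig,
    SubjectProfile,
    simulate_cohort,
    simulate_session,
)
from dualcontrol.trial_data import trials_to_frame


@pytest.fixture(scope="session")
def td_profile() -> SubjectProfile:
    """A typical well-controlled subject with all proactive effects on."""
    return SubjectProfile(
        subject_id="td001",
        group="TD",
        mu=420.0,
        sigma=76.0,
        tau=75.0,
        ssrt_true=280.0,
        p_choice_error=0.04,
        p_omission=0.02,
        beta_context=30.0,
        beta_pes=42.0,
        beta_antic=500.0,
    )


@pytest.fixture(scope="session")
def plain_profile() -> SubjectProfile:
    """A subject with no proactive modulation (all betas zero)."""
    return SubjectProfile(
        subject_id="s000",
        group="TD",
        mu=420.0,
        sigma=76.0,
        tau=75.0,
        ssrt_true=280.0,
        p_choice_error=0.04,
        p_omission=0.02,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-subject cohort with both tasks (shared across tests)."""
    return simulate_cohort(CohortConfig(n_td=8, n_adhd=8, seed=11))


@pytest.fixture()
def sst_trials(td_profile):
    rng = np.random.default_rng(5)
    recs = simulate_session(td_profile, "SST", 1, rng)
    recs += simulate_session(td_profile, "SST", 2, rng)
    return trials_to_frame(recs)


@pytest.fixture()
def csst_trials(td_profile):
    rng = np.random.default_rng(6)
    recs = simulate_session(td_profile, "CSST", 1, rng)
    recs += simulate_session(td_profile, "CSST", 2, rng)
    return trials_to_frame(recs)
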