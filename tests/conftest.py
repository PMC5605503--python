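import numpy as np
import pytest

from chasedot.observer import GlmmParams, sample_cohort, simulate_study
from chasedot.design import build_design
from chasedot.stimulus import SimConfig, TrialSpec, simulate_trial


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def present_trial():
    """One chase-present baseline trial at mid subtlety."""
    return simulate_trial(TrialSpec("baseline", 45.0, True, seed=11))


@pytest.fixture(scope="session")
def absent_trial():
    return simulate_trial(TrialSpec("baseline", 45.0, False, seed=12))


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study: 8 participants per group, full design."""
    params = GlmmParams()
    rng = np.random.default_rng(7)
    design = build_design(16, rng=rng)
    cohort = sample_cohort(8, params, rng)
    responses = simulate_study(design, cohort, params, rng)
    return design, cohort, responses, params
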