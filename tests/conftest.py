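import numpy as np
import pandas as pd
import pytest

from cptscale import IntervalCensoredSurvReg, ModelSpec
from cptscale.simulate import (
    CellSpec,
    DEFAULT_SCHEDULE,
    apply_check_schedule,
    simulate_removal_times,
)
from cptscale.trials import ObservationSet, make_intervals


def simulated_obs(family, mu, sigma, n, seed, schedule=DEFAULT_SCHEDULE,
                  trial_length=56.0, mode="in_person", labels=None):
    """Removal times -> check-schedule discretisation -> ObservationSet."""
    cell = CellSpec(family, mu, sigma, labels or {}, n)
    times = simulate_removal_times(cell, seed=seed)
    recs = apply_check_schedule(times, schedule, trial_length, mode=mode,
                                labels=labels or {})
    return make_intervals(recs)


def exact_obs(times, labels=None):
    """Near-exact (width 1e-3) intervals at the given removal times."""
    times = np.asarray(times, dtype=float)
    cov = pd.DataFrame([labels or {"bird_type": "gamebird"}] * len(times))
    return ObservationSet(times - 1e-3, times, cov, np.ones(len(times)))


@pytest.fixture
def exponential_fit():
    obs = simulated_obs("exponential", np.log(15.0), 1.0, 300, seed=4)
    return IntervalCensoredSurvReg(obs, ModelSpec("exponential")).fit(seed=0)
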