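import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import evreg as ev

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_stimuli() -> ev.StimulusSet:
    """Tiny session: 4 bases x 6 variants + 8 catch, mirrored -> 64 trials."""
    return ev.build_stimulus_set(n_long=4, n_catch=8, rng=11)


@pytest.fixture(scope="session")
def full_stimuli() -> ev.StimulusSet:
    """The default 480-trial session."""
    return ev.build_stimulus_set(rng=7)


@pytest.fixture(scope="session")
def small_outcomes(small_stimuli) -> list[ev.TrialOutcome]:
    return ev.simulate_outcomes(small_stimuli, rng=13)


@pytest.fixture(scope="session")
def small_session(small_stimuli, small_outcomes) -> ev.SignalTensor:
    """Pure-noise tensor (no embedded effects) for the tiny session."""
    return ev.simulate_session(small_stimuli, small_outcomes, [],
                               noise_sd=1.0, rng=17, n_channels=6)
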