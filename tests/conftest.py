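import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def validation_study():
    from trunklab.reliability import load_validation_study
    return load_validation_study()


@pytest.fixture(scope="session")
def noiseless_hold():
    """Simulated 30-degree hold for 5 s, then 3 deg/s droop, no tremor."""
    from trunklab import synth
    sc = synth.PostureScenario(initial_roll=30.0, hold_duration=5.0,
                               droop_rate=3.0, tremor_sd=0.0, seed=11)
    traj = synth.simulate_trajectory(sc, 10.0)
    return sc, traj
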