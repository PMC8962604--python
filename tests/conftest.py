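import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phylloflight.synthetic import (MorphSimSpec, TrajectoryParams,
                                    simulate_drop_flight, simulate_morphometrics)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_trial():
    """Noise-free drop-recovery trial at the default study parameters."""
    return simulate_drop_flight(TrajectoryParams())


@pytest.fixture(scope="session")
def noisy_trial():
    """One trial with 0.5 mm landmark tracking noise."""
    return simulate_drop_flight(TrajectoryParams(noise_sd=5e-4, seed=7))


@pytest.fixture(scope="session")
def morph_table():
    """Default simulated morphometrics cohort (20 males, 20 females)."""
    return simulate_morphometrics(MorphSimSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
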