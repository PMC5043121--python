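import numpy as np
import pytest

import dodgekin as dk


@pytest.fixture(scope="session")
def dims():
    return dk.BodyDimensions(hip_height=1.0, trunk_length=0.5, arm_length=0.7,
                             eye_height=1.6, shin_height=0.45)


@pytest.fixture(scope="session")
def model(dims):
    return dk.BodyModel(dims)


@pytest.fixture(scope="session")
def baseline():
    return dk.LumbarBaseline(lumbar_flexion_high=15.0, lumbar_flexion_mid=30.0,
                             lumbar_flexion_low=60.0)


@pytest.fixture(scope="session")
def ih_sets(dims, baseline):
    return {level: dk.impact_heights_for_level(dims, baseline, level)
            for level in (1, 2, 3)}


@pytest.fixture(scope="session")
def small_schedule(ih_sets):
    """Reduced round: one ball per impact height per set, no practice."""
    cfg = dk.ScheduleConfig(balls_per_set=5, balls_per_height=1,
                            lateral_offsets=(0.0,), practice=False, seed=3)
    return dk.generate_schedule(cfg, ih_sets)


@pytest.fixture(scope="session")
def noiseless_session(small_schedule, dims):
    return dk.simulate_session(small_schedule, dims, dk.StrategyProfile(),
                               seed=2, noise_std=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
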