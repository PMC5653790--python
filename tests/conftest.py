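import numpy as np
import pytest

from ringclock import (
    ClockParams,
    ColonyModel,
    LightSchedule,
    get_scenario,
    ring_deposition_times,
)


@pytest.fixture
def ld_schedule():
    """12:12 LD, lights on at t=0."""
    return LightSchedule()


@pytest.fixture
def dd_schedule():
    """Constant darkness from t=0 (previously entrained culture)."""
    return LightSchedule(dd_start=0.0)


@pytest.fixture
def clock_245():
    return ClockParams(free_running_period=24.5)


@pytest.fixture
def small_colony():
    """A colony small enough for fast full-image tests."""
    return ColonyModel(growth_rate=2.0, seed_center=(160.0, 160.0), start_radius=10.0,
                      duration=72.0, ring_amplitude=50.0)


@pytest.fixture
def dd_scenario():
    return get_scenario("dd_20C")


@pytest.fixture
def dd_truth(dd_schedule, clock_245):
    colony = ColonyModel(duration=144.0)
    return ring_deposition_times(dd_schedule, clock_245, 144.0, colony=colony)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
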