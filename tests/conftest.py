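import numpy as np
import pytest

from playmetrics.assessment import default_instrument
from playmetrics.pipeline import extract_cohort
from playmetrics.session import ExtractionConfig
from playmetrics.simulate import CohortConfig, simulate_cohort

#: Downscaled game durations so simulated fixtures stay fast.
SMALL_DURATIONS = {
    "boxes": 45.0,
    "sharing": 55.0,
    "pinwheel": 45.0,
    "creativity": 55.0,
    "catdog": 40.0,
}


def small_cohort_config(**overrides) -> CohortConfig:
    base = dict(
        n_children=8,
        durations=dict(SMALL_DURATIONS),
        motion_hz=50.0,
        touch_hz=40.0,
        seed=11,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    return extract_cohort(small_cohort.sessions, ExtractionConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
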