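import numpy as np
import pytest

from adlmotion.core import AcquisitionSpec, PhaseAnnotation
from adlmotion.synth import DRINKING_SCHEDULE, EATING_SCHEDULE, SynthConfig, simulate_dataset


@pytest.fixture(scope="session")
def spec():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def drinking_schedule():
    return DRINKING_SCHEDULE


@pytest.fixture(scope="session")
def eating_schedule():
    return EATING_SCHEDULE


@pytest.fixture
def equal_annotation():
    """Eight boundaries at whole seconds — every phase 1/7 of the cycle."""
    return PhaseAnnotation("eq", tuple(float(k) for k in range(8)))


@pytest.fixture(scope="session")
def small_dataset():
    """Three simulated drinking subjects (shared across read-only tests)."""
    return simulate_dataset(SynthConfig(n_subjects=3), seed=123)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
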