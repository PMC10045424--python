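import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from flexglove import (  # noqa: E402
    CalibrationModel,
    NoiseModel,
    build_hand_model,
)


@pytest.fixture(scope="session")
def model():
    return build_hand_model()


@pytest.fixture
def default_calib():
    return CalibrationModel.default()


@pytest.fixture
def zero_noise():
    return NoiseModel(0.0, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
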