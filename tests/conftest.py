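import numpy as np
import pytest

from amplimotion import calibrate, default_skeleton_model
from amplimotion.synth_motion import PlayerParams, generate_calibration_trace


@pytest.fixture(scope="session")
def avatar():
    return default_skeleton_model()


@pytest.fixture(scope="session")
def player_params():
    """A moderately impaired seated player used across tests."""
    return PlayerParams(amplitude_scale=0.3, seated=True, seed=42)


@pytest.fixture(scope="session")
def calibration_trace(player_params):
    return generate_calibration_trace(player_params)


@pytest.fixture(scope="session")
def profile(calibration_trace, avatar):
    return calibrate(calibration_trace, avatar)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
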