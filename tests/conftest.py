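import numpy as np
import pytest

from boldhrf.acquisition import preset_3t, preset_9p4t
from boldhrf.synthetic_data import HrfModel, NoiseModel


@pytest.fixture
def acq_uhf():
    return preset_9p4t()


@pytest.fixture
def acq_3t():
    return preset_3t()


@pytest.fixture
def plain_model():
    """Positive lobe only: peak 6 s, sigma-like width 2 s."""
    return HrfModel(
        amplitude_percent=1.0, peak_time_seconds=6.0, dispersion_seconds=2.0
    )


@pytest.fixture
def undershoot_model():
    return HrfModel(
        amplitude_percent=1.0,
        peak_time_seconds=5.0,
        dispersion_seconds=2.0,
        undershoot_ratio=0.3,
        undershoot_delay_seconds=10.0,
    )


@pytest.fixture
def quiet_noise():
    return NoiseModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
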