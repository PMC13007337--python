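import numpy as np
import pytest

from odorbulb import StimulusProtocol, sample_ground_truth
from odorbulb.simulate import TuningConfig


@pytest.fixture(scope="session")
def protocol():
    """Default acquisition protocol: 25 Hz, 3/5/16 s, 7 stimuli, 3 trials."""
    return StimulusProtocol()


@pytest.fixture(scope="session")
def small_tuning():
    """Compact noiseless tuning for fast unit tests (small frame, no drift)."""
    return TuningConfig(noise_sd=0.0, drift_max_px=0, frame_shape=(128, 128))


@pytest.fixture(scope="session")
def noiseless_gt(protocol, small_tuning):
    return sample_ground_truth(12, protocol, small_tuning, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
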