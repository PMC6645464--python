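import numpy as np
import pytest

from preictal.preprocess import preprocess_recording
from preictal.synth import SynthConfig, simulate_recording


@pytest.fixture(scope="session")
def small_cfg():
    # 4 channels, 2 minutes, alternating 60-s states, all effects planted
    return SynthConfig(n_channels=4, fs=8000.0, duration=120.0, duration_per_state=60.0, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return simulate_recording(small_cfg)


@pytest.fixture(scope="session")
def small_streams(small_recording):
    rec, _gt = small_recording
    return preprocess_recording(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
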