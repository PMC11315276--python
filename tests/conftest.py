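import numpy as np
import pytest

from vigispec import Channel, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=250.0, emg=None, **meta) -> Recording:
    channels = [Channel("EEG1", np.asarray(data, float))]
    if emg is not None:
        channels.append(Channel("EMG1", np.asarray(emg, float), role="emg"))
    return Recording(channels=channels, fs=fs, **meta)


@pytest.fixture
def white_recording(rng):
    """10 s of unit-variance white noise at 250 Hz."""
    return make_recording(rng.standard_normal(2500))
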