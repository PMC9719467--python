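import datetime as dt

import numpy as np
import pytest

from atonia import DetectionParams, EmgChannel, Role


@pytest.fixture(scope="session")
def params():
    return DetectionParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


RECORDING_START = dt.datetime(2024, 1, 1, 23, 0, 0)


def make_channel(samples, fs=256.0, role=Role.MENTALIS, label="EMG Ment"):
    return EmgChannel(role=role, samples=np.asarray(samples, dtype=float),
                      fs=fs, label=label)


def band_noise(rng, n, fs=256.0, rms=1.0):
    """Unit test noise: 10-100 Hz band-limited Gaussian, scaled to `rms`."""
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, [10.0, 100.0], btype="band", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x * x)) * rms
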