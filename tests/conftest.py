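import numpy as np
import pytest

from fogatsf import ImuRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(gyro, site="left_foot", rate_hz=100.0, t0_s=0.0, accel=None,
                   subject_id="test"):
    gyro = np.asarray(gyro, dtype=float)
    if gyro.ndim == 1:  # single-axis convenience: put signal on y
        g = np.zeros((gyro.size, 3))
        g[:, 1] = gyro
        gyro = g
    return ImuRecording(subject_id=subject_id, site=site, rate_hz=rate_hz,
                        t0_s=t0_s, gyro=gyro, accel=accel)


@pytest.fixture
def make_rec():
    return make_recording
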