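import numpy as np
import pytest
from hypothesis import settings

import turnkit as tk

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")

FS = 128.0


def make_trace(omega_dps, fs=FS, location="L5"):
    """YawTrace from a vertical angular-velocity series (trapezoid yaw)."""
    omega_dps = np.asarray(omega_dps, float)
    return tk.integrate_yaw(omega_dps, fs, location=location)


def make_recording(location="L5", n=1280, fs=FS, acc=None, gyr=None, mag=None):
    """Minimal valid ImuRecording; channels default to rest (1 g on VT)."""
    t = np.arange(n) / fs
    if acc is None:
        acc = np.vstack([np.ones(n), np.zeros(n), np.zeros(n)])
    if gyr is None:
        gyr = np.zeros((3, n))
    return tk.ImuRecording(location=location, t=t, acc=acc, gyr=gyr,
                           mag=mag, fs=fs)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return tk.control_like(seed=11, noise_gyr_dps=0.0, noise_acc_g=0.0,
                           noise_mag_gauss=0.0, gyro_bias_dps=(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def noiseless_session(noiseless_cfg):
    return tk.simulate_session(noiseless_cfg, subject_id="clean")


@pytest.fixture(scope="session")
def default_session():
    return tk.simulate_session(tk.control_like(seed=7), subject_id="noisy")


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_session):
    session, _ = noiseless_session
    return tk.analyze_session(session, tk.DetectionConfig(deadband_dps=0.0))
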