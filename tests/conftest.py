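import numpy as np
import pytest

from accelee.signal_io import RawAccelSignal


@pytest.fixture
def sinusoid_signal():
    """2-min, 30 Hz, 2 Hz sinusoid of 0.5 g amplitude on the x axis."""
    fs, dur = 30.0, 120.0
    t = np.arange(int(fs * dur)) / fs
    x = 0.5 * np.sin(2 * np.pi * 2.0 * t)
    zeros = np.zeros_like(x)
    return RawAccelSignal("sin2hz", t, x, zeros, zeros, fs)


def make_signal(record_id="sig", fs=30.0, dur_s=120.0, amp=0.5, freq=2.0,
                gravity_axis=None, noise_sd=0.0, seed=0):
    """Parametric single-axis test signal (motion on x)."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(fs * dur_s)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, len(t))
    y = np.zeros_like(x)
    z = np.zeros_like(x)
    if gravity_axis == "z":
        z = z + 1.0
    elif gravity_axis == "x":
        x = x + 1.0
    return RawAccelSignal(record_id, t, x, y, z, fs)
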