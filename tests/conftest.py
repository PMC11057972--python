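import logging

import numpy as np
import pytest

from myospect import EmgSignal, MotorUnitModel

# simulator support-truncation warnings are expected in tests that use
# deliberately small windows; keep them out of the captured output
logging.getLogger("myospect").setLevel(logging.ERROR)

FS = 20_000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_signal():
    """10 s of a unit 100 Hz sinusoid at the acquisition rate."""
    t = np.arange(int(10 * FS)) / FS
    return EmgSignal(np.sin(2 * np.pi * 100 * t), FS)


def make_sine(freq_hz: float, duration_s: float = 10.0, fs: float = FS) -> EmgSignal:
    t = np.arange(round(duration_s * fs)) / fs
    return EmgSignal(np.sin(2 * np.pi * freq_hz * t), fs)


@pytest.fixture
def default_unit():
    return MotorUnitModel(waveform_order=1, amplitude=1.0, lambda_ms=2.5, mean_rate=8.0, isi_cv=0.15)
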