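import numpy as np
import pytest

from ionobeat.acoustics import PressureTrace
from ionobeat.timing import ACQUISITION_SAMPLING_HZ


@pytest.fixture(scope="session")
def fs():
    return ACQUISITION_SAMPLING_HZ


@pytest.fixture()
def sinusoid_trace(fs):
    def make(f0, duration=30e-6, amplitude=1.0, phase=0.0):
        t = np.arange(int(duration * fs)) / fs
        return PressureTrace(amplitude * np.sin(2 * np.pi * f0 * t + phase), fs)

    return make


@pytest.fixture(scope="session")
def two_impulse_trace(fs):
    def make(dt_sep, amp2=0.6, duration=400e-6, i0=1000):
        p = np.zeros(int(duration * fs))
        i1 = i0 + int(round(dt_sep * fs))
        p[i0] = 1.0
        p[i1] = amp2
        return PressureTrace(p, fs), (i1 - i0) / fs

    return make
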