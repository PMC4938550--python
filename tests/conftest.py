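import numpy as np
import pytest

from neurosid.signal_io import AudioSignal


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sine_8k():
    """1 s of a 500 Hz sine at 8 kHz, nominal amplitude."""
    t = np.arange(8000) / 8000.0
    return AudioSignal(0.5 * np.sin(2 * np.pi * 500 * t), 8000.0, label="sine500")


def make_tone(freq, duration, rate, amp=0.5, phase=0.0):
    t = np.arange(int(round(duration * rate))) / rate
    return AudioSignal(amp * np.sin(2 * np.pi * freq * t + phase), rate)
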