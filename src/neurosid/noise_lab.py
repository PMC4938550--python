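"""Noise generation and exact-SNR mixing.

Three noise types are supported: white Gaussian, pink (1/f power spectrum,
-10 dB/decade PSD slope), and a street-noise surrogate (pink base,
low-passed at 3.7 kHz, with slow random amplitude modulation to mimic the
non-stationarity of traffic noise). All generators are driven by
``numpy.random.Generator`` (PCG64), so a fixed seed reproduces the waveform
bit for bit across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt

from .signal_io import AudioSignal

#: Sentinel SNR meaning "no noise added".
CLEAN = np.inf

#: Street-noise surrogate band limit, Hz.
STREET_BAND_LIMIT_HZ = 3700.0

_KINDS = ("white", "pink", "street")


@dataclass(frozen=True)
class NoiseSpec:
    """What noise to add and how much.

    ``snr_db`` may be :data:`CLEAN` (+inf) to request the clean condition.
    """

    kind: str
    snr_db: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {_KINDS}")


def _pink(rng: np.random.Generator, n: int) -> np.ndarray:
    # FFT spectral shaping of white Gaussian noise: |H(f)| ~ f^(-1/2)
    # gives a 1/f power spectrum (-10 dB/decade PSD slope).
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity; DC gain = that of the lowest bin
    spec *= f ** -0.5
    return np.fft.irfft(spec, n)


def gen_noise(spec: NoiseSpec, n: int, rate: float) -> AudioSignal:
    """Generate ``n`` samples of unit-RMS noise of the requested kind."""
    if n <= 0:
        raise ValueError("sample count must be positive")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "white":
        x = rng.standard_normal(n)
    elif spec.kind == "pink":
        x = _pink(rng, n)
    else:  # street surrogate
        x = _pink(rng, n)
        # zero-phase forward-backward pass: effective 10th-order roll-off
        sos = butter(5, STREET_BAND_LIMIT_HZ, btype="low", fs=rate, output="sos")
        x = sosfiltfilt(sos, x)
        # slow (~1 Hz) positive amplitude modulation for non-stationarity
        env_sos = butter(2, 1.0, btype="low", fs=rate, output="sos")
        env = sosfiltfilt(env_sos, rng.standard_normal(n))
        env = 1.0 + env / (3.0 * max(np.std(env), np.finfo(float).tiny))
        x = x * np.clip(env, 0.1, None)
    x = x / np.sqrt(np.mean(x**2))
    return AudioSignal(x, rate, label=f"{spec.kind} noise seed={spec.seed}")


def mix_at_snr(speech: AudioSignal, spec: NoiseSpec) -> AudioSignal:
    """Add generated noise to ``speech`` at exactly ``spec.snr_db``.

    The SNR is defined on the full segment: ``10*log10(P_speech /
    P_scaled_noise)``. A ``snr_db`` of +inf returns the speech unchanged.
    """
    if np.isinf(spec.snr_db) and spec.snr_db > 0:
        return AudioSignal(speech.samples.copy(), speech.rate, label=speech.label)
    p_speech = np.mean(speech.samples**2)
    if p_speech == 0.0:
        raise ValueError("speech power is zero; cannot set an SNR")
    noise = gen_noise(spec, speech.samples.size, speech.rate)
    p_noise = np.mean(noise.samples**2)
    scale = np.sqrt(p_speech / (p_noise * 10.0 ** (spec.snr_db / 10.0)))
    return AudioSignal(
        speech.samples + scale * noise.samples,
        speech.rate,
        label=f"{speech.label}+{spec.kind}@{spec.snr_db}dB",
    )


def measure_snr(speech: AudioSignal, noisy: AudioSignal) -> float:
    """SNR implied by a clean/noisy pair: ``10*log10(P_speech / P_residual)``.

    Returns +inf when the residual is identically zero.
    """
    if speech.samples.size != noisy.samples.size:
        raise ValueError("speech and noisy signals must have equal length")
    residual = noisy.samples - speech.samples
    p_res = np.mean(residual**2)
    if p_res == 0.0:
        return np.inf
    return float(10.0 * np.log10(np.mean(speech.samples**2) / p_res))
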