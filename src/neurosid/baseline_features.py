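"""Baseline acoustic front-ends: 39-dim MFCC and 22-dim GFCC.

Both operate on the raw (uncalibrated or calibrated) waveform and share the
GMM-UBM back-end with the neurogram feature, so identification experiments
compare front-ends only.

MFCC: pre-emphasis 0.97, 25 ms Hamming frames with 10 ms hop, 23-filter mel
bank, log, DCT; 13 cepstra with the 0th replaced by log frame energy, plus
2-frame-regression deltas and double-deltas (13 + 13 + 13 = 39).

GFCC: 64 ERB-spaced 4th-order gammatone channels (50 Hz to Nyquist), 10 ms
frame energies, cubic-root compression, DCT across channels, coefficients
1..22 kept (the noise-sensitive 0th is dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft
from scipy.signal import lfilter
from scipy.signal.windows import hamming

from .signal_io import AudioSignal

_LOG_FLOOR = 1e-30


@dataclass
class FeatureMatrix:
    """Frames x D feature matrix with its framing clock."""

    features: np.ndarray
    frame_hop_s: float
    kind: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        expected = {"mfcc": 39, "gfcc": 22}.get(self.kind)
        if expected is not None and self.features.shape[1] != expected:
            raise ValueError(
                f"{self.kind} features must be {expected}-dimensional, "
                f"got {self.features.shape[1]}"
            )

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def _frames(x: np.ndarray, flen: int, hop: int) -> np.ndarray:
    if x.size < flen:
        raise ValueError(
            f"signal of {x.size} samples shorter than one {flen}-sample frame"
        )
    n = (x.size - flen) // hop + 1
    idx = hop * np.arange(n)[:, None] + np.arange(flen)[None, :]
    return x[idx]


def _deltas(c: np.ndarray, n_reg: int = 2) -> np.ndarray:
    """Standard regression deltas over +/- n_reg frames (replicated edges)."""
    padded = np.concatenate(
        [np.repeat(c[:1], n_reg, axis=0), c, np.repeat(c[-1:], n_reg, axis=0)]
    )
    num = sum(
        k * (padded[n_reg + k : padded.shape[0] - n_reg + k]
             - padded[n_reg - k : padded.shape[0] - n_reg - k])
        for k in range(1, n_reg + 1)
    )
    return num / (2.0 * sum(k * k for k in range(1, n_reg + 1)))


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filt: int, nfft: int, rate: float) -> np.ndarray:
    mels = np.linspace(_hz_to_mel(0.0), _hz_to_mel(rate / 2.0), n_filt + 2)
    bins = np.floor((nfft + 1) * _mel_to_hz(mels) / rate).astype(int)
    fb = np.zeros((n_filt, nfft // 2 + 1))
    for i in range(n_filt):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        if mid > lo:
            fb[i, lo:mid] = (np.arange(lo, mid) - lo) / (mid - lo)
        if hi > mid:
            fb[i, mid:hi] = (hi - np.arange(mid, hi)) / (hi - mid)
    return fb


def mfcc39(sig: AudioSignal, n_mel: int = 23, preemph: float = 0.97) -> FeatureMatrix:
    """39-dim MFCC: 13 log-energy-based cepstra + deltas + double-deltas."""
    if sig.rate < 8000:
        raise ValueError("MFCC front-end expects a rate of at least 8 kHz")
    x = lfilter([1.0, -preemph], [1.0], sig.samples)
    flen = int(round(0.025 * sig.rate))
    hop = int(round(0.010 * sig.rate))
    frames = _frames(x, flen, hop)
    log_e = np.log(np.maximum(np.sum(frames**2, axis=1), _LOG_FLOOR))
    win = hamming(flen, sym=False)
    nfft = 1 << (flen - 1).bit_length()
    power = np.abs(rfft(frames * win, n=nfft, axis=1)) ** 2
    fb = _mel_filterbank(n_mel, nfft, sig.rate)
    log_mel = np.log(np.maximum(power @ fb.T, _LOG_FLOOR))
    ceps = dct(log_mel, type=2, norm="ortho", axis=1)[:, :13]
    ceps[:, 0] = log_e
    feats = np.hstack([ceps, _deltas(ceps), _deltas(_deltas(ceps))])
    return FeatureMatrix(feats, 0.010, "mfcc")


def _erb_rate(f):
    return 21.4 * np.log10(1.0 + 4.37 * np.asarray(f) / 1000.0)


def _erb_rate_inv(e):
    return (10.0 ** (np.asarray(e) / 21.4) - 1.0) * 1000.0 / 4.37


def _erb(f):
    return 24.7 * (4.37 * np.asarray(f) / 1000.0 + 1.0)


def _gammatone_out(x: np.ndarray, fc: float, rate: float) -> np.ndarray:
    """Real output of a unity-peak-gain 4th-order gammatone at ``fc``."""
    b = 1.019 * _erb(fc)
    r = np.exp(-2.0 * np.pi * b / rate)
    a = r * np.exp(2j * np.pi * fc / rate)
    y = x.astype(np.complex128)
    for _ in range(4):
        y = lfilter([1.0 - r], [1.0, -a], y)
    return 2.0 * y.real


def gfcc22(sig: AudioSignal, n_channels: int = 64, f_lo: float = 50.0) -> FeatureMatrix:
    """22-dim GFCC: gammatone channel energies, cube root, DCT, drop the 0th."""
    if sig.rate < 8000:
        raise ValueError("GFCC front-end expects a rate of at least 8 kHz")
    hop = int(round(0.010 * sig.rate))
    n_frames = sig.samples.size // hop
    if n_frames == 0:
        raise ValueError("signal shorter than one 10 ms frame")
    fcs = _erb_rate_inv(
        np.linspace(_erb_rate(f_lo), _erb_rate(0.99 * sig.rate / 2.0), n_channels)
    )
    energies = np.empty((n_frames, n_channels))
    for c, fc in enumerate(fcs):
        out = _gammatone_out(sig.samples, float(fc), sig.rate)
        seg = out[: n_frames * hop].reshape(n_frames, hop)
        energies[:, c] = np.mean(seg**2, axis=1)
    compressed = np.cbrt(energies)
    ceps = dct(compressed, type=2, norm="ortho", axis=1)
    return FeatureMatrix(ceps[:, 1:23], 0.010, "gfcc")


def extract_features(sig: AudioSignal, kind: str, **kw):
    """Dispatch: ``mfcc`` or ``gfcc`` (neurograms come from their own modules)."""
    if kind == "mfcc":
        return mfcc39(sig, **kw)
    if kind == "gfcc":
        return gfcc22(sig, **kw)
    raise ValueError(f"unknown baseline feature kind {kind!r}")
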