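"""Neurogram construction: the 2-D time x CF feature matrix.

Fiber rates simulated at the model rate are binned at 100 us, then smoothed
with a normalised 42 ms Hamming window advanced with 60% overlap (16.8 ms
hop, 25.2 ms effective frame length); the window-weighted mean of each frame
per CF is the feature. The "narrowband" variant keeps only the first 12 CFs
(below ~1 kHz), whose responses phase-lock and stay comparatively clean
under additive noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hamming

from .an_periphery import FiberRateMatrix


@dataclass
class NeurogramConfig:
    """CF grid and framing parameters of the neurogram."""

    n_cfs: int = 25
    cf_lo: float = 250.0
    cf_hi: float = 4000.0
    bin_width_s: float = 1e-4
    window_s: float = 0.042
    overlap_frac: float = 0.6
    narrowband_cfs: int = 12

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_frac < 1.0):
            raise ValueError("overlap_frac must be in (0, 1)")
        if self.narrowband_cfs > self.n_cfs:
            raise ValueError("narrowband_cfs cannot exceed n_cfs")
        if self.cf_lo >= self.cf_hi:
            raise ValueError("require cf_lo < cf_hi")

    @property
    def window_bins(self) -> int:
        return int(round(self.window_s / self.bin_width_s))

    @property
    def hop_bins(self) -> int:
        return int(round(self.window_bins * (1.0 - self.overlap_frac)))

    @classmethod
    def for_effective_window(cls, effective_ms: float, **kw) -> "NeurogramConfig":
        """Config whose effective frame length (overlap * window) is
        ``effective_ms``; e.g. 25.2 ms -> 42 ms window at 60% overlap."""
        return cls(window_s=effective_ms / 1000.0 / 0.6, **kw)


@dataclass
class Neurogram:
    """Frames x CFs matrix of windowed mean discharge rate (spikes/s)."""

    features: np.ndarray
    cfs: np.ndarray
    frame_hop_s: float
    source: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.cfs = np.asarray(self.cfs, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[1] != self.cfs.size:
            raise ValueError("features must be (n_frames, n_cfs)")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]


def make_cf_grid(cfg: NeurogramConfig) -> np.ndarray:
    """Logarithmically spaced CF grid: cf_i = lo * (hi/lo)^(i/(n-1))."""
    if cfg.n_cfs < 2:
        raise ValueError("need at least 2 CFs")
    return cfg.cf_lo * (cfg.cf_hi / cfg.cf_lo) ** (
        np.arange(cfg.n_cfs) / (cfg.n_cfs - 1)
    )


def bin_rates(rates: FiberRateMatrix, cfg: NeurogramConfig) -> np.ndarray:
    """Average fiber rates into fixed-width time bins (default 100 us).

    Each bin is the mean of the model-rate samples it covers; a trailing
    partial bin is dropped.
    """
    spb = rates.fs_model * cfg.bin_width_s
    if abs(spb - round(spb)) > 1e-9 or round(spb) < 1:
        raise ValueError("fs_model * bin_width_s must be a positive integer")
    spb = int(round(spb))
    n_bins = rates.rates.shape[0] // spb
    if n_bins == 0:
        raise ValueError("signal shorter than one bin")
    trimmed = rates.rates[: n_bins * spb]
    return trimmed.reshape(n_bins, spb, -1).mean(axis=1)


def frame_features(binned: np.ndarray, cfg: NeurogramConfig,
                   cfs: np.ndarray | None = None, source: str = "") -> Neurogram:
    """Window-weighted frame means: the neurogram features.

    Frame j, CF c: ``sum_n w_n x[jH+n, c] / sum_n w_n`` with ``w`` a Hamming
    window of ``window_bins`` bins and hop ``H = round(window * (1 -
    overlap))``. The normalisation makes the window a weighted mean, so a
    constant input passes through unchanged.
    """
    binned = np.asarray(binned, dtype=np.float64)
    w_bins, hop = cfg.window_bins, cfg.hop_bins
    n_bins = binned.shape[0]
    if n_bins < w_bins:
        raise ValueError(
            f"input has {n_bins} bins but one frame needs {w_bins} "
            f"({w_bins * cfg.bin_width_s * 1e3:.1f} ms minimum)"
        )
    win = hamming(w_bins, sym=False)
    win = win / win.sum()
    n_frames = (n_bins - w_bins) // hop + 1
    starts = hop * np.arange(n_frames)
    idx = starts[:, None] + np.arange(w_bins)[None, :]
    feats = np.einsum("w,fwc->fc", win, binned[idx])
    if cfs is None:
        cfs = make_cf_grid(cfg)
    return Neurogram(feats, cfs, cfg.hop_bins * cfg.bin_width_s, source=source)


def build_neurogram(rates: FiberRateMatrix, cfg: NeurogramConfig | None = None,
                    source: str = "") -> Neurogram:
    """Bin then frame a fiber-rate matrix into a neurogram."""
    cfg = cfg or NeurogramConfig()
    return frame_features(bin_rates(rates, cfg), cfg, cfs=rates.cfs, source=source)


def select_band(ng: Neurogram, band: str,
                cfg: NeurogramConfig | None = None) -> Neurogram:
    """Column subset: ``narrow`` keeps the first 12 CFs, ``wide`` keeps all."""
    if band == "wide":
        return ng
    if band != "narrow":
        raise ValueError(f"band must be 'narrow' or 'wide', got {band!r}")
    k = (cfg or NeurogramConfig()).narrowband_cfs
    k = min(k, ng.cfs.size)
    return Neurogram(ng.features[:, :k], ng.cfs[:k], ng.frame_hop_s, source=ng.source)


def neurogram_correlation(clean: Neurogram, noisy: Neurogram) -> np.ndarray:
    """Per-CF Pearson correlation between clean and noisy neurograms.

    Requires equal shapes (enforced upstream by trimming both signals with
    the clean utterance's VAD mask). Zero-variance columns yield NaN with a
    warning.
    """
    if clean.features.shape != noisy.features.shape:
        raise ValueError("clean and noisy neurograms must have equal shapes")
    a = clean.features - clean.features.mean(axis=0)
    b = noisy.features - noisy.features.mean(axis=0)
    sa = np.sqrt(np.sum(a**2, axis=0))
    sb = np.sqrt(np.sum(b**2, axis=0))
    bad = (sa == 0) | (sb == 0)
    if bad.any():
        warnings.warn("zero-variance CF column(s); correlation undefined there")
    denom = np.where(bad, np.nan, sa * sb)
    return np.sum(a * b, axis=0) / denom
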