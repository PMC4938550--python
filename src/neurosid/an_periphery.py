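"""Phenomenological auditory-periphery front-end.

Produces per-characteristic-frequency (CF) instantaneous discharge rates of
auditory-nerve fibers in response to a calibrated pressure waveform. The
chain has five blocks:

1. middle-ear band-pass filter,
2. a feed-forward control path (wide gammatone -> smoothed level in dB SPL)
   that sets the instantaneous gain/bandwidth of
3. the narrowband C1 basilar-membrane filter (4th-order gammatone realised
   as a cascade of complex one-pole sections with a level-dependent pole
   radius: bandwidth broadens and on-CF gain compresses as level rises),
4. inner-hair-cell transduction (asymmetric logarithmic nonlinearity
   followed by a fifth-order low-pass, which imposes the phase-locking
   roll-off above a few kHz),
5. an IHC-AN synapse with a saturating drive and exponential-plus-
   power-law-like adaptation (one fast kernel and four log-spaced kernels
   with tau^-1/2 weights).

Three spontaneous-rate (SR) fiber classes (high/medium/low) are simulated
per CF and mixed 0.6/0.2/0.2. The output is a deterministic rate (no spike
sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import butter, hilbert, lfilter, sosfilt

from .signal_io import P_REF, AudioSignal, resample

SR_CLASSES = ("high", "med", "low")

#: 10-dB bandwidth of a 4-stage complex one-pole cascade, in units of the
#: per-stage Lorentzian half-width: solve (1+x^2)^4 = 10 -> full width 2x.
_BW10_FACTOR = 2.0 * np.sqrt(10.0 ** 0.25 - 1.0)


def q10_base(cf: float | np.ndarray) -> float | np.ndarray:
    """Baseline sharpness of tuning (cat-like power law in CF)."""
    return 10.0 ** (0.4708 * np.log10(np.asarray(cf) / 1000.0) + 0.4664)


@dataclass
class ANConfig:
    """Parameters of the periphery model.

    ``q10_scale`` multiplies the baseline Q10: 2.0 halves the bandwidth
    (sharper), 0.25 makes it four times broader. ``level_params`` is
    ``(theta, s, gamma)``: the logistic midpoint (dB SPL), slope (dB) and
    maximum fractional bandwidth broadening of the C1 filter with level.
    """

    cfs: np.ndarray | None = None
    fs_model: float = 100_000.0
    q10_scale: float = 1.0
    sr_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)
    sr_spont: tuple[float, float, float] = (60.0, 4.0, 0.1)
    sr_sat: tuple[float, float, float] = (250.0, 150.0, 100.0)
    ihc_cutoff_hz: float = 3000.0
    ihc_order: int = 5
    level_params: tuple[float, float, float] = (60.0, 10.0, 1.0)
    #: IHC nonlinearity pressure scale, 1/Pa (onset of log compression).
    ihc_b: float = 3000.0
    #: synapse drive gain, spikes/s per unit IHC output.
    synapse_gain: float = 250.0
    #: adaptation kernel time constants, seconds (fast exponential first).
    adapt_taus: tuple[float, ...] = (0.002, 0.01, 0.1, 1.0, 3.0)
    #: total adaptation depth (sum of kernel weights, < 1).
    adapt_depth: float = 0.93
    #: weight of the fast (first) exponential kernel; the remaining kernels
    #: share ``adapt_depth - adapt_fast_weight`` with tau^-1/2 weights.
    adapt_fast_weight: float = 0.02

    def __post_init__(self) -> None:
        if self.cfs is None:
            from .neurogram import NeurogramConfig, make_cf_grid

            self.cfs = make_cf_grid(NeurogramConfig())
        self.cfs = np.asarray(self.cfs, dtype=np.float64)
        if abs(sum(self.sr_weights) - 1.0) > 1e-12:
            raise ValueError("sr_weights must sum to 1")
        if self.q10_scale <= 0:
            raise ValueError("q10_scale must be positive")
        if self.fs_model < 20.0 * self.cfs.max():
            raise ValueError("fs_model must be at least 20x the highest CF")

    def adapt_weights(self) -> np.ndarray:
        """Fast-kernel weight plus a tau^-1/2 ladder for the slow kernels.

        The slow (power-law-like) kernels share ``adapt_depth -
        adapt_fast_weight``; the total is < 1 so a sustained response
        survives adaptation.
        """
        w = np.asarray(self.adapt_taus[1:]) ** -0.5
        slow = (self.adapt_depth - self.adapt_fast_weight) * w / w.sum()
        return np.concatenate([[self.adapt_fast_weight], slow])

    def c1_base_bandwidth(self, cf: float) -> float:
        """Per-stage Lorentzian half-width (Hz) giving the baseline 10-dB
        bandwidth ``cf / (Q10_base * q10_scale)`` for the 4-stage cascade."""
        bw10 = cf / (q10_base(cf) * self.q10_scale)
        return bw10 / _BW10_FACTOR


@dataclass
class FiberRateMatrix:
    """SR-weighted instantaneous discharge rate, [time @ fs_model] x [CF]."""

    rates: np.ndarray
    cfs: np.ndarray
    fs_model: float

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.cfs = np.asarray(self.cfs, dtype=np.float64)
        if self.rates.ndim != 2 or self.rates.shape[1] != self.cfs.size:
            raise ValueError("rates must be (time, n_cfs)")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if self.rates.min() < 0:
            raise ValueError("rates must be nonnegative")


# ---------------------------------------------------------------------------
# stage 1: middle ear


def _middle_ear_sos(fs: float):
    return butter(2, [400.0, 6000.0], btype="bandpass", fs=fs, output="sos")


def middle_ear_filter(sig: AudioSignal, fs_model: float = 100_000.0) -> AudioSignal:
    """Band-pass filter standing in for middle-ear transmission.

    Near-unity gain around 1 kHz, >= 20 dB down at 50 Hz and 20 kHz.
    """
    if sig.rate != fs_model:
        raise ValueError(f"expected signal at fs_model={fs_model} Hz, got {sig.rate}")
    out = sosfilt(_middle_ear_sos(sig.rate), sig.samples)
    return AudioSignal(out, sig.rate, label=sig.label)


# ---------------------------------------------------------------------------
# complex one-pole gammatone machinery


def _analytic(x) -> np.ndarray:
    """Analytic signal of a real input (complex input passes through).

    Filtering the analytic signal removes the negative-frequency image, so
    a one-pole cascade behaves as a clean Lorentzian-skirt gammatone even
    when the bandwidth is a sizeable fraction of CF.
    """
    x = np.asarray(x)
    if np.iscomplexobj(x):
        return x
    return hilbert(x)


def _onepole_cascade_lti(x: np.ndarray, cf: float, beta: float, fs: float,
                         nstages: int = 4) -> np.ndarray:
    """LTI complex gammatone: cascade of identical one-pole sections.

    Expects the analytic input; per-stage gain is normalised to unity at
    CF, so an on-CF analytic tone passes with unit amplitude.
    """
    r = 1.0 - 2.0 * np.pi * beta / fs
    a = r * np.exp(2j * np.pi * cf / fs)
    y = _analytic(x).astype(np.complex128)
    for _ in range(nstages):
        y = lfilter([1.0 - r], [1.0, -a], y)
    return y


@njit(cache=False)
def _tv_gammatone(x_re: np.ndarray, x_im: np.ndarray, cos_t: float, sin_t: float,
                  r: np.ndarray, g: float, nstages: int) -> np.ndarray:
    """Time-varying 4th-order complex gammatone on an analytic input.

    ``r`` is the per-sample pole radius; the per-stage numerator gain ``g``
    is held at its low-level value, so on-CF gain falls as the bandwidth
    broadens (cochlear compression).
    """
    n = x_re.size
    cur_re = x_re.astype(np.float64)
    cur_im = x_im.astype(np.float64)
    for _ in range(nstages):
        acc_re = 0.0
        acc_im = 0.0
        out_re = np.empty(n)
        out_im = np.empty(n)
        for i in range(n):
            ar = r[i] * cos_t
            ai = r[i] * sin_t
            new_re = g * cur_re[i] + ar * acc_re - ai * acc_im
            new_im = g * cur_im[i] + ar * acc_im + ai * acc_re
            acc_re = new_re
            acc_im = new_im
            out_re[i] = new_re
            out_im[i] = new_im
        cur_re = out_re
        cur_im = out_im
    return cur_re


@njit(cache=False)
def _lowpass_cascade_2d(x: np.ndarray, p: float, order: int) -> np.ndarray:
    """Cascade of ``order`` identical one-pole low-pass sections, column-wise."""
    n, m = x.shape
    out = x.copy()
    g = 1.0 - p
    for _ in range(order):
        acc = np.zeros(m)
        for i in range(n):
            for j in range(m):
                acc[j] = g * out[i, j] + p * acc[j]
                out[i, j] = acc[j]
    return out


@njit(cache=False)
def _adapt_2d(y: np.ndarray, ps: np.ndarray, ws: np.ndarray) -> np.ndarray:
    """``y - sum_k w_k (y * e_k)`` with unit-DC-gain one-pole kernels e_k."""
    n, m = y.shape
    out = y.copy()
    k_n = ps.size
    acc = np.zeros((k_n, m))
    for i in range(n):
        for k in range(k_n):
            g = 1.0 - ps[k]
            for j in range(m):
                acc[k, j] = g * y[i, j] + ps[k] * acc[k, j]
                out[i, j] -= ws[k] * acc[k, j]
    return out


# ---------------------------------------------------------------------------
# stage 2: control path


def _smooth_rms(x2: np.ndarray, fs: float, tau: float = 0.005) -> np.ndarray:
    p = np.exp(-1.0 / (fs * tau))
    return np.sqrt(lfilter([1.0 - p], [1.0, -p], x2))


def control_path_level(sig, cf: float, cfg: ANConfig) -> np.ndarray:
    """Instantaneous stimulus level (dB SPL) seen by the OHC control path.

    A wide (2.5x the baseline C1 bandwidth) gammatone at ``cf``, RMS with
    5 ms exponential smoothing, converted to dB SPL and floored at 0.
    """
    if not (125.0 <= cf <= 20000.0):
        raise ValueError(f"cf {cf} Hz outside [125, 20000]")
    x = sig.samples if isinstance(sig, AudioSignal) else np.asarray(sig)
    beta = 2.5 * cfg.c1_base_bandwidth(cf)
    y = _onepole_cascade_lti(_analytic(x), cf, beta, cfg.fs_model)
    env = _smooth_rms(np.abs(y) ** 2 / 2.0, cfg.fs_model)
    return np.maximum(20.0 * np.log10(np.maximum(env, P_REF) / P_REF), 0.0)


def c1_filter(sig, cf: float, level_env: np.ndarray, cfg: ANConfig) -> np.ndarray:
    """Level-dependent narrowband basilar-membrane (C1) filter output.

    Instantaneous 10-dB bandwidth is the baseline value times
    ``1 + gamma * logistic((L - theta)/s)``; the numerator gain stays at its
    baseline value, so on-CF output grows at < 1 dB/dB above ``theta``.
    """
    x = sig.samples if isinstance(sig, AudioSignal) else np.asarray(sig)
    xa = _analytic(x)
    theta, s, gamma = cfg.level_params
    beta_ref = cfg.c1_base_bandwidth(cf)
    sigma = 1.0 / (1.0 + np.exp(-(level_env - theta) / s))
    beta = beta_ref * (1.0 + gamma * sigma)
    r = 1.0 - 2.0 * np.pi * beta / cfg.fs_model
    g = 2.0 * np.pi * beta_ref / cfg.fs_model
    theta_c = 2.0 * np.pi * cf / cfg.fs_model
    return _tv_gammatone(
        np.ascontiguousarray(xa.real), np.ascontiguousarray(xa.imag),
        np.cos(theta_c), np.sin(theta_c),
        np.ascontiguousarray(r), g, 4,
    )


# ---------------------------------------------------------------------------
# stage 3: inner hair cell


def ihc_transduce(bm: np.ndarray, cfg: ANConfig) -> np.ndarray:
    """IHC potential: asymmetric log nonlinearity + fifth-order low-pass.

    The static nonlinearity is ``log(1 + B|x|)`` with a 3:1 positive:negative
    gain asymmetry (the source of the rectified DC component); the low-pass
    is a cascade of ``ihc_order`` one-pole sections at ``ihc_cutoff_hz``,
    which removes the AC (phase-locked) component at high CFs.
    """
    bm = np.asarray(bm, dtype=np.float64)
    pot = np.log1p(cfg.ihc_b * np.abs(bm)) * np.where(bm >= 0, 1.0, -1.0 / 3.0)
    p = np.exp(-2.0 * np.pi * cfg.ihc_cutoff_hz / cfg.fs_model)
    squeeze = pot.ndim == 1
    out = _lowpass_cascade_2d(np.ascontiguousarray(np.atleast_2d(pot.T).T), p,
                              cfg.ihc_order)
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# stage 4: synapse


def synapse_adapt(ihc: np.ndarray, sr_class: str, cfg: ANConfig) -> np.ndarray:
    """Adapting synapse: saturating drive minus slow-kernel feedback.

    The IHC potential is half-wave rectified (transmitter release cannot go
    negative) and saturated, ``y = R * tanh(G * max(x, 0) / R)`` with
    ``R = r_max - r_spont``; the adaptation term ``sum_k a_k (y * e_tau_k)``
    (unit-DC-gain exponential kernels, one fast at 2 ms plus four log-spaced
    at 10 ms..3 s with tau^-1/2 weights, approximating power-law adaptation)
    produces the onset emphasis. Rates are floored at zero and equal the
    spontaneous rate for silent input.
    """
    if sr_class not in SR_CLASSES:
        raise ValueError(f"unknown SR class {sr_class!r}")
    i = SR_CLASSES.index(sr_class)
    spont, sat = cfg.sr_spont[i], cfg.sr_sat[i]
    x = np.asarray(ihc, dtype=np.float64)
    r_dr = sat - spont
    y = r_dr * np.tanh(cfg.synapse_gain * np.maximum(x, 0.0) / r_dr)
    ps = np.exp(-1.0 / (cfg.fs_model * np.asarray(cfg.adapt_taus)))
    squeeze = y.ndim == 1
    adapted = _adapt_2d(np.ascontiguousarray(np.atleast_2d(y.T).T), ps,
                        cfg.adapt_weights())
    if squeeze:
        adapted = adapted[:, 0]
    return np.maximum(0.0, spont + adapted)


# ---------------------------------------------------------------------------
# full chain


def simulate_periphery(sig: AudioSignal, cfg: ANConfig) -> FiberRateMatrix:
    """Run the full periphery: SR-weighted discharge rate per CF.

    The input must be calibrated in Pascal (see
    :func:`neurosid.signal_io.normalize_spl`); it is resampled internally to
    ``cfg.fs_model``. Deterministic: no spike sampling.
    """
    if sig.rate != cfg.fs_model:
        sig = resample(sig, cfg.fs_model)
    me = middle_ear_filter(sig, cfg.fs_model)
    xa = _analytic(me.samples)  # shared across CFs
    n = me.samples.size
    n_cf = cfg.cfs.size
    bm = np.empty((n, n_cf))
    for j, cf in enumerate(cfg.cfs):
        level = control_path_level(xa, float(cf), cfg)
        bm[:, j] = c1_filter(xa, float(cf), level, cfg)
    pot = ihc_transduce(bm, cfg)
    rates = np.zeros_like(pot)
    for w, sr in zip(cfg.sr_weights, SR_CLASSES):
        rates += w * synapse_adapt(pot, sr, cfg)
    return FiberRateMatrix(rates, cfg.cfs, cfg.fs_model)


# ---------------------------------------------------------------------------
# probes


def vector_strength(rate: np.ndarray, f0: float, fs_model: float) -> float:
    """Synchrony index in [0, 1] of a rate sequence to frequency ``f0``."""
    rate = np.asarray(rate, dtype=np.float64)
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    total = rate.sum()
    if total <= 0:
        raise ValueError("vector strength undefined for an all-zero rate")
    t = np.arange(rate.size) / fs_model
    return float(np.abs(np.sum(rate * np.exp(2j * np.pi * f0 * t))) / total)


def pure_tone(freq: float, duration: float, fs: float, level_db_spl: float,
              phase: float = 0.0) -> AudioSignal:
    """Calibrated pure tone: RMS equals ``P_REF * 10**(level/20)`` Pascal."""
    t = np.arange(int(round(duration * fs))) / fs
    amp = np.sqrt(2.0) * P_REF * 10.0 ** (level_db_spl / 20.0)
    return AudioSignal(amp * np.sin(2 * np.pi * freq * t + phase), fs,
                       label=f"tone {freq} Hz @ {level_db_spl} dB SPL")


def _steady_rate(sig: AudioSignal, cf: float, cfg: ANConfig,
                 sr_class: str = "high") -> float:
    """Mean rate over the final third of the response to ``sig`` at one CF."""
    me = middle_ear_filter(sig if sig.rate == cfg.fs_model else resample(sig, cfg.fs_model),
                           cfg.fs_model)
    level = control_path_level(me, cf, cfg)
    bm = c1_filter(me, cf, level, cfg)
    pot = ihc_transduce(bm, cfg)
    rate = synapse_adapt(pot, sr_class, cfg)
    return float(rate[-rate.size // 3:].mean())


def rate_level_curve(cf: float, levels_db, cfg: ANConfig | None = None,
                     sr_class: str = "high", duration: float = 0.25) -> np.ndarray:
    """Steady-state rate of one fiber for an on-CF tone at each level."""
    cfg = cfg or ANConfig(cfs=np.array([cf]))
    return np.array([
        _steady_rate(pure_tone(cf, duration, cfg.fs_model, lv), cf, cfg, sr_class)
        for lv in levels_db
    ])


def measure_bw10(cf: float, cfg: ANConfig | None = None, level_db: float = 40.0,
                 n_freqs: int = 61, duration: float = 0.15) -> float:
    """Measured 10-dB bandwidth (Hz) of the C1 stage from a tone sweep.

    Plays tones (straight into the control path and C1 filter, bypassing the
    middle ear so its response does not tilt the tuning curve) on a linear
    frequency grid sized to the design bandwidth, records the steady-state
    C1 output RMS, and reads off the width of the band within 10 dB of the
    peak (log-linear interpolation at the edges).
    """
    cfg = cfg or ANConfig(cfs=np.array([cf]))
    bw_design = cf / (q10_base(cf) * cfg.q10_scale)
    freqs = cf + np.linspace(-1.4, 1.4, n_freqs) * bw_design
    freqs = freqs[freqs >= 30.0]
    resp = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        sig = pure_tone(float(f), duration, cfg.fs_model, level_db)
        level = control_path_level(sig, cf, cfg)
        bm = c1_filter(sig, cf, level, cfg)
        tail = bm[-bm.size // 3:]
        resp[i] = np.sqrt(np.mean(tail**2))
    n_freqs = freqs.size
    resp_db = 20.0 * np.log10(resp / resp.max())
    above = resp_db >= -10.0
    lo_i = int(np.argmax(above))
    hi_i = int(len(above) - 1 - np.argmax(above[::-1]))

    def _edge(i_out: int, i_in: int) -> float:
        d0, d1 = resp_db[i_out], resp_db[i_in]
        frac = (-10.0 - d0) / (d1 - d0)
        return float(freqs[i_out] + frac * (freqs[i_in] - freqs[i_out]))

    f_lo = _edge(lo_i - 1, lo_i) if lo_i > 0 else float(freqs[0])
    f_hi = _edge(hi_i + 1, hi_i) if hi_i < n_freqs - 1 else float(freqs[-1])
    return f_hi - f_lo
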