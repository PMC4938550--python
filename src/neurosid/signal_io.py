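"""Audio I/O, resampling, SPL calibration and energy-based voice-activity trimming.

Samples in ``[-1, 1]`` straight off a WAV file are treated as uncalibrated;
:func:`normalize_spl` is the single point where physical pressure units
(Pascal, re 20 uPa) are imposed before the signal reaches the auditory
periphery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

log = logging.getLogger(__name__)

#: Reference pressure for dB SPL, in Pascal.
P_REF = 20e-6


@dataclass
class AudioSignal:
    """A mono pressure waveform with its sampling rate.

    Parameters
    ----------
    samples
        Amplitude sequence. Uncalibrated signals live in a nominal
        ``[-1, 1]`` range; after :func:`normalize_spl` they are in Pascal.
    rate
        Sampling frequency in Hz.
    label
        Free-text provenance tag.
    """

    samples: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal expects a 1-D sample array")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.size == 0:
            raise ValueError("zero-length audio")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass
class VadMask:
    """Frame-level keep/drop decisions from the energy VAD.

    The mask is computed once on a clean utterance and can be re-applied to a
    time-aligned noisy copy so that clean and noisy neurogram columns stay
    aligned frame for frame.
    """

    frame_length_s: float
    hop_s: float
    keep: np.ndarray
    threshold_db: float
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    def sample_mask(self) -> np.ndarray:
        """Expand the frame mask to a boolean per-sample mask."""
        # A sample is kept if any kept frame covers it.
        mask = np.zeros(self.n_samples, dtype=bool)
        frame = self.frame_length_s
        hop = self.hop_s
        last = self.keep.size - 1
        for i in np.flatnonzero(self.keep):
            lo = int(round(i * hop * self._rate))
            hi = min(lo + int(round(frame * self._rate)), self.n_samples)
            if i == last:  # final frame absorbs the partial tail
                hi = self.n_samples
            mask[lo:hi] = True
        return mask

    # set by vad_trim; needed to map frames back to samples
    _rate: float = field(default=0.0, repr=False)


def read_wav(path) -> AudioSignal:
    """Read a WAV file into a mono :class:`AudioSignal` scaled to ``[-1, 1]``.

    Integer PCM is scaled by the type's full-scale value (``2**(bits-1)``),
    so a full-scale 16-bit square wave maps to ``±32767/32768``. Stereo
    input is down-mixed by channel mean.
    """
    try:
        rate, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise IOError(f"cannot read WAV file {path!r}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError(f"zero-length audio in {path!r}")
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(2 ** (8 * data.dtype.itemsize - 1))
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioSignal(data, float(rate), label=str(path))


def write_wav(path, sig: AudioSignal, *, dtype: str = "float") -> None:
    """Write an :class:`AudioSignal` to a WAV file (IEEE float or 16-bit PCM)."""
    if dtype == "float":
        wavfile.write(path, int(sig.rate), sig.samples.astype(np.float32))
    elif dtype == "int16":
        clipped = np.clip(sig.samples, -1.0, 32767 / 32768)
        wavfile.write(path, int(sig.rate), np.round(clipped * 32768).astype(np.int16))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")


def resample(sig: AudioSignal, target_rate: float) -> AudioSignal:
    """Polyphase resampling to ``target_rate`` Hz.

    Duration is preserved to within one sample period and no spectral
    content is created above the original Nyquist frequency.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == sig.rate:
        return replace(sig, samples=sig.samples.copy())
    from fractions import Fraction

    frac = Fraction(int(round(target_rate)), int(round(sig.rate))).limit_denominator(10000)
    out = resample_poly(sig.samples, frac.numerator, frac.denominator)
    return AudioSignal(out, target_rate, label=sig.label)


def normalize_spl(sig: AudioSignal, target_db_spl: float) -> AudioSignal:
    """Scale a signal so its RMS equals ``P_REF * 10**(target_db_spl/20)`` Pascal.

    This is the calibration step: downstream of it, samples are physical
    pressures. Scale-equivariant (any positive prior gain is irrelevant)
    and idempotent under repeated application.
    """
    rms = sig.rms()
    if rms == 0.0:
        raise ValueError("cannot normalize an all-zero signal")
    target_rms = P_REF * 10.0 ** (target_db_spl / 20.0)
    return AudioSignal(sig.samples * (target_rms / rms), sig.rate, label=sig.label)


def spl_of(sig: AudioSignal) -> float:
    """Sound pressure level of a calibrated signal, dB re 20 uPa."""
    rms = sig.rms()
    if rms == 0.0:
        return -np.inf
    return 20.0 * np.log10(rms / P_REF)


def _frame_energies(x: np.ndarray, flen: int, hop: int) -> np.ndarray:
    n_frames = 1 + max(0, (x.size - flen)) // hop
    if x.size < flen:
        n_frames = 1
        x = np.pad(x, (0, flen - x.size))
    idx = np.arange(flen)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.sum(x[idx] ** 2, axis=1)


def vad_trim(
    sig: AudioSignal,
    frame_length_s: float = 0.025,
    hop_s: float = 0.010,
    threshold_db: float = -35.0,
) -> tuple[AudioSignal, VadMask]:
    """Energy-based voice-activity trimming.

    Frames whose short-time energy exceeds ``max frame energy + threshold_db``
    are kept; kept runs are dilated by one frame on each side so onsets and
    offsets are not clipped. The output is the concatenation of samples
    covered by kept frames.
    """
    if not (frame_length_s >= hop_s > 0):
        raise ValueError("require frame_length_s >= hop_s > 0")
    flen = int(round(frame_length_s * sig.rate))
    hop = int(round(hop_s * sig.rate))
    energies = _frame_energies(sig.samples, flen, hop)
    e_db = 10.0 * np.log10(energies + np.finfo(float).tiny)
    keep = e_db > (e_db.max() + threshold_db)
    if not keep.any():
        raise ValueError(
            f"VAD kept no frames at threshold {threshold_db} dB; "
            "lower the threshold or check the signal"
        )
    # one-frame dilation each side
    dil = keep.copy()
    dil[:-1] |= keep[1:]
    dil[1:] |= keep[:-1]
    mask = VadMask(frame_length_s, hop_s, dil, threshold_db, n_samples=sig.samples.size)
    mask._rate = sig.rate
    return apply_vad_mask(sig, mask), mask


def apply_vad_mask(sig: AudioSignal, mask: VadMask) -> AudioSignal:
    """Apply a previously computed VAD mask to a time-aligned signal.

    Used to trim a noisy copy of an utterance with the clean utterance's
    mask so the two stay sample-aligned.
    """
    if sig.samples.size != mask.n_samples:
        raise ValueError(
            f"signal length {sig.samples.size} does not match "
            f"mask length {mask.n_samples}"
        )
    smask = mask.sample_mask()
    return AudioSignal(sig.samples[smask], sig.rate, label=sig.label)
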