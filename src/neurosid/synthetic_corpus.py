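"""Synthetic multi-speaker formant-speech corpus.

Source-filter synthesis: a glottal pulse train (per-speaker pitch with slow
drift and cycle jitter, spectral tilt set by a glottal-shape parameter) is
filtered through a cascade of four second-order resonators whose centre
frequencies follow a random sequence of vowel-like formant targets derived
from the speaker's formant profile. Brief low-energy gaps exercise the
voice-activity detector. Every waveform is a deterministic function of
``(speaker seed, utterance seed)``, and ground-truth speaker parameters are
available for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_toeplitz
from scipy.signal import lfilter

from .signal_io import AudioSignal, write_wav

_FORMANT_RANGES = ((300.0, 900.0), (900.0, 2500.0), (2200.0, 3200.0), (3000.0, 4000.0))
_F0_RANGE = (90.0, 250.0)


@dataclass
class SpeakerProfile:
    """Generative voice parameters of one synthetic speaker."""

    f0_base: float
    formant_means: tuple[float, float, float, float]
    formant_bandwidths: tuple[float, float, float, float]
    glottal_shape: float
    seed: int

    def __post_init__(self) -> None:
        if not (80.0 <= self.f0_base <= 300.0):
            raise ValueError("f0_base outside [80, 300] Hz")
        f = self.formant_means
        if not (f[0] < f[1] < f[2] < f[3]):
            raise ValueError("formants must satisfy F1 < F2 < F3 < F4")
        if any(b <= 0 for b in self.formant_bandwidths):
            raise ValueError("formant bandwidths must be positive")


@dataclass
class CorpusSpec:
    """Corpus dimensions and reproducibility seed."""

    n_speakers: int = 10
    utterances_per_speaker: int = 12
    utterance_s: float = 1.5
    rate: float = 20_000.0
    train_fraction: float = 0.75
    master_seed: int = 42

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_speakers < 1 or self.utterances_per_speaker < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class UtteranceRecord:
    """One synthesized utterance plus its labels."""

    signal: AudioSignal
    speaker_id: str
    utterance_index: int
    split: str
    seed: int
    path: str = ""


def _normalized_distance(a: SpeakerProfile, b: SpeakerProfile,
                         include_f0: bool = True) -> float:
    """Euclidean distance in (f0, F1, F2), each normalised by its range.

    With ``include_f0=False`` only the (F1, F2) subspace is used — the
    axes a formant-based classifier can see.
    """
    spans = (
        _F0_RANGE[1] - _F0_RANGE[0],
        _FORMANT_RANGES[0][1] - _FORMANT_RANGES[0][0],
        _FORMANT_RANGES[1][1] - _FORMANT_RANGES[1][0],
    )
    va = (a.f0_base, a.formant_means[0], a.formant_means[1])
    vb = (b.f0_base, b.formant_means[0], b.formant_means[1])
    start = 0 if include_f0 else 1
    return float(np.sqrt(sum(
        ((x - y) / s) ** 2
        for x, y, s in zip(va[start:], vb[start:], spans[start:])
    )))


def sample_speakers(spec: CorpusSpec, min_separation: float = 0.15) -> list[SpeakerProfile]:
    """Draw speaker profiles with a lower bound on pairwise separation.

    Separation is Euclidean in (f0, F1, F2) normalised by each range's
    width; candidates closer than ``min_separation`` to an accepted speaker
    — in the full space or in the (F1, F2) subspace alone, so no pair
    differs only in pitch — are rejected (up to 1000 draws).
    """
    rng = np.random.default_rng([spec.master_seed, 101])
    speakers: list[SpeakerProfile] = []
    attempts = 0
    while len(speakers) < spec.n_speakers:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError(
                "could not place speakers with the requested separation; "
                "use fewer speakers or a smaller min_separation"
            )
        f0 = rng.uniform(*_F0_RANGE)
        formants = tuple(rng.uniform(lo, hi) for lo, hi in _FORMANT_RANGES)
        if not (formants[0] < formants[1] < formants[2] < formants[3]):
            continue
        cand = SpeakerProfile(
            f0_base=float(f0),
            formant_means=formants,
            formant_bandwidths=(
                float(rng.uniform(50, 90)),
                float(rng.uniform(70, 120)),
                float(rng.uniform(120, 200)),
                float(rng.uniform(180, 280)),
            ),
            glottal_shape=float(rng.uniform(0.95, 0.985)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if all(
            _normalized_distance(cand, s) >= min_separation
            and _normalized_distance(cand, s, include_f0=False) >= min_separation
            for s in speakers
        ):
            speakers.append(cand)
    return speakers


def _resonator_coeffs(freq: float, bw: float, rate: float):
    r = np.exp(-np.pi * bw / rate)
    theta = 2.0 * np.pi * freq / rate
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    b0 = 1.0 - 2.0 * r * np.cos(theta) + r * r
    return [b0], a


def _glottal_source(rng: np.random.Generator, n: int, rate: float,
                    f0_base: float, shape: float) -> np.ndarray:
    """Pulse train with slow f0 drift (+-10%) and 1% cycle jitter, shaped by
    a two-pole glottal low-pass and a radiation differentiator."""
    # smooth +-10% drift from a few random anchor points
    anchors = rng.uniform(-0.10, 0.10, size=6)
    drift = np.interp(np.arange(n), np.linspace(0, n - 1, 6), anchors)
    f0 = f0_base * (1.0 + drift)
    src = np.zeros(n)
    t = 0.0
    while True:
        i = int(round(t))
        if i >= n:
            break
        src[i] = 1.0
        period = rate / f0[i] * (1.0 + 0.01 * rng.standard_normal())
        t += max(period, 2.0)
    # glottal spectral tilt (-12 dB/oct) then radiation (+6 dB/oct)
    src = lfilter([1.0], [1.0, -2.0 * shape, shape * shape], src)
    return lfilter([1.0, -1.0], [1.0], src)


def synthesize_utterance(speaker: SpeakerProfile, utt_seed: int,
                         duration_s: float = 1.5,
                         rate: float = 20_000.0) -> AudioSignal:
    """Render one utterance: 3-6 vowel-like segments with 50 ms crossfades
    and one or two brief low-energy gaps; voiced fraction >= 70%."""
    if rate < 2.0 * speaker.formant_means[3]:
        raise ValueError("rate must be at least twice F4")
    rng = np.random.default_rng([speaker.seed, utt_seed])
    n = int(round(duration_s * rate))
    src = _glottal_source(rng, n, rate, speaker.f0_base, speaker.glottal_shape)

    # per-utterance formant perturbation, then per-segment vowel targets
    utt_factor = 1.0 + rng.uniform(-0.05, 0.05, size=4)
    n_seg = int(rng.integers(3, 7))
    bounds = np.linspace(0, n, n_seg + 1).astype(int)
    fade = int(round(0.050 * rate))
    out = np.zeros(n)
    window_sum = np.zeros(n)
    for k in range(n_seg):
        target_jitter = np.concatenate([
            1.0 + rng.uniform(-0.10, 0.10, size=2),   # F1, F2 move vowel to vowel
            1.0 + rng.uniform(-0.04, 0.04, size=2),   # F3, F4 nearly fixed
        ])
        formants = np.array(speaker.formant_means) * utt_factor * target_jitter
        formants = np.sort(formants)
        lo = max(bounds[k] - fade, 0)
        hi = min(bounds[k + 1] + fade, n)
        seg = src[lo:hi]
        for f, bw in zip(formants, speaker.formant_bandwidths):
            b, a = _resonator_coeffs(float(f), float(bw), rate)
            seg = lfilter(b, a, seg)
        win = np.ones(hi - lo)
        ramp = np.linspace(0, 1, fade)
        if lo > 0:
            win[:fade] = ramp
        if hi < n:
            win[-fade:] = ramp[::-1]
        out[lo:hi] += seg * win
        window_sum[lo:hi] += win
    out /= np.maximum(window_sum, 1e-12)

    # low-energy gaps (at most ~15% of the utterance stays unvoiced)
    n_gaps = int(rng.integers(1, 3))
    for _ in range(n_gaps):
        gap = int(round(rng.uniform(0.060, 0.100) * rate))
        start = int(rng.integers(fade, max(n - gap - fade, fade + 1)))
        taper = np.ones(gap)
        edge = min(gap // 4, int(0.01 * rate))
        if edge > 0:
            taper[:edge] = np.linspace(1, 0.02, edge)
            taper[edge:-edge] = 0.02
            taper[-edge:] = np.linspace(0.02, 1, edge)
        out[start:start + gap] *= taper

    out = out / np.sqrt(np.mean(out**2)) * 0.05
    peak = np.max(np.abs(out))
    if peak > 0.95:
        out *= 0.95 / peak
    return AudioSignal(out, rate, label=f"spk{speaker.seed}-utt{utt_seed}")


def generate_corpus(spec: CorpusSpec) -> list[UtteranceRecord]:
    """Synthesize the whole corpus in memory with the default split."""
    speakers = sample_speakers(spec)
    records: list[UtteranceRecord] = []
    for s_idx, sp in enumerate(speakers):
        sid = f"spk{s_idx:02d}"
        splits = default_split(spec, s_idx)
        for u in range(spec.utterances_per_speaker):
            utt_seed = int(
                np.random.SeedSequence([spec.master_seed, s_idx, u]).generate_state(1)[0]
            )
            sig = synthesize_utterance(sp, utt_seed, spec.utterance_s, spec.rate)
            records.append(UtteranceRecord(sig, sid, u, splits[u], utt_seed))
    return records


def default_split(spec: CorpusSpec, speaker_index: int) -> list[str]:
    """Per-speaker train/test assignment under the master seed."""
    rng = np.random.default_rng([spec.master_seed, 7, speaker_index])
    n = spec.utterances_per_speaker
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1) if n > 1 else n
    order = rng.permutation(n)
    split = ["test"] * n
    for i in order[:n_train]:
        split[i] = "train"
    return split


def resplit(records: list[UtteranceRecord], train_fraction: float,
            seed: int) -> list[UtteranceRecord]:
    """A fresh per-speaker train/test split of an existing corpus."""
    out = []
    by_speaker: dict[str, list[UtteranceRecord]] = {}
    for r in records:
        by_speaker.setdefault(r.speaker_id, []).append(r)
    for s_idx, (sid, recs) in enumerate(sorted(by_speaker.items())):
        rng = np.random.default_rng([seed, 13, s_idx])
        n = len(recs)
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1) if n > 1 else n
        order = rng.permutation(n)
        train_idx = set(int(i) for i in order[:n_train])
        for i, r in enumerate(recs):
            out.append(UtteranceRecord(r.signal, r.speaker_id, r.utterance_index,
                                       "train" if i in train_idx else "test",
                                       r.seed, r.path))
    return out


def build_corpus(spec: CorpusSpec, out_dir) -> pd.DataFrame:
    """Write WAV files and a CSV manifest (path, speaker, split, seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in generate_corpus(spec):
        fname = f"{rec.speaker_id}_u{rec.utterance_index:02d}.wav"
        write_wav(out_dir / fname, rec.signal)
        rows.append({
            "path": fname,
            "speaker": rec.speaker_id,
            "split": rec.split,
            "seed": rec.seed,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


# ---------------------------------------------------------------------------
# ground-truth-recovery helpers


def _lpc(x: np.ndarray, order: int) -> np.ndarray:
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1 : x.size + order]
    if ac[0] <= 0:
        raise ValueError("signal has no energy")
    return solve_toeplitz((ac[:-1], ac[:-1]), ac[1:])


def estimate_formants(sig: AudioSignal, n_formants: int = 2,
                      order: int = 12) -> np.ndarray:
    """LPC-based formant frequency estimates (Hz), lowest first.

    Pole angles of an autocorrelation LPC fit with bandwidth < 500 Hz are
    taken as formant candidates.
    """
    x = lfilter([1.0, -0.97], [1.0], sig.samples)
    a = _lpc(x, order)
    roots = np.roots(np.concatenate([[1.0], -a]))
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * sig.rate / (2 * np.pi)
    bws = -sig.rate / np.pi * np.log(np.maximum(np.abs(roots), 1e-12))
    cand = np.sort(freqs[(bws < 500.0) & (freqs > 150.0)])
    return cand[:n_formants]
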