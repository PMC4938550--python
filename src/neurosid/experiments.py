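"""Experiment orchestration: identification grids and correlation analyses.

Protocol throughout is train-on-clean / test-on-noisy (mismatched
conditions): speaker models are built from clean training utterances only;
test utterances are corrupted per grid cell before feature extraction.
Noisy test signals are trimmed with the clean utterance's VAD mask so that
clean and noisy neurogram frames stay aligned.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gmm_ubm
from .an_periphery import ANConfig, simulate_periphery
from .baseline_features import extract_features
from .neurogram import (
    Neurogram,
    NeurogramConfig,
    build_neurogram,
    make_cf_grid,
    neurogram_correlation,
    select_band,
)
from .noise_lab import CLEAN, NoiseSpec, mix_at_snr
from .signal_io import AudioSignal, apply_vad_mask, normalize_spl, vad_trim
from .synthetic_corpus import UtteranceRecord, resplit

log = logging.getLogger(__name__)

NEUROGRAM_KINDS = ("neurogram",)
BASELINE_KINDS = ("mfcc", "gfcc")


@dataclass
class ExperimentGrid:
    """The conditions to sweep. The clean condition is always evaluated."""

    feature_kinds: tuple = ("neurogram",)
    bands: tuple = ("narrow", "wide")
    noise_kinds: tuple = ("white",)
    snrs_db: tuple = (-5.0, 0.0, 5.0, 10.0, 15.0)
    effective_window_ms: tuple = (25.2,)
    spl_db: tuple = (70.0,)
    q10_scales: tuple = (1.0,)
    seeds: tuple = (0,)
    train_fraction: float = 0.75
    gmm_components: int = 16
    relevance: float = 16.0

    def __post_init__(self) -> None:
        for name in ("feature_kinds", "bands", "noise_kinds", "effective_window_ms",
                     "spl_db", "q10_scales", "seeds"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be nonempty")

    def snr_list(self) -> list[float]:
        snrs = [s for s in self.snrs_db if np.isfinite(s)]
        return snrs + [CLEAN]


def _noise_seed(*parts) -> int:
    """Stable noise seed from a mixed tuple (run- and platform-independent)."""
    ints = []
    for p in parts:
        if isinstance(p, str):
            ints.append(zlib.crc32(p.encode()))
        else:
            ints.append(int(round(10 * float(p))) % (2**31))
    return int(np.random.SeedSequence(ints).generate_state(1)[0])


@dataclass
class EvalResult:
    """Per-cell accuracies plus per-utterance decisions."""

    cells: pd.DataFrame
    decisions: pd.DataFrame


class NeurogramPipeline:
    """Clean-trim -> mix -> calibrate -> periphery -> neurogram, with a cache.

    The cache is keyed on (utterance, condition) and stores full 25-CF
    neurograms per window length; band selection happens on top, so narrow
    and wide features share one periphery run.
    """

    def __init__(self, an_cfg: ANConfig | None = None,
                 ng_cfg: NeurogramConfig | None = None,
                 windows_ms: tuple = (25.2,), spl_db: float = 70.0,
                 vad_threshold_db: float = -35.0):
        self.base_ng = ng_cfg or NeurogramConfig()
        self.an_cfg = an_cfg or ANConfig(cfs=make_cf_grid(self.base_ng))
        self.windows_ms = tuple(windows_ms)
        self.spl_db = spl_db
        self.vad_threshold_db = vad_threshold_db
        self._trimmed: dict = {}
        self._cache: dict = {}

    def _ng_cfg(self, window_ms: float) -> NeurogramConfig:
        return NeurogramConfig.for_effective_window(
            window_ms,
            n_cfs=self.base_ng.n_cfs, cf_lo=self.base_ng.cf_lo,
            cf_hi=self.base_ng.cf_hi, bin_width_s=self.base_ng.bin_width_s,
            narrowband_cfs=self.base_ng.narrowband_cfs,
        )

    def trimmed(self, rec: UtteranceRecord) -> AudioSignal:
        """The VAD-trimmed clean waveform of a record (cached)."""
        key = (rec.speaker_id, rec.utterance_index)
        if key not in self._trimmed:
            self._trimmed[key], _ = vad_trim(
                rec.signal, threshold_db=self.vad_threshold_db
            )
        return self._trimmed[key]

    def prepared(self, rec: UtteranceRecord, noise: NoiseSpec | None) -> AudioSignal:
        """Trimmed, optionally corrupted, SPL-calibrated waveform."""
        sig = self.trimmed(rec)
        if noise is not None and np.isfinite(noise.snr_db):
            sig = mix_at_snr(sig, noise)
        return normalize_spl(sig, self.spl_db)

    def neurograms(self, rec: UtteranceRecord,
                   noise: NoiseSpec | None = None) -> dict[float, Neurogram]:
        """Full-band neurograms of one utterance per window length."""
        cond = (None if noise is None or not np.isfinite(noise.snr_db)
                else (noise.kind, noise.snr_db, noise.seed))
        key = (rec.speaker_id, rec.utterance_index, cond,
               self.spl_db, self.an_cfg.q10_scale)
        if key not in self._cache:
            sig = self.prepared(rec, noise)
            rates = simulate_periphery(sig, self.an_cfg)
            self._cache[key] = {
                w: build_neurogram(rates, self._ng_cfg(w),
                                   source=f"{rec.speaker_id}/u{rec.utterance_index}")
                for w in self.windows_ms
            }
        return self._cache[key]

    def features(self, rec: UtteranceRecord, kind: str, band: str,
                 window_ms: float, noise: NoiseSpec | None = None) -> np.ndarray:
        """Feature matrix for one utterance under one condition."""
        if kind == "neurogram":
            ng = self.neurograms(rec, noise)[window_ms]
            return select_band(ng, band, self.base_ng).features
        sig = self.prepared(rec, noise)
        return extract_features(sig, kind).features


def run_identification(records: list[UtteranceRecord], grid: ExperimentGrid,
                       pipelines: dict | None = None,
                       ng_cfg: NeurogramConfig | None = None) -> EvalResult:
    """Run the full identification grid on a corpus.

    For every (seed, feature, band, window, SPL, Q10 scale) the speaker
    models are trained on the clean training split; every (noise, SNR) cell
    then corrupts the test split, extracts features and identifies. Cells
    that fail raise a log entry and a NaN accuracy, not an exception.
    Baseline features (MFCC/GFCC) are full-band front-ends and are
    evaluated once per cell regardless of the band axis (reported as
    ``wide``).
    """
    pipelines = pipelines if pipelines is not None else {}
    cells, decisions = [], []
    speakers = sorted({r.speaker_id for r in records})
    if len(speakers) == 1:
        log.warning("single-speaker corpus: identification is degenerate")
    for spl in grid.spl_db:
        for q10 in grid.q10_scales:
            pkey = (spl, q10)
            if pkey not in pipelines:
                ng = ng_cfg or NeurogramConfig()
                pipelines[pkey] = NeurogramPipeline(
                    an_cfg=ANConfig(cfs=make_cf_grid(ng), q10_scale=q10),
                    ng_cfg=ng, windows_ms=grid.effective_window_ms, spl_db=spl,
                )
            pipe = pipelines[pkey]
            for rep in grid.seeds:
                split = resplit(records, grid.train_fraction, rep)
                train = [r for r in split if r.split == "train"]
                test = [r for r in split if r.split == "test"]
                for kind in grid.feature_kinds:
                    bands = grid.bands if kind in NEUROGRAM_KINDS else ("wide",)
                    for window in grid.effective_window_ms:
                        models_by_band = {}
                        for band in bands:
                            by_speaker: dict[str, np.ndarray] = {}
                            for r in train:
                                f = pipe.features(r, kind, band, window)
                                by_speaker.setdefault(r.speaker_id, []).append(f)
                            by_speaker = {s: np.vstack(fs)
                                          for s, fs in sorted(by_speaker.items())}
                            models_by_band[band] = gmm_ubm.train_speaker_models(
                                by_speaker, n_components=grid.gmm_components,
                                seed=rep, relevance=grid.relevance,
                            )
                        for noise_kind in grid.noise_kinds:
                            for snr in grid.snr_list():
                                for band in bands:
                                    row = dict(feature=kind, band=band,
                                               noise=noise_kind, snr_db=snr,
                                               window_ms=window, spl_db=spl,
                                               q10_scale=q10, seed=rep)
                                    try:
                                        n_ok = 0
                                        for r in test:
                                            noise = None
                                            if np.isfinite(snr):
                                                noise = NoiseSpec(
                                                    noise_kind, snr,
                                                    _noise_seed(rep, r.speaker_id,
                                                                r.utterance_index,
                                                                noise_kind, 10 * snr),
                                                )
                                            f = pipe.features(r, kind, band,
                                                              window, noise)
                                            sid, margin = gmm_ubm.identify(
                                                models_by_band[band], f)
                                            ok = sid == r.speaker_id
                                            n_ok += ok
                                            decisions.append({
                                                **row,
                                                "speaker": r.speaker_id,
                                                "utterance": r.utterance_index,
                                                "decision": sid,
                                                "margin": margin,
                                                "correct": ok,
                                            })
                                        row.update(
                                            n_correct=n_ok, n_total=len(test),
                                            accuracy=100.0 * n_ok / len(test),
                                        )
                                    except Exception:  # keep the grid running
                                        log.exception("cell failed: %s", row)
                                        row.update(n_correct=np.nan,
                                                   n_total=len(test),
                                                   accuracy=np.nan)
                                    cells.append(row)
    return EvalResult(pd.DataFrame(cells), pd.DataFrame(decisions))


def accuracy_table(result: EvalResult) -> pd.DataFrame:
    """Noise x window rows, SNR columns (clean last), seed-averaged."""
    df = result.cells.copy()
    if df.empty:
        raise ValueError("no results to tabulate")
    df["snr_label"] = df["snr_db"].map(
        lambda s: "Clean" if not np.isfinite(s) else f"{s:g} dB"
    )
    order = [f"{s:g} dB" for s in sorted(set(df.snr_db[np.isfinite(df.snr_db)]))]
    order.append("Clean")
    table = df.pivot_table(
        index=["feature", "band", "noise", "window_ms"],
        columns="snr_label", values="accuracy", aggfunc="mean",
    )
    return table.reindex(columns=[c for c in order if c in table.columns])


def correlation_experiment(records: list[UtteranceRecord], noise_kinds,
                           snrs_db, n_utterances: int = 5,
                           pipeline: NeurogramPipeline | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Per-CF clean-vs-noisy neurogram correlation, mean and sd over
    utterances, for each (noise, SNR) condition.

    Both neurograms of a pair come from signals trimmed with the clean
    utterance's VAD mask, so their frames are time-aligned.
    """
    if n_utterances < 2:
        raise ValueError("need at least 2 utterances")
    pipe = pipeline or NeurogramPipeline()
    window = pipe.windows_ms[0]
    subset = records[:n_utterances]
    rows = []
    for noise_kind in noise_kinds:
        for snr in snrs_db:
            rs = []
            for i, rec in enumerate(subset):
                clean_ng = pipe.neurograms(rec)[window]
                if np.isfinite(snr):
                    spec = NoiseSpec(noise_kind, snr,
                                     _noise_seed(seed, noise_kind, i, 10 * snr))
                    noisy_ng = pipe.neurograms(rec, spec)[window]
                else:
                    noisy_ng = clean_ng
                rs.append(neurogram_correlation(clean_ng, noisy_ng))
            rs = np.array(rs)
            for c in range(rs.shape[1]):
                rows.append({
                    "noise": noise_kind, "snr_db": snr, "cf_index": c,
                    "cf_hz": float(pipe.an_cfg.cfs[c]),
                    "mean_r": float(np.nanmean(rs[:, c])),
                    "sd_r": float(np.nanstd(rs[:, c], ddof=1)),
                })
    return pd.DataFrame(rows)
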