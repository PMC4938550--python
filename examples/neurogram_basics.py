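"""Build a neurogram for one synthetic utterance.

Synthesizes a 1.5 s formant-speech utterance, trims silence, calibrates to
70 dB SPL, simulates 25 auditory-nerve fibers and prints the resulting
time x CF feature matrix's shape and summary statistics.
"""

import numpy as np

from neurosid.an_periphery import ANConfig, simulate_periphery
from neurosid.neurogram import NeurogramConfig, build_neurogram, make_cf_grid, select_band
from neurosid.signal_io import normalize_spl, vad_trim
from neurosid.synthetic_corpus import CorpusSpec, sample_speakers, synthesize_utterance

speaker = sample_speakers(CorpusSpec(n_speakers=1, master_seed=42))[0]
print(f"speaker: f0 = {speaker.f0_base:.0f} Hz, formants = "
      f"{[round(f) for f in speaker.formant_means]} Hz")

sig = synthesize_utterance(speaker, utt_seed=0, duration_s=1.5, rate=20_000.0)
trimmed, mask = vad_trim(sig)
print(f"VAD kept {trimmed.duration:.2f} s of {sig.duration:.2f} s")

calibrated = normalize_spl(trimmed, 70.0)
cfg = NeurogramConfig()
rates = simulate_periphery(calibrated, ANConfig(cfs=make_cf_grid(cfg)))
ng = build_neurogram(rates, cfg)
print(f"neurogram: {ng.n_frames} frames x {ng.cfs.size} CFs "
      f"(hop {ng.frame_hop_s * 1000:.1f} ms)")
print(f"rate range: {ng.features.min():.1f}-{ng.features.max():.1f} spikes/s")

narrow = select_band(ng, "narrow", cfg)
print(f"narrowband variant: {narrow.features.shape[1]} CFs up to "
      f"{narrow.cfs.max():.0f} Hz")
print("(each entry is the Hamming-weighted mean discharge rate of one fiber")
print(" in one 42 ms window; rows advance by 16.8 ms)")
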