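# Methods

## Overview

`neurosid` identifies speakers from simulated auditory-nerve (AN) responses.
The processing chain is: voice-activity trimming → SPL calibration → (optional
noise mixing) → auditory-periphery simulation → neurogram framing → GMM-UBM
classification. This note documents the model, its parameters and the design
choices, in that order.

## Pre-processing

The voice-activity detector computes short-time energy in 25 ms frames with a
10 ms hop and keeps frames within `threshold_db` (default −35 dB) of the
loudest frame, dilating kept runs by one frame per side so onsets are not
clipped. When a clean utterance and a noisy copy of it are compared, the
**clean** signal's mask is applied to both, which keeps their neurogram frames
time-aligned for correlation analysis.

Samples as read from WAV files are unitless in [−1, 1]. `normalize_spl` is
the single calibration point: it scales the waveform so its RMS equals
20 μPa · 10^(L/20) for a target level L in dB SPL (default 70 dB, applied
after VAD trimming and after any noise mixing; scaling does not change SNR).
All periphery stages downstream assume Pascal.

## Noise

Three generators, all unit-RMS and driven by `numpy.random.Generator`
(PCG64), so a fixed seed reproduces the waveform exactly:

- **white** — i.i.d. Gaussian;
- **pink** — FFT spectral shaping of white noise with |H(f)| ∝ f^(−1/2),
  giving a −10 dB/decade PSD slope;
- **street** (surrogate) — pink noise low-passed at 3.7 kHz (5th-order
  Butterworth applied forward-backward, i.e. a 10th-order zero-phase
  roll-off) and amplitude-modulated by a smoothed (~1 Hz) positive envelope.
  Real street recordings are not distributable; the surrogate reproduces the
  two properties that matter here — the ~3.7 kHz band limit and
  non-stationarity.

`mix_at_snr` scales the noise so that 10·log₁₀(P_speech/P_noise), measured
over the full (VAD-trimmed) segment, equals the requested SNR to within
0.01 dB. The clean condition is the sentinel SNR +∞.

## Auditory periphery

The front-end is a deliberately simplified, phenomenological periphery: five
blocks with explicit, testable contracts rather than a reimplementation of
any published full model. It reproduces the qualitative behaviours the
neurogram feature depends on — phase locking with high-frequency roll-off,
level-dependent tuning and compression, onset adaptation, and spontaneous-
rate (SR) classes — not exact physiological constants.

1. **Middle ear** — 2nd-order Butterworth band-pass, 400 Hz–6 kHz: near-unity
   gain around 1 kHz, ≥ 20 dB down at 50 Hz and 20 kHz.
2. **Control path** — per CF, a wide gammatone (2.5× the C1 bandwidth) whose
   smoothed RMS envelope (5 ms exponential window) is expressed in dB SPL.
   This is the feed-forward outer-hair-cell surrogate that sets the C1
   filter's instantaneous state.
3. **C1 (basilar-membrane) filter** — a 4th-order gammatone realised as four
   identical complex one-pole sections applied to the analytic (Hilbert)
   signal; using the analytic signal removes the negative-frequency image so
   the skirts stay Lorentzian even for very broad filters. The per-sample
   10-dB bandwidth is
   `BW(t) = (cf / (Q10(cf) · q10_scale)) · (1 + γ·σ((L(t) − θ)/s))`
   with the logistic σ, level L(t) from the control path, and defaults
   θ = 60 dB SPL, s = 10 dB, γ = 1 (bandwidth roughly doubles from 40 to
   90 dB). The numerator gain is pinned at its low-level value, so on-CF
   gain falls as the bandwidth broadens: output growth is < 1 dB/dB above θ
   (compression). The baseline sharpness is a cat-like power law
   Q10(cf) = 10^(0.4708·log₁₀(cf/1000) + 0.4664) (≈ 2.93 at 1 kHz);
   `q10_scale` multiplies it (2 → half bandwidth, 0.25 → 4× broader), and a
   tone-sweep measurement of the 10-dB bandwidth tracks the knob within 10%.
4. **Inner hair cell** — static nonlinearity `log(1 + B·|x|)` with a 3:1
   positive:negative gain asymmetry (B = 3000 /Pa, placing the onset of
   compression near typical basilar-membrane output amplitudes at
   conversational levels), followed by a 5th-order low-pass (five one-pole
   sections at 3 kHz). The low-pass is what removes the AC component at high
   CFs; with this cutoff, simulated vector strength falls from ≈ 0.6 at
   500 Hz to ≈ 0.05 at 4 kHz, i.e. phase locking is gone by 4–5 kHz.
5. **Synapse** — the IHC potential is half-wave rectified and saturated,
   `y = R·tanh(G·max(x,0)/R)` with R = r_max − r_spont per SR class and
   G = 250 (spikes/s per unit IHC output, set so the high-SR rate-level
   function is compressive above ~60 dB while a 70 dB onset still reaches
   the rail). Adaptation subtracts `Σ aₖ (y ⋆ e_τₖ)` with unit-DC-gain
   exponential kernels: one fast kernel (τ = 2 ms, weight 0.02) plus four
   log-spaced kernels τ ∈ {10 ms, 100 ms, 1 s, 3 s} with weights ∝ τ^(−1/2)
   approximating power-law adaptation, all weights summing to 0.93 so a
   sustained response survives. Saturation is applied to the drive *before*
   the adaptation subtraction: rectified transmitter release is what the
   adaptation stores see, and this ordering is what lets a 70 dB tone burst
   show both an onset/steady-state ratio ≥ 1.5 and a flatter rate-level
   slope at 80 dB than at 50 dB. Rates are floored at zero and equal the
   spontaneous rate in silence.

Three SR classes are simulated per CF — spontaneous rates (60, 4, 0.1)
spikes/s and saturation rates (250, 150, 100) for high/medium/low — and mixed
with weights 0.6/0.2/0.2. The output is the deterministic instantaneous rate;
no spike times are sampled. The model runs at 100 kHz (inputs are resampled
internally), which is required for the filter recursions, not for signal
bandwidth.

## Neurogram

Rates are averaged into 100 μs bins (trailing partial bin dropped), then
framed with a Hamming window of 420 bins (42 ms) advanced by
`round(420 · 0.4) = 168` bins (16.8 ms; 60% overlap; effective frame length
0.6 · 42 = 25.2 ms). The feature is the **window-weighted, normalised** mean
of each frame per CF — an unweighted mean would make the window a no-op, so
the weighted reading is the only self-consistent one. A constant input passes
through unchanged, every entry is a nonnegative rate, and the frame count
obeys `floor((n_bins − 420)/168) + 1`.

The CF grid is 25 points, logarithmically spaced 250–4000 Hz (cf₁₂ = 1 kHz
exactly). `narrow` keeps the first 12 columns (≤ 891 Hz), `wide` all 25.
Alternative time resolutions are specified by effective frame length e with
window = e/0.6: 7.6 → 12.7 ms (127 bins), 12 → 20 ms (200 bins). No feature
normalisation (log, CMVN) is applied by default.

## Baseline front-ends

- **MFCC (39-dim)**: pre-emphasis 0.97, 25 ms Hamming frames with 10 ms hop,
  23-filter mel bank, log, DCT; 13 cepstra with the 0th replaced by the log
  frame energy, plus 2-frame-regression deltas and double-deltas.
- **GFCC (22-dim)**: 64 ERB-spaced 4th-order gammatone channels (50 Hz to
  just below Nyquist), 10 ms rectangular frame energies, cubic-root
  compression, DCT across channels, coefficients 1–22 kept (the 0th is the
  most noise-sensitive and is dropped).

Both are full-band front-ends; in the experiment grids the band axis applies
to neurogram features only.

## Classifier

Diagonal-covariance GMM. EM starts from seeded k-means++ centres, iterates to
a relative log-likelihood gain < 10⁻⁴ or 100 iterations, floors per-dimension
variances at 10⁻³ × the global data variance (protects near-constant
neurogram dimensions), and records the per-iteration log-likelihood, which is
non-decreasing. The UBM is trained on the pooled clean training features of
all enrolled speakers (closed-set task); speaker models adapt the means only
(relevance factor 16), leaving weights and variances bit-identical to the
UBM. Identification is the arg-max of total log-likelihood, with ties broken
by enrolment order; the reported margin is the per-frame gap between best and
second best. Scores are raw log-likelihoods: for equal-length test inputs
UBM normalisation shifts every speaker equally and cannot change the arg-max.

The faithful default is 128 mixture components; the desk-scale experiments
use 16, matched to the few thousand training frames a 10-speaker synthetic
corpus provides.

## Synthetic corpus

Each speaker is a draw of f0 ∈ [90, 250] Hz, formant means F1 ∈ [300, 900],
F2 ∈ [900, 2500], F3 ∈ [2200, 3200], F4 ∈ [3000, 4000] Hz (ordered),
bandwidths in physiologic ranges, and a glottal-shape parameter. Rejection
sampling enforces a minimum pairwise distance of 0.15 (range-normalised
Euclidean) both in (f0, F1, F2) and in the (F1, F2) subspace alone, so no
pair of speakers differs only in pitch. An utterance is a glottal pulse train
(±10% slow f0 drift, 1% cycle jitter, two-pole glottal tilt plus radiation
differentiator) filtered through four cascaded second-order resonators that
follow 3–6 vowel-like formant targets (per-utterance ±5% scaling, per-target
±10% movement on F1/F2, ±4% on F3/F4) with 50 ms crossfades; one or two
60–100 ms low-energy gaps exercise the VAD, keeping the voiced fraction
≥ 70%. Everything is a deterministic function of (master seed, speaker index,
utterance index).

Default corpus: 10 speakers × 12 utterances × 1.5 s at 20 kHz, 75% train —
90 training and 30 test utterances, sized so the full closed-loop evaluation
runs in minutes on one CPU. A nearest-centroid classifier on per-utterance
LPC estimates of (F1, F2) already exceeds 80% accuracy, pinning the task as
solvable.

What the generator does **not** emulate: consonants and fricatives, channel
and handset effects, session variability, coarticulation, or natural prosody.
Passing results therefore demonstrate that the pipeline extracts and
preserves speaker-discriminative spectral structure under additive noise —
not performance on natural speech.

## Experiment protocol

Train-on-clean / test-on-noisy throughout. For each repetition seed the
corpus is re-split per speaker; the UBM and speaker models are trained on the
clean training split; test utterances are corrupted per grid cell (noise
type × SNR, grid {−5, 0, 5, 10, 15, clean} dB by default), features
extracted, and accuracy tabulated as 100·n_correct/n_total. Repetitions with
different splits are averaged. Failed cells are reported as missing, not as
zero. Accuracy tables order SNR columns ascending with clean last.

## Numerical choices and degenerate inputs

- Polyphase resampling (`scipy.signal.resample_poly`) — no energy above the
  source Nyquist; duration preserved to one sample.
- All stochastic components take explicit integer seeds; derived seeds are
  produced by `numpy.random.SeedSequence` from structural indices (speaker,
  utterance, condition), never from Python's salted `hash`.
- An all-zero signal is rejected at calibration (SPL undefined); a VAD that
  keeps no frames raises with the threshold named; zero-variance neurogram
  columns yield NaN correlation with a warning; an unoccupied mixture
  component under MAP with relevance 0 keeps its prior mean.
- Single-speaker identification returns that speaker with an infinite margin
  (flagged as degenerate in experiment logs).

## Known limitations

- The periphery is a behavioural surrogate: no two-tone suppression path,
  no C2/peak-splitting phenomena, no best-frequency shift with level, no
  spike-time generation or refractoriness.
- The street-noise surrogate matches the band limit and non-stationarity of
  traffic noise, nothing finer.
- Identification accuracies on the synthetic corpus characterise the
  pipeline, not any natural-speech benchmark; absolute numbers depend on the
  corpus difficulty (speaker separation, utterance length).
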