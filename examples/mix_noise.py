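"""Generate the three noise types and mix them at exact SNRs.

Shows that the mixer hits the requested SNR to within 0.01 dB and what
each generator's spectrum looks like in coarse octave bands.
"""

import numpy as np

from neurosid.noise_lab import NoiseSpec, gen_noise, measure_snr, mix_at_snr
from neurosid.signal_io import AudioSignal

rate = 20_000.0
t = np.arange(int(rate)) / rate
speech = AudioSignal(0.3 * np.sin(2 * np.pi * 300 * t), rate, label="tone")

for kind in ("white", "pink", "street"):
    noise = gen_noise(NoiseSpec(kind, 0.0, seed=7), 2**16, rate)
    spec = np.abs(np.fft.rfft(noise.samples)) ** 2
    f = np.fft.rfftfreq(noise.samples.size, 1 / rate)
    bands = [(125, 250), (250, 500), (500, 1000), (1000, 2000), (2000, 4000),
             (4000, 8000)]
    powers = [10 * np.log10(spec[(f >= lo) & (f < hi)].sum() / spec.sum())
              for lo, hi in bands]
    print(f"{kind:6s} octave-band power (dB re total):",
          " ".join(f"{p:6.1f}" for p in powers))

print()
for snr in (-5.0, 0.0, 10.0):
    noisy = mix_at_snr(speech, NoiseSpec("pink", snr, seed=3))
    print(f"requested {snr:+5.1f} dB -> measured {measure_snr(speech, noisy):+7.3f} dB")
print("(white is flat, pink falls 3 dB/octave, street is pink band-limited")
print(" to 3.7 kHz with slow amplitude modulation)")
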