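"""Clean-vs-noisy neurogram correlation per characteristic frequency.

Adds 0 dB white noise to a few utterances and correlates each CF row of
the noisy neurogram with its clean counterpart. Low CFs stay correlated
(phase locking rides the high-energy voiced harmonics); high CFs do not.
"""

from neurosid.experiments import NeurogramPipeline, correlation_experiment
from neurosid.synthetic_corpus import CorpusSpec, generate_corpus

records = generate_corpus(
    CorpusSpec(n_speakers=3, utterances_per_speaker=2, utterance_s=1.5,
               master_seed=42)
)
pipe = NeurogramPipeline()
corr = correlation_experiment(records, ["white"], [0.0], n_utterances=5,
                              pipeline=pipe)

print("CF (Hz)   mean r    sd")
for _, row in corr.iterrows():
    bar = "#" * int(max(row.mean_r, 0) * 40)
    print(f"{row.cf_hz:7.0f}   {row.mean_r:+.3f}  {row.sd_r:.3f}  {bar}")

low = corr[corr.cf_hz < 891].mean_r.mean()
high = corr[corr.cf_hz > 2000].mean_r.mean()
print(f"\nmean r below 891 Hz: {low:.3f}; above 2 kHz: {high:.3f}")
print("(the gap is why the narrowband feature — first 12 CFs — is the robust")
print(" choice under noise, at the cost of some accuracy in quiet)")
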