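# tremorkit

Scriptable analysis of tremor electrophysiology recordings: wrist
accelerometry (ACC) plus surface EMG of the antagonist forearm muscles
(extensor and flexor carpi radialis, ECR/FCR), up to six channels, any
sampling rate, loaded from plain-text files — the universal export format of
clinical acquisition systems.

The electrophysiological work-up of tremor distinguishes essential tremor,
enhanced physiological tremor, parkinsonian rest tremor, functional tremor
and orthostatic tremor by where the tremor's spectral peak lies (organic
tremors span ~3–18 Hz), whether ACC and EMG oscillate coherently, and how
these change across conditions. `tremorkit` provides that analysis chain as
a library and CLI for clinicians and researchers who have the standard
hardware but lack analysis software:

* **Preprocessing** — third-order zero-phase Butterworth band-limiting
  (ACC 2–30 Hz; EMG 20–300 Hz), with full-wave rectification and 30 Hz
  low-pass smoothing of EMG to demodulate the burst envelope.
* **Spectra** — full-segment FFT power spectra (one-sided,
  Parseval-normalized) and tremor-band peak-frequency extraction.
* **Coherence** — segmented magnitude-squared coherence with split-cosine
  tapering, the scalar 95% confidence limit `1 − α^(1/(L−1))` for L
  segments, and per-frequency confidence intervals via the atanh(√C)
  variance-stabilizing transform.
* **Spectrograms** — sliding ~1 s power-of-two windows with 50% overlap.
* **Agreement statistics** — ICC(A,1) (two-way random effects, single
  rater, absolute agreement) with McGraw–Wong 95% CIs and Koo–Li
  reliability categories, plus a harness that scores the agreement of two
  peak-frequency extraction procedures over a cohort of recordings.
* **Synthetic tremor simulator** — a seedable generator of six-channel
  recordings (central oscillator driving ACC plus burst-modulated EMG
  noise), used by the test suite in place of patient data.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Simulate a 30 s, 1000 Hz recording with a 5 Hz tremor, run the full
pipeline, and check ACC–EMG coherence:

```sh
tremorkit simulate --f0 5 --seed 42 -o rec.txt
tremorkit run rec.txt --fs 1000 -o results
```

`results/peaks.json` (first entries):

```json
[
  {
    "channel": "L-ACC",
    "peak_freq_hz": 4.966666666666667,
    "peak_power": 10002.16103276512,
    "band_lo_hz": 3.0,
    "band_hi_hz": 18.0
  },
  {
    "channel": "L-ECR",
    "peak_freq_hz": 4.966666666666667,
    "peak_power": 359.3110252846608,
    "band_lo_hz": 3.0,
    "band_hi_hz": 18.0
  }
]
```

Every channel's spectral peak lands on the frequency-grid bin nearest the
simulated 5 Hz tremor (grid step 1/30 Hz; the simulator's slow frequency
drift puts this run's peak one bin below 5.0). The run directory also holds
per-channel spectra, coherence tables with confidence intervals
(`coherence_L-ACC_L-ECR.csv`: L = 30 one-second segments, 95% confidence
limit 0.098 — the simulated coherent tremor peak at 5 Hz sits far above
it), spectrograms, and a `manifest.json` that records every setting needed
to reproduce the run.

The simulated validation study — does the full pipeline agree with a bare
direct-FFT peak extractor across a cohort? — runs as:

```sh
tremorkit validate --n 10 --seed 7
```

```json
{
  "ACC": {"estimate": 1.0, "ci_low": 1.0, "ci_high": 1.0, "category": "excellent"},
  "ECR": {"estimate": 0.9999862686502445, "ci_low": 0.9999659181091156,
          "ci_high": 0.9999945270145518, "category": "excellent"},
  "FCR": {"estimate": 1.0, "ci_low": 1.0, "ci_high": 1.0, "category": "excellent"}
}
```

An ICC(A,1) near 1 per channel group means the two procedures return
essentially identical tremor frequencies for every simulated patient.

The same statistics are available from Python:

```python
import tremorkit as tk

rec = tk.simulate_recording(f0=5.0, seed=42)
acc = tk.preprocess_acc(rec.channel("L-ACC"), rec.fs)
emg = tk.preprocess_emg(rec.channel("L-ECR"), rec.fs)
peak = tk.peak_frequency(tk.power_spectrum(acc, rec.fs), band=(3, 18))
coh = tk.msc(acc, emg, rec.fs, window_samples=1024)
```

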