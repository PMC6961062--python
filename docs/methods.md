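# Methods

`tremorkit` implements the standard electrophysiological work-up of upper-limb
tremor: multi-channel recordings of wrist accelerometry (ACC) and surface EMG
from antagonist forearm muscles (extensor and flexor carpi radialis, ECR/FCR)
are conditioned per channel role, transformed to the frequency domain, and
compared across channels by magnitude-squared coherence. An ICC-based
agreement module quantifies how closely two peak-frequency extraction
procedures agree across a cohort of recordings.

## Signal model and preprocessing

Organic tremors oscillate between roughly 3 Hz (cerebellar) and 18 Hz
(orthostatic). The ACC channel measures that oscillation directly, so it is
band-passed to 2–30 Hz: wide enough to keep every organic tremor and a first
harmonic, narrow enough to reject DC/gravitational drift and mains
interference. Surface EMG carries tremor information differently — motor
units fire in bursts once per tremor cycle, amplitude-modulating a broadband
(tens to hundreds of Hz) interference pattern. EMG channels are therefore
band-passed to 20–300 Hz to isolate that carrier, then full-wave rectified
and smoothed: rectification demodulates the burst envelope, shifting
burst-rate power down into the tremor band where it can be compared with the
ACC spectrum.

All filters are third-order Butterworth. They are applied zero-phase
(forward–backward with reflection padding), a deliberate choice: coherence
and burst-timing analyses need the temporal alignment between ACC and EMG
preserved, and a causal pass would delay each band differently. The cost is
that the effective magnitude response is |H(f)|² — attenuation at the nominal
cutoffs is −6 dB rather than −3 dB — which every test oracle accounts for.

The smoothing stage is a 30 Hz third-order zero-phase Butterworth low-pass
applied after rectification. The cutoff matches the upper edge of the tremor
analysis band (and the ACC low-pass), so the envelope retains everything the
peak search can use while carrier ripple is removed. Nyquist violations
(high cutoff ≥ fs/2, or EMG preprocessing at fs ≤ 600 Hz) are hard errors,
never silently clamped: a silently narrowed band would change clinical
interpretation.

## Spectra and peak extraction

The full-segment spectrum is a plain FFT of the demeaned signal — no taper,
no segment averaging — reported one-sided with Parseval normalization: the
sum of power bins equals the signal's sum of squared deviations. Demeaning
matters because the rectified EMG envelope has a large DC term that would
otherwise dominate both the display scale and the peak search; the DC bin is
reported as zero. Frequency resolution is fs/N (1/30 Hz for the standard
30 s at 1000 Hz recording).

Peak extraction returns the frequency of the largest bin inside a band,
default 3–18 Hz. Exact ties break toward the lower frequency
(deterministic); a band with identically zero power returns "no peak"
(`None`) rather than an arbitrary bin.

## Coherence and its confidence statistics

Magnitude-squared coherence between two channels uses the segmented
estimator standard in sensorimotor neurophysiology: L = ⌊N/W⌋ contiguous
non-overlapping windows of W samples, each demeaned and tapered with a
split-cosine bell (raised-cosine ramps over ⌈pW⌉ samples per end, p = 0.1 by
default), cross- and auto-spectra averaged over windows *before* the ratio

    C(f) = |Σ X_l conj(Y_l)|² / (Σ |X_l|² · Σ |Y_l|²).

Averaging before the ratio is essential — per-segment coherence is
identically 1 — so L = 1 is rejected as degenerate. Non-overlapping
segments are used because the null-distribution theory below assumes
independent segments. No taper power correction is applied to coherence:
the window's scale cancels in the ratio.

Under independence the estimator's CDF is 1 − (1 − C)^(L−1), giving the
scalar 95% confidence limit **1 − α^(1/(L−1))** (0.95 at L = 2, falling
strictly with L); coherence above the line is significant at level α.
Per-frequency confidence intervals use the variance-stabilizing transform
g = atanh(√C), approximately normal with variance 1/(2L): bounds are
tanh(g ∓ z₁₋α/₂/√(2L))², with the lower argument floored at zero so the
interval always contains the estimate and respects [0, 1]. Bins with zero
denominator (possible at DC after demeaning) report coherence 0.

## Spectrogram

Time-resolved spectra use sliding windows of W = the power of two nearest
the sampling rate (1024 at 1000 Hz, ~1 s; exact midpoints round up), hopping
by W/2 (50% overlap). Each frame is demeaned, Hann-tapered — the
conventional window for 50% overlap — and transformed with the same
one-sided power convention as the full-segment spectrum. The frame count is
exactly ⌊(N − W)/(W/2)⌋ + 1; an incomplete trailing frame is dropped rather
than zero-padded, matching the coherence module's remainder policy.
Timestamps are frame-center samples divided by fs.

## Agreement statistics

The validation statistic is ICC(A,1): intraclass correlation under a two-way
random-effects model, single rater, absolute agreement. From the two-way
ANOVA mean squares (MSR between subjects, MSC between raters, MSE residual):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)).

Absolute agreement is the right form when two analysis packages must report
the *same* frequency: unlike the consistency form it penalizes systematic
offsets. The 95% CI is the McGraw & Wong F-distribution construction with
Satterthwaite degrees of freedom (cross-checked in the test suite against
both a raw sums-of-squares oracle and pingouin's ICC2 row). Degenerate
inputs with zero total variance raise an error; the perfect-agreement corner
(MSC = MSE = 0) collapses the CI to [1, 1]; negative estimates are reported
as computed, not floored.

Reliability categories follow Koo & Li: poor < 0.5 ≤ moderate < 0.75 ≤
good < 0.9 ≤ excellent, applied to the CI lower bound by default (a flag
switches to the point estimate). The boundary values 0.5/0.75/0.9 are
assigned to the higher category; this left-closed convention is a documented
constant since verbal range descriptions leave the boundaries ambiguous.

`compare_extractors` builds one subjects × 2 ratings matrix per channel
group (ACC, ECR, FCR — pooled across limbs, one row per recording-channel
pair) and returns ICC(A,1) per group. `run_simulated_validation` exercises
it on a simulated cohort: half the recordings "postural" with tremor
frequency uniform in 4–8 Hz (essential-tremor-like), half "rest" in 3–6 Hz
(parkinsonian-like), 30 s at 1000 Hz each — comparing the full-pipeline
extractor against a deliberately different reference (raw FFT for ACC,
rectify-then-FFT for EMG, no filtering).

## Synthetic tremor generator

The generator is the package's test bed and ships as first-class code. Per
limb, a central oscillator d(t) = sin(φ(t)) drives both modalities:

* **ACC** = amp·(coupling·d + (1−coupling)·d′) + noise, where d′ is an
  independent oscillator (for two-oscillator negative controls) and the
  noise is white Gaussian shaped to 2–30 Hz — deliberately inside the ACC
  passband so preprocessing cannot trivially remove it.
* **EMG** = broadband white noise × (1 + m·max(0, sin(φ + θ))): noise
  amplitude-modulated by the half-wave-rectified drive, i.e. one burst per
  tremor cycle. Half-wave (not full-wave) rectification of the modulator
  keeps the burst fundamental at f0 rather than 2·f0. The flexor channel's
  bursts sit at phase θ = π relative to the extensor's (alternating
  activation), so burst-pattern analyses remain possible.

Defaults: fs = 1000 Hz, 30 s, f0 = 5 Hz, ACC amplitude 1.0 with noise SD
0.3, EMG noise SD 1.0 with modulation depth m = 0.7, coupling 1.0. These
mirror a typical clinical recording: a clear but not noise-free tremor with
strongly burst-modulated EMG.

Instantaneous frequency wanders as a mean-reverting AR(1) walk: per-sample
Gaussian steps of 0.002 Hz, reversion time constant 1 s, clipped to
f0 ± 0.5 Hz. Mean reversion is deliberate: tremor frequency is stable within
a recording session, and an unanchored random walk at this step size would
drift the 30 s spectral peak by several tenths of a Hz, which is not what
clinical full-segment analysis encounters. With these defaults the recovered
peak stays within two grid bins (0.067 Hz) of f0 across seeds.

All randomness derives from one seed via `numpy` SeedSequence spawning (one
substream per limb × {oscillator, second oscillator, ACC noise, ECR noise,
FCR noise}), so recordings are bitwise reproducible and channels are
statistically independent where the model says they are.

What the generator does **not** emulate: biomechanical limb resonance and
loading effects, mechanical-reflex components, EMG motor-unit structure
(shape, recruitment), electrode artifacts, movement artifacts, and
non-stationarity beyond slow frequency drift. Passing tests therefore show
the analysis machinery is correct and calibrated on signals with the right
first-order structure — not that it handles every pathology of real
recordings.

## Numerical choices and test design

* Zero-phase filtering uses reflection padding of 3 × the coefficient
  length; inputs shorter than the pad are rejected.
* Filter correctness is checked against the analytic Butterworth magnitude
  response (|H|², squared again for the power of the two-pass application),
  by two empirical routes: the FFT of a measured impulse response
  (deterministic, accurate down to gains of 1e−7) and a white-noise Welch
  spectrum ratio (statistical, meaningful where the zero-phase gain exceeds
  0.05 — below that the estimate is leakage-limited at any practical data
  volume).
* The FFT path is verified against a direct O(N²) discrete-Fourier sum and
  Parseval's identity; the coherence estimator against a from-scratch
  evaluation of its defining formula at L = 2; the Halliday limit and CI
  against independent arithmetic; the coherence null calibration by
  Monte-Carlo (per-bin exceedance of the 95% limit ≈ 5% over 50 independent
  noise pairs).
* Simulation-based test sizes (10–50 seeds, 30–60 s signals) were chosen to
  keep each statistical check's sampling error well below its asserted
  margin while the full suite runs in seconds.

## Known limitations

* The split-cosine taper fraction (0.1 per end) and the CI transform are
  documented conventions for an estimator family whose literature admits
  variants; both are exposed as parameters where they matter.
* ICC significance tests (p-values for ICC > 0) are not provided — only
  estimates, CIs and categories.
* No notch filtering, artifact rejection, or resampling; recordings are
  assumed contiguous and clean. Missing values are load-time errors by
  design.
* The agreement harness requires every extractor to succeed on every
  channel; it does not handle partially missing ratings.
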