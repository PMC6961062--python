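"""Seedable generator of physiologically structured synthetic tremor
recordings.

The generative model mimics a central-oscillator tremor: a common drive
d(t) = sin(phi(t)) whose instantaneous frequency wanders slowly around the
tremor frequency f0, shared between the limb's accelerometer and its EMG.

* ACC channel: the drive (optionally mixed with an independent second
  oscillator for negative controls) plus band-limited 2-30 Hz noise, so that
  preprocessing cannot trivially strip all of it.
* EMG channels: broadband white noise whose *amplitude* is modulated by the
  half-wave-rectified drive — bursts once per tremor cycle, the textbook
  surface-EMG picture. Rectifying and smoothing such a signal demodulates
  the burst envelope back to f0, which is exactly what the EMG
  preprocessing pipeline is designed to do. The flexor channel's bursts are
  phase-shifted relative to the extensor's (alternating activation by
  default, pi radians).

Frequency jitter is a mean-reverting (AR(1)) random walk: per-sample
Gaussian steps of scale ``freq_jitter_sd`` with a 1 s reversion time
constant, clipped to f0 +/- 0.5 Hz. Mean reversion keeps the simulated
tremor frequency stable over a 30 s recording — as clinical tremor is
within a session — so the full-segment spectral peak stays within the grid
resolution of f0; an unanchored walk would drift the peak by several times
that. All randomness flows from a single seed through per-channel
substreams, so recordings are bitwise reproducible.

Standard montage (matching a bilateral upper-limb tremor study): L-ACC,
L-ECR, L-FCR, R-ACC, R-ECR, R-FCR — wrist accelerometer plus extensor and
flexor carpi radialis surface EMG per limb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .exceptions import InsufficientDataError, ParameterError
from .preprocess import FilterSpec, butter_bandpass
from .recording_io import ChannelRole, ChannelSpec, Limb, Recording

__all__ = ["TremorSimParams", "simulate_oscillator", "simulate_recording", "MONTAGE"]

MONTAGE = (
    ChannelSpec("L-ACC", ChannelRole.ACC, 0, Limb.LEFT),
    ChannelSpec("L-ECR", ChannelRole.EMG, 1, Limb.LEFT),
    ChannelSpec("L-FCR", ChannelRole.EMG, 2, Limb.LEFT),
    ChannelSpec("R-ACC", ChannelRole.ACC, 3, Limb.RIGHT),
    ChannelSpec("R-ECR", ChannelRole.EMG, 4, Limb.RIGHT),
    ChannelSpec("R-FCR", ChannelRole.EMG, 5, Limb.RIGHT),
)

_JITTER_CLIP_HZ = 0.5
_JITTER_TAU_S = 1.0  # mean-reversion time constant of the frequency walk


@dataclass(frozen=True)
class TremorSimParams:
    """Parameters of the synthetic tremor generator.

    fs: sampling rate in Hz.
    duration_s: recording length in seconds.
    f0: tremor frequency in Hz; organic tremors span 3-18 Hz and the
        default enforces that band (disable via ``enforce_tremor_band`` for
        negative controls).
    freq_jitter_sd: per-sample scale (Hz) of the mean-reverting frequency walk.
    acc_amp: amplitude of the tremor oscillation on the ACC channel.
    acc_noise_sd: SD of the white noise shaped to 2-30 Hz and added to ACC.
    emg_burst_depth: modulation depth m in [0, 1] of EMG noise amplitude by
        the rectified drive; 0 = no bursts, 1 = fully gated.
    emg_noise_sd: SD of the broadband EMG carrier noise.
    antagonist_phase: phase offset (radians) of flexor bursts relative to
        extensor bursts; pi = alternating activation.
    coupling: fraction in [0, 1] of the oscillator shared between the ACC
        and the EMG drive; below 1 the ACC mixes in an independent second
        oscillator (two-oscillator negative control).
    seed: master RNG seed; every channel draws from its own substream.
    """

    fs: float = 1000.0
    duration_s: float = 30.0
    f0: float = 5.0
    freq_jitter_sd: float = 0.002
    acc_amp: float = 1.0
    acc_noise_sd: float = 0.3
    emg_burst_depth: float = 0.7
    emg_noise_sd: float = 1.0
    antagonist_phase: float = math.pi
    coupling: float = 1.0
    seed: int = 0
    enforce_tremor_band: bool = True

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.enforce_tremor_band and not 3.0 <= self.f0 <= 18.0:
            raise ParameterError(
                f"f0={self.f0} Hz is outside the organic tremor band [3, 18] Hz "
                "(set enforce_tremor_band=False for negative controls)"
            )
        for name in ("freq_jitter_sd", "acc_noise_sd", "emg_noise_sd", "acc_amp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.emg_burst_depth <= 1.0:
            raise ParameterError(
                f"emg_burst_depth must be in [0, 1], got {self.emg_burst_depth}"
            )
        if not 0.0 <= self.coupling <= 1.0:
            raise ParameterError(f"coupling must be in [0, 1], got {self.coupling}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _oscillator_phase(params: TremorSimParams, rng: np.random.Generator) -> np.ndarray:
    """Instantaneous phase of the central oscillator (radians)."""
    n = params.n_samples
    if params.freq_jitter_sd > 0:
        steps = rng.normal(0.0, params.freq_jitter_sd, n)
        rho = 1.0 - 1.0 / (params.fs * _JITTER_TAU_S)
        # AR(1) recursion j[i] = rho * j[i-1] + steps[i] as an IIR filter
        jitter = lfilter([1.0], [1.0, -rho], steps)
        jitter = np.clip(jitter, -_JITTER_CLIP_HZ, _JITTER_CLIP_HZ)
    else:
        jitter = np.zeros(n)
    inst_freq = params.f0 + jitter
    return np.cumsum(2.0 * np.pi * inst_freq / params.fs)


def simulate_oscillator(
    params: TremorSimParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Unit-amplitude oscillator drive d(t) = sin(phi(t)).

    With ``freq_jitter_sd = 0`` this is a pure sinusoid at f0. Deterministic
    for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    return np.sin(_oscillator_phase(params, rng))


def _half_rectified(phase: np.ndarray, offset: float) -> np.ndarray:
    return np.maximum(np.sin(phase + offset), 0.0)


def simulate_recording(params: TremorSimParams | None = None, **overrides) -> Recording:
    """Six-channel synthetic tremor recording (L/R x ACC, ECR, FCR).

    Per limb, with d the limb's oscillator drive and d' an independent one:

        ACC = acc_amp * (coupling * d + (1 - coupling) * d') + shaped noise
        EMG = emg_noise_sd * white * (1 + m * halfrect(d at muscle phase))

    Both limbs use independent oscillators and noise. Accepts either a
    :class:`TremorSimParams` or keyword overrides of its defaults.
    """
    if params is None:
        params = TremorSimParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    n = params.n_samples
    if n < 2 * params.fs:
        raise InsufficientDataError(
            f"recording of {params.duration_s} s is too short; need at least 2 s"
        )
    # one substream per (limb, source): osc, osc', acc noise, ECR noise, FCR noise
    streams = np.random.SeedSequence(params.seed).spawn(10)
    rngs = [np.random.default_rng(s) for s in streams]
    acc_noise_spec = FilterSpec(2.0, 30.0, 3)

    channels = []
    for limb_idx in range(2):
        r_osc, r_osc2, r_accn, r_ecrn, r_fcrn = rngs[limb_idx * 5 : limb_idx * 5 + 5]
        phase = _oscillator_phase(params, r_osc)
        d = np.sin(phase)
        if params.coupling < 1.0:
            d2 = np.sin(_oscillator_phase(params, r_osc2))
            acc_drive = params.coupling * d + (1.0 - params.coupling) * d2
        else:
            acc_drive = d
        if params.acc_noise_sd > 0:
            shaped = butter_bandpass(
                r_accn.normal(0.0, params.acc_noise_sd, n), params.fs, acc_noise_spec
            )
        else:
            shaped = np.zeros(n)
        acc = params.acc_amp * acc_drive + shaped

        m = params.emg_burst_depth
        ecr = r_ecrn.normal(0.0, params.emg_noise_sd, n) * (
            1.0 + m * _half_rectified(phase, 0.0)
        )
        fcr = r_fcrn.normal(0.0, params.emg_noise_sd, n) * (
            1.0 + m * _half_rectified(phase, params.antagonist_phase)
        )
        channels.extend([acc, ecr, fcr])

    samples = np.column_stack(channels)
    return Recording(samples=samples, fs=params.fs, channels=list(MONTAGE))
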