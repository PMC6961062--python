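"""Role-specific conditioning of ACC and surface-EMG channels.

Accelerometer channels are band-limited to 2–30 Hz, covering every known
organic tremor (roughly 3 Hz for cerebellar tremor up to 18 Hz for
orthostatic tremor) while rejecting DC offset and gravitational drift. EMG
channels are band-limited to 20–300 Hz to keep the motor-unit spike content,
then full-wave rectified and smoothed: rectification demodulates the burst
envelope, moving burst-rate power down into the tremor band where it can be
compared against the accelerometer.

All filters are third-order Butterworth, applied zero-phase
(forward-backward), so the effective magnitude response is |H(f)|^2 and
temporal alignment between channels is preserved — a prerequisite for
meaningful ACC-EMG coherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import InsufficientDataError, NyquistError

__all__ = [
    "FilterSpec",
    "ACC_BAND",
    "EMG_BAND",
    "FILTER_ORDER",
    "SMOOTH_CUTOFF_HZ",
    "butter_bandpass",
    "preprocess_acc",
    "preprocess_emg",
    "rectify",
    "smooth",
    "preprocess_channel",
]

# Defaults for the analysis bands; all overridable per call.
ACC_BAND = (2.0, 30.0)
EMG_BAND = (20.0, 300.0)
FILTER_ORDER = 3
SMOOTH_CUTOFF_HZ = 30.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass parameters (low/high cutoffs in Hz, order)."""

    low_cut_hz: float
    high_cut_hz: float
    order: int = FILTER_ORDER

    def __post_init__(self) -> None:
        if self.low_cut_hz <= 0:
            raise ValueError(f"low cutoff must be > 0, got {self.low_cut_hz}")
        if self.high_cut_hz <= self.low_cut_hz:
            raise ValueError(
                f"high cutoff ({self.high_cut_hz}) must exceed low cutoff ({self.low_cut_hz})"
            )
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")


def _design_bandpass(spec: FilterSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nyq = fs / 2.0
    if spec.high_cut_hz >= nyq:
        raise NyquistError(
            f"high cutoff {spec.high_cut_hz} Hz is not below Nyquist ({nyq} Hz at fs={fs})"
        )
    b, a = signal.butter(spec.order, [spec.low_cut_hz, spec.high_cut_hz], btype="band", fs=fs)
    return b, a


def _filtfilt(b: np.ndarray, a: np.ndarray, x: np.ndarray) -> np.ndarray:
    # Reflection padding, pad length 3 x filter length: scipy's default
    # transient suppression, kept explicit so the contract is visible.
    padlen = 3 * max(len(a), len(b))
    if len(x) <= padlen:
        raise InsufficientDataError(
            f"signal of {len(x)} samples is too short for zero-phase filtering "
            f"(needs > {padlen})"
        )
    return signal.filtfilt(b, a, x, padlen=padlen)


def butter_bandpass(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth band-pass; same length as the input."""
    x = np.asarray(x, dtype=float)
    b, a = _design_bandpass(spec, fs)
    return _filtfilt(b, a, x)


def preprocess_acc(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = ACC_BAND,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Condition an accelerometer channel: band-pass 2-30 Hz (zero-phase)."""
    return butter_bandpass(x, fs, FilterSpec(band[0], band[1], order))


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification: y[i] = |x[i]|."""
    return np.abs(np.asarray(x, dtype=float))


def smooth(
    x: np.ndarray,
    fs: float,
    cutoff_hz: float = SMOOTH_CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase low-pass smoothing of a rectified EMG envelope.

    Cutoff defaults to 30 Hz — the upper edge of the tremor analysis band —
    so that burst-rate content survives while carrier ripple is removed.
    """
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        raise NyquistError(
            f"smoothing cutoff {cutoff_hz} Hz is not below Nyquist ({nyq} Hz at fs={fs})"
        )
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=fs)
    return _filtfilt(b, a, np.asarray(x, dtype=float))


def preprocess_emg(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = EMG_BAND,
    order: int = FILTER_ORDER,
    smooth_cutoff_hz: float = SMOOTH_CUTOFF_HZ,
) -> np.ndarray:
    """Condition a surface-EMG channel for tremor-band frequency analysis.

    Pipeline: band-pass 20-300 Hz -> full-wave rectification -> low-pass
    smoothing. The output is the burst envelope; it may undershoot zero
    slightly because the final smoothing stage can ring.
    """
    if fs <= 2 * band[1]:
        raise NyquistError(
            f"EMG preprocessing needs fs > {2 * band[1]} Hz for the {band[1]} Hz "
            f"low-pass; got fs={fs}"
        )
    y = butter_bandpass(x, fs, FilterSpec(band[0], band[1], order))
    y = rectify(y)
    return smooth(y, fs, cutoff_hz=smooth_cutoff_hz, order=order)


def preprocess_channel(x: np.ndarray, fs: float, role) -> np.ndarray:
    """Dispatch on channel role (ACC or EMG); accepts the enum or its name."""
    from .recording_io import ChannelRole

    role = ChannelRole(role) if not isinstance(role, ChannelRole) else role
    if role is ChannelRole.ACC:
        return preprocess_acc(x, fs)
    return preprocess_emg(x, fs)
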