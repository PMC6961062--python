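"""Time-resolved spectra: sliding ~1 s power-of-two windows, 50% overlap.

The window length defaults to the power of two nearest the sampling rate, so
at 1000 Hz each frame covers 1024 samples (~1 s) — long enough to resolve
tremor frequencies (grid step fs/W ≈ 1 Hz) yet short enough to track changes
such as re-emergent tremor or frequency shifts between conditions. Frames
hop by W/2 (50% overlap); each frame is demeaned, Hann-windowed, and
transformed to a one-sided power spectrum. An incomplete trailing frame is
dropped rather than zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, ParameterError

__all__ = ["Spectrogram", "pow2_window", "spectrogram"]


@dataclass
class Spectrogram:
    """Power as a matrix over (frequency, time): shape n_freqs x n_times."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    window_samples: int

    @property
    def n_frames(self) -> int:
        return len(self.times)


def pow2_window(fs: float) -> int:
    """Power of two nearest to the sampling rate; ties resolve upward.

    pow2_window(1000) == 1024 — roughly one second of data per frame at the
    common tremor-study sampling rate.
    """
    if fs < 16:
        raise ParameterError(f"sampling rate must be >= 16 Hz, got {fs}")
    target = round(fs)
    lo = 2 ** int(np.floor(np.log2(target)))
    hi = lo * 2
    if target - lo < hi - target:
        return lo
    return hi  # nearer to hi, or exact midpoint (ties go up)


def spectrogram(
    x: np.ndarray, fs: float, window_samples: int | None = None
) -> Spectrogram:
    """Sliding-window one-sided power spectrogram with 50% overlap.

    Frame count is floor((N - W) / (W/2)) + 1; frame timestamps are the
    frame-center sample divided by fs. Power normalization matches
    :func:`tremorkit.spectral.power_spectrum` applied per frame (Hann taper
    added; DC bin zeroed by the per-frame demeaning convention).
    """
    x = np.asarray(x, dtype=float)
    W = pow2_window(fs) if window_samples is None else int(window_samples)
    if W < 16:
        raise ParameterError(f"window must be >= 16 samples, got {W}")
    n = len(x)
    if n < W:
        raise InsufficientDataError(
            f"signal of {n} samples is shorter than one window ({W} samples)"
        )
    hop = W // 2
    n_frames = (n - W) // hop + 1
    win = np.hanning(W)

    starts = hop * np.arange(n_frames)
    frames = np.stack([x[s : s + W] for s in starts])
    frames = (frames - frames.mean(axis=1, keepdims=True)) * win

    X = np.fft.rfft(frames, axis=1)
    p = np.abs(X) ** 2 / W
    p[:, 1:] *= 2.0
    if W % 2 == 0:
        p[:, -1] /= 2.0
    p[:, 0] = 0.0

    freqs = np.fft.rfftfreq(W, d=1.0 / fs)
    times = (starts + W / 2.0) / fs
    return Spectrogram(times=times, freqs=freqs, power=p.T, window_samples=W)
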