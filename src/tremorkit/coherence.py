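"""Magnitude-squared coherence between two channels with Halliday-style
confidence statistics.

The estimator follows the segmented-periodogram framework standard in
sensorimotor neurophysiology (Halliday et al., Prog Biophys Mol Biol 1995):
the two signals are cut into L contiguous non-overlapping windows of W
samples, each window is demeaned and tapered with a split-cosine bell, and
the cross- and auto-spectra are averaged over windows before forming

    C(f) = |sum_l X_l conj(Y_l)|^2 / (sum_l |X_l|^2 * sum_l |Y_l|^2).

Averaging the spectra before the ratio is essential: per-segment coherence
is identically 1, so with L = 1 the estimator is degenerate and rejected.

Under the null hypothesis of independence the estimate has CDF
1 - (1 - C)^(L-1), giving the 95% confidence limit 1 - alpha^(1/(L-1));
coherence above that line is deemed significant at level alpha.
Per-frequency confidence intervals use the variance-stabilizing
atanh(sqrt(C)) transform, whose variance is 1/(2L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateCoherenceError, ParameterError, WindowError

__all__ = [
    "CoherenceResult",
    "SegmentationPlan",
    "segment_signal",
    "split_cosine_taper",
    "coherence_confidence_limit",
    "coherence_ci",
    "msc",
]


@dataclass(frozen=True)
class SegmentationPlan:
    """How a signal of N samples is cut for coherence estimation."""

    window_samples: int
    n_segments: int
    taper_fraction: float = 0.1

    @classmethod
    def for_signal(cls, n: int, window_samples: int, taper_fraction: float = 0.1):
        if window_samples < 16:
            raise ParameterError(f"window must be >= 16 samples, got {window_samples}")
        if window_samples > n:
            raise WindowError(
                f"window of {window_samples} samples exceeds signal length {n}"
            )
        return cls(window_samples, n // window_samples, taper_fraction)


@dataclass
class CoherenceResult:
    """Per-frequency magnitude-squared coherence with confidence statistics.

    ``confidence_limit`` is the scalar null threshold 1 - alpha^(1/(L-1));
    ``ci_low``/``ci_high`` bracket each frequency's estimate.
    """

    freqs: np.ndarray
    coherence: np.ndarray
    L: int
    alpha: float
    confidence_limit: float
    ci_low: np.ndarray
    ci_high: np.ndarray


def segment_signal(x: np.ndarray, window_samples: int) -> list[np.ndarray]:
    """Cut into L = floor(N/W) contiguous non-overlapping windows, in order.

    The trailing remainder of N mod W samples is discarded.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if window_samples > n:
        raise WindowError(f"window of {window_samples} samples exceeds signal length {n}")
    if window_samples < 1:
        raise ParameterError(f"window must be >= 1 sample, got {window_samples}")
    L = n // window_samples
    return [x[i * window_samples : (i + 1) * window_samples] for i in range(L)]


def _split_cosine_window(w: int, p: float) -> np.ndarray:
    """Split-cosine-bell weights: raised-cosine ramps over ceil(p*W) samples
    at each end, flat 1 in between. p = 0 is the identity; p = 0.5 leaves no
    flat region (a full Hann-type bell)."""
    if not 0.0 <= p <= 0.5:
        raise ParameterError(f"taper fraction must be in [0, 0.5], got {p}")
    win = np.ones(w)
    m = int(np.ceil(p * w))
    if m > 0:
        # half-sample offset keeps the end weights strictly positive and the
        # ramp symmetric, the classic cosine-bell convention
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(m) + 0.5) / m))
        win[:m] = ramp
        win[w - m :] = ramp[::-1]
    return win


def split_cosine_taper(segment: np.ndarray, p: float = 0.1) -> np.ndarray:
    """Apply a split-cosine-bell taper to one segment (p per end)."""
    segment = np.asarray(segment, dtype=float)
    return segment * _split_cosine_window(len(segment), p)


def coherence_confidence_limit(L: int, alpha: float = 0.05) -> float:
    """Null significance threshold for coherence from L independent segments.

    Returns 1 - alpha^(1/(L-1)): the level exceeded with probability alpha
    by the coherence of two independent signals. Strictly decreasing in L.
    """
    if L < 2:
        raise DegenerateCoherenceError(
            f"confidence limit needs L >= 2 segments, got {L}"
        )
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    return 1.0 - alpha ** (1.0 / (L - 1))


def coherence_ci(
    C: float | np.ndarray, L: int, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency confidence interval via the atanh(sqrt(C)) transform.

    g = atanh(sqrt(C)) is approximately normal with variance 1/(2L); the
    interval is tanh(g -+ z/sqrt(2L)) squared, clipped to [0, 1].
    """
    if L < 2:
        raise DegenerateCoherenceError(f"confidence interval needs L >= 2, got {L}")
    C = np.clip(np.asarray(C, dtype=float), 0.0, 1.0)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    h = z / np.sqrt(2.0 * L)
    # atanh(1) is +inf; handled by errstate, tanh maps it back to 1
    with np.errstate(divide="ignore"):
        g = np.arctanh(np.sqrt(C))
    low = np.tanh(np.maximum(g - h, 0.0)) ** 2
    high = np.tanh(g + h) ** 2
    return np.clip(low, 0.0, 1.0), np.clip(high, 0.0, 1.0)


def msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_samples: int,
    alpha: float = 0.05,
    taper_fraction: float = 0.1,
) -> CoherenceResult:
    """Segmented, tapered magnitude-squared coherence of two equal-length signals.

    Each of the L = floor(N/W) non-overlapping windows is demeaned, tapered
    with a split-cosine bell (``taper_fraction`` per end) and Fourier
    transformed; the cross- and auto-spectra are averaged over windows before
    the coherence ratio is formed. No taper power renormalization is applied:
    the window's scale cancels in the ratio.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ParameterError(
            f"signals must have equal length, got {len(x)} and {len(y)}"
        )
    plan = SegmentationPlan.for_signal(len(x), window_samples, taper_fraction)
    L = plan.n_segments
    if L < 2:
        raise DegenerateCoherenceError(
            f"coherence needs >= 2 segments (got L={L}); with one segment the "
            "estimator is identically 1"
        )
    W = plan.window_samples
    win = _split_cosine_window(W, taper_fraction)

    segs_x = np.stack(segment_signal(x, W))
    segs_y = np.stack(segment_signal(y, W))
    segs_x = (segs_x - segs_x.mean(axis=1, keepdims=True)) * win
    segs_y = (segs_y - segs_y.mean(axis=1, keepdims=True)) * win

    X = np.fft.rfft(segs_x, axis=1)
    Y = np.fft.rfft(segs_y, axis=1)
    Sxy = np.sum(X * np.conj(Y), axis=0)
    Sxx = np.sum(np.abs(X) ** 2, axis=0)
    Syy = np.sum(np.abs(Y) ** 2, axis=0)

    denom = Sxx * Syy
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.abs(Sxy) ** 2 / denom
    C = np.where(denom > 0, C, 0.0)
    C = np.clip(C, 0.0, 1.0)

    limit = coherence_confidence_limit(L, alpha)
    lo, hi = coherence_ci(C, L, alpha)
    freqs = np.fft.rfftfreq(W, d=1.0 / fs)
    return CoherenceResult(
        freqs=freqs,
        coherence=C,
        L=L,
        alpha=alpha,
        confidence_limit=limit,
        ci_low=lo,
        ci_high=hi,
    )
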