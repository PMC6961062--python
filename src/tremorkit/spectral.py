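"""Full-segment power spectra and tremor-band peak extraction.

The spectrum is a plain (untapered) FFT over the whole recording segment,
demeaned first so the rectified-EMG DC term does not dominate. Power is
one-sided and Parseval-normalized: the sum of the power bins equals the
signal's sum of squared deviations from its mean. Peak extraction searches a
frequency band — by default 3-18 Hz, spanning the organic tremor range from
cerebellar (~3 Hz) to orthostatic (~18 Hz) tremor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import BandError, InsufficientDataError

__all__ = ["Spectrum", "PeakResult", "TREMOR_BAND", "power_spectrum", "peak_frequency"]

TREMOR_BAND = (3.0, 18.0)


@dataclass
class Spectrum:
    """One-sided power spectrum on the grid 0 .. fs/2 with step fs/N."""

    freqs: np.ndarray
    power: np.ndarray
    channel: str = ""
    n_samples: int = 0

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.power):
            raise ValueError("freqs and power must have equal length")

    @property
    def df(self) -> float:
        """Frequency resolution (grid step) in Hz."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class PeakResult:
    """Location and height of the largest spectral bin within a band."""

    frequency: float
    power: float
    band: tuple[float, float]


def power_spectrum(x: np.ndarray, fs: float, channel: str = "") -> Spectrum:
    """One-sided, Parseval-normalized power spectrum of the full segment.

    The mean is removed before the transform and the DC bin is reported as
    zero. For a signal of N samples, sum(power) equals sum((x - mean(x))^2)
    exactly (to rounding). An all-constant input yields a valid all-zero
    spectrum.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 16:
        raise InsufficientDataError(f"power_spectrum needs >= 16 samples, got {n}")
    xd = x - x.mean()
    X = np.fft.rfft(xd)
    # |X|^2 / N sums (over the full two-sided grid) to the sum of squares;
    # double the interior bins to fold the negative frequencies in.
    p = np.abs(X) ** 2 / n
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0  # Nyquist bin is not mirrored
    p[0] = 0.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return Spectrum(freqs=freqs, power=p, channel=channel, n_samples=n)


def peak_frequency(
    spec: Spectrum, band: tuple[float, float] = TREMOR_BAND
) -> PeakResult | None:
    """Frequency of the maximum-power bin within [lo, hi].

    Ties break toward the lower frequency. Returns None when every in-band
    bin has zero power (no peak to report); raises :class:`BandError` when
    the band misses the frequency grid entirely.
    """
    lo, hi = band
    if hi < lo:
        raise BandError(f"band ({lo}, {hi}) is empty")
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not mask.any():
        raise BandError(
            f"band ({lo}, {hi}) Hz does not intersect the frequency grid "
            f"(0..{spec.freqs[-1]:g} Hz, step {spec.df:g})"
        )
    p = spec.power[mask]
    f = spec.freqs[mask]
    if np.all(p == 0):
        return None
    i = int(np.argmax(p))  # argmax returns the first (lowest-frequency) maximum
    return PeakResult(frequency=float(f[i]), power=float(p[i]), band=(lo, hi))
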