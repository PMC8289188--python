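"""Spectral utilities: background subtraction, weighted spectral
difference (WSD), and first-derivative peak localization.

WSD condenses the difference between two spectra (CD here, but any
wavelength-indexed signal works) into one scalar, weighting each
wavelength by the magnitude of the reference spectrum so that regions
where the reference is strong dominate:

    WSD = sqrt( (1/n) Σ_i w_i (ref_i − test_i)² ),
    w_i = |ref_i| / mean_j |ref_j|       (weights average to 1).

The weights come from the reference only, so WSD is deliberately
asymmetric in its arguments.  Replicate scans (e.g. five CD repeats)
propagate into a standard deviation of WSD over all cross pairings of
reference and test repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "WsdResult",
    "SpectrumError",
    "NoPeakError",
    "subtract_background",
    "weighted_spectral_difference",
    "wsd_uncertainty",
    "spectral_maximum",
]

_MIN_WSD_POINTS = 10


class SpectrumError(ValueError):
    """Invalid or incompatible spectra."""


class NoPeakError(ValueError):
    """The spectrum has no interior maximum."""


@dataclass
class Spectrum:
    """A wavelength-indexed signal, optionally with repeat scans.

    ``values`` holds the working signal (for repeat data, their mean
    unless given explicitly); ``repeats`` is an (n_repeats, n_points)
    array of individual scans.
    """

    wavelengths: NDArray[np.float64]  # nm, strictly increasing
    values: NDArray[np.float64]  # mdeg (CD) or a.u. (fluorescence)
    repeats: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise SpectrumError("wavelengths and values must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(self.wavelengths)) and np.all(np.isfinite(self.values))):
            raise SpectrumError("spectrum contains non-finite values")
        if self.repeats is not None:
            self.repeats = np.atleast_2d(np.asarray(self.repeats, dtype=float))
            if self.repeats.shape[1] != self.wavelengths.size:
                raise SpectrumError("repeats must match the wavelength grid")

    @classmethod
    def from_repeats(
        cls, wavelengths: NDArray[np.float64], repeats: NDArray[np.float64]
    ) -> "Spectrum":
        """Build a spectrum whose working values are the repeat mean."""
        repeats = np.atleast_2d(np.asarray(repeats, dtype=float))
        return cls(wavelengths, repeats.mean(axis=0), repeats)

    @property
    def n_repeats(self) -> int:
        return 0 if self.repeats is None else self.repeats.shape[0]


@dataclass(frozen=True)
class WsdResult:
    """Weighted spectral difference with its repeat-based uncertainty."""

    wsd: float  # units of the spectra
    sd: float = 0.0  # SD over repeat pairings
    n_pairs: int = 0


def _interp_onto(target_wl: NDArray, spec: Spectrum) -> tuple[NDArray, NDArray]:
    """Restrict target grid to the overlap and interpolate ``spec`` onto it.

    Extrapolation is forbidden: only the overlapping wavelength range
    is used.
    """
    lo = max(target_wl[0], spec.wavelengths[0])
    hi = min(target_wl[-1], spec.wavelengths[-1])
    if lo > hi:
        raise SpectrumError("wavelength ranges do not overlap")
    mask = (target_wl >= lo) & (target_wl <= hi)
    wl = target_wl[mask]
    return mask, np.interp(wl, spec.wavelengths, spec.values)


def subtract_background(sample: Spectrum, background: Spectrum) -> Spectrum:
    """Subtract a background spectrum (buffer, free POM) pointwise.

    On identical grids the subtraction is exact; otherwise the
    background is linearly interpolated onto the sample grid over the
    overlapping range and the sample is restricted to that range.
    Repeat scans on the sample have the same background removed.
    """
    if sample.wavelengths.size == background.wavelengths.size and np.array_equal(
        sample.wavelengths, background.wavelengths
    ):
        bg = background.values
        wl, vals = sample.wavelengths, sample.values - bg
        reps = None if sample.repeats is None else sample.repeats - bg
        return Spectrum(wl, vals, reps)
    mask, bg = _interp_onto(sample.wavelengths, background)
    wl = sample.wavelengths[mask]
    vals = sample.values[mask] - bg
    reps = None if sample.repeats is None else sample.repeats[:, mask] - bg
    return Spectrum(wl, vals, reps)


def _wsd_scalar(ref: NDArray, test: NDArray) -> float:
    mean_abs = np.mean(np.abs(ref))
    if mean_abs == 0.0:
        raise SpectrumError("all-zero reference: WSD weights undefined")
    w = np.abs(ref) / mean_abs
    return float(np.sqrt(np.mean(w * (ref - test) ** 2)))


def weighted_spectral_difference(reference: Spectrum, test: Spectrum) -> WsdResult:
    """WSD between a reference and a test spectrum on a common grid.

    Zero iff the spectra are identical; scales linearly with a uniform
    scaling of (test − reference) at fixed reference.  Asymmetric: the
    weights are taken from the reference.
    """
    if not np.array_equal(reference.wavelengths, test.wavelengths):
        raise SpectrumError("WSD requires a common wavelength grid")
    if reference.wavelengths.size < _MIN_WSD_POINTS:
        raise SpectrumError(f"WSD requires >= {_MIN_WSD_POINTS} points")
    return WsdResult(wsd=_wsd_scalar(reference.values, test.values))


def wsd_uncertainty(reference: Spectrum, test: Spectrum) -> WsdResult:
    """WSD of the repeat means, with SD over all repeat pairings.

    The point estimate uses the repeat-mean spectra; the uncertainty is
    the standard deviation of WSD(ref repeat i, test repeat j) over all
    i × j pairings (25 pairs for five repeats each side).
    """
    if reference.n_repeats < 2 or test.n_repeats < 2:
        raise SpectrumError("WSD uncertainty requires >= 2 repeats on both spectra")
    if not np.array_equal(reference.wavelengths, test.wavelengths):
        raise SpectrumError("WSD requires a common wavelength grid")
    if reference.wavelengths.size < _MIN_WSD_POINTS:
        raise SpectrumError(f"WSD requires >= {_MIN_WSD_POINTS} points")
    point = _wsd_scalar(reference.repeats.mean(axis=0), test.repeats.mean(axis=0))
    pair_wsd = [
        _wsd_scalar(r, t) for r in reference.repeats for t in test.repeats
    ]
    return WsdResult(
        wsd=point,
        sd=float(np.std(pair_wsd, ddof=1)),
        n_pairs=len(pair_wsd),
    )


def spectral_maximum(
    spectrum: Spectrum, smoothing_window: int = 9, polyorder: int = 2
) -> float:
    """Locate a spectral maximum by the first-derivative method.

    The spectrum is smoothed with a Savitzky–Golay filter
    (``smoothing_window`` points, polynomial order ``polyorder``), the
    first derivative is evaluated on the grid, and the maximum is the
    positive-to-negative zero crossing of the derivative, refined by
    linear interpolation between the bracketing grid points.  Monotone
    spectra raise :class:`NoPeakError`.
    """
    wl, y = spectrum.wavelengths, spectrum.values
    if wl.size < 5:
        raise SpectrumError("too few points to locate a maximum")
    window = min(smoothing_window, wl.size if wl.size % 2 == 1 else wl.size - 1)
    if window > polyorder + 1:
        y = savgol_filter(y, window, polyorder)
    d = np.gradient(y, wl)
    # positive-to-negative crossings of the first derivative
    crossings = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]
    if crossings.size == 0:
        raise NoPeakError("no interior maximum: first derivative never crosses zero")
    # keep the crossing with the highest smoothed signal
    i = crossings[np.argmax(y[crossings])]
    if d[i] == d[i + 1]:
        return float((wl[i] + wl[i + 1]) / 2.0)
    frac = d[i] / (d[i] - d[i + 1])
    return float(wl[i] + frac * (wl[i + 1] - wl[i]))
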