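"""Spectral data model and elementary spectral operations.

Discrete-wavelength IR microscopes (quantum-cascade-laser instruments)
record absorbance on a fixed, decreasing wavenumber grid.  Everything in
this package operates on that grid: band selection, trapezoidal band
integration, Savitzky-Golay second derivatives, and band ratios.

The default axis covers the fingerprint region 1800-900 cm^-1 sampled
every 4 cm^-1, which yields 225 channels (1800, 1796, ..., 904); 900 cm^-1
itself is not a grid point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "SpectralAxis",
    "Spectrum",
    "HyperspectralSlice",
    "BandWindow",
    "default_axis",
    "build_axis",
    "channels_in_window",
    "integrate_band",
    "integrate_full_range",
    "total_absorbance",
    "second_derivative",
    "second_derivative_array",
    "band_ratio",
    "RATIO_UNDEFINED",
]

#: Relative epsilon used to flag vanishing ratio denominators, expressed as a
#: fraction of the full-range area of a unit (A=1 everywhere) spectrum.
DENOMINATOR_EPS_REL = 1e-12

#: Sentinel returned by :func:`band_ratio` when the denominator area vanishes.
RATIO_UNDEFINED = float("nan")

# Savitzky-Golay defaults: a 7-channel window is 28 cm^-1 at 4 cm^-1
# sampling, standard for protein-region band sharpening; order 3 keeps
# quadratic band tops exact.
SG_WINDOW_DEFAULT = 7
SG_POLYORDER_DEFAULT = 3


@dataclass(frozen=True)
class SpectralAxis:
    """Uniform, strictly decreasing wavenumber grid.

    Channel ``k`` sits at ``start - k * step`` (cm^-1).
    """

    start: float = 1800.0
    step: float = 4.0
    n_channels: int = 225

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.n_channels < 1:
            raise ValueError("axis needs at least one channel")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.start - self.step * np.arange(self.n_channels)

    @property
    def stop(self) -> float:
        """Wavenumber of the last channel."""
        return self.start - self.step * (self.n_channels - 1)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_channels


def default_axis() -> SpectralAxis:
    """The instrument grid: 1800 to 904 cm^-1 in 4 cm^-1 steps, 225 channels."""
    return SpectralAxis(1800.0, 4.0, 225)


def build_axis(start: float, stop: float, step: float) -> SpectralAxis:
    """Build a decreasing axis from ``start`` down toward ``stop`` (exclusive
    unless on-grid minus one step; ``n = floor((start - stop)/step)``).

    ``build_axis(1800, 900, 4)`` gives the default 225-channel instrument grid
    whose last channel is 904 cm^-1.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if start <= stop:
        raise ValueError("start must exceed stop")
    n = math.floor((start - stop) / step)
    if n < 1:
        raise ValueError("axis would be empty")
    return SpectralAxis(float(start), float(step), n)


def _check_same_axis(a: SpectralAxis, b: SpectralAxis) -> None:
    if a != b:
        raise ValueError(f"spectral axes differ: {a} vs {b}")


@dataclass
class Spectrum:
    """One absorbance spectrum on a shared axis (a.u. per channel)."""

    axis: SpectralAxis
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 1 or self.absorbance.size != self.axis.n_channels:
            raise ValueError(
                f"absorbance length {self.absorbance.size} != axis channels "
                f"{self.axis.n_channels}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass
class HyperspectralSlice:
    """One tissue section: a pixel grid of spectra plus a foreground mask.

    ``absorbance`` is (height, width, n_channels); background pixels carry
    all-zero spectra.  ``pixel_size`` is the in-plane sampling in micrometres
    (20 um by default, i.e. 5x5-binned detector elements).
    """

    axis: SpectralAxis
    absorbance: np.ndarray
    foreground: np.ndarray
    pixel_size: float = 20.0
    section_index: int = 0
    thickness: float = 20.0

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance)
        self.foreground = np.asarray(self.foreground, dtype=bool)
        if self.absorbance.ndim != 3:
            raise ValueError("absorbance must be (height, width, channels)")
        if self.absorbance.shape[-1] != self.axis.n_channels:
            raise ValueError("channel count does not match axis")
        if self.foreground.shape != self.absorbance.shape[:2]:
            raise ValueError("foreground shape does not match pixel grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def height(self) -> int:
        return self.absorbance.shape[0]

    @property
    def width(self) -> int:
        return self.absorbance.shape[1]


@dataclass(frozen=True)
class BandWindow:
    """Closed wavenumber interval [lo, hi] (cm^-1) with a name."""

    name: str
    hi: float
    lo: float

    def __post_init__(self) -> None:
        # degenerate hi == lo selects (at most) the single on-grid channel
        if self.hi < self.lo:
            raise ValueError(f"window {self.name}: hi must not be below lo")


def channels_in_window(axis: SpectralAxis, window: BandWindow) -> np.ndarray:
    """Indices of all channels whose wavenumber lies in [lo, hi], in
    decreasing-wavenumber order (i.e. increasing channel index).

    Selection is a closed interval on the grid: printed limits that fall off
    the grid (1710, 1027, ...) simply bound the selection, no rounding to the
    nearest channel.
    """
    nu = axis.wavenumbers
    sel = np.flatnonzero((nu >= window.lo) & (nu <= window.hi))
    if sel.size == 0:
        raise ValueError(
            f"window {window.name} [{window.lo}, {window.hi}] selects no channel "
            f"on axis {axis.start}..{axis.stop}"
        )
    return sel


def _trapezoid_weights(axis: SpectralAxis, window: BandWindow) -> tuple[np.ndarray, np.ndarray]:
    """Channel indices and trapezoid quadrature weights (cm^-1) for a window."""
    idx = channels_in_window(axis, window)
    w = np.full(idx.size, axis.step)
    if idx.size == 1:
        return idx, np.zeros(1)
    w[0] = w[-1] = axis.step / 2.0
    return idx, w


def integrate_band(spectrum: Spectrum, window: BandWindow) -> float:
    """Trapezoidal integral of absorbance over the window (a.u. * cm^-1).

    Positive orientation: a nonnegative spectrum gives a nonnegative area
    even though the grid runs from high to low wavenumber.
    """
    idx, w = _trapezoid_weights(spectrum.axis, window)
    return float(np.dot(spectrum.absorbance[idx], w))


def integrate_band_array(values: np.ndarray, axis: SpectralAxis, window: BandWindow) -> np.ndarray:
    """Vectorised :func:`integrate_band` over the trailing channel dimension."""
    idx, w = _trapezoid_weights(axis, window)
    return np.asarray(values)[..., idx] @ w


def full_range_window(axis: SpectralAxis) -> BandWindow:
    return BandWindow("full", axis.start, axis.stop)


def integrate_full_range(spectrum: Spectrum) -> float:
    """Band integral over the whole axis (the full spectral intensity)."""
    return integrate_band(spectrum, full_range_window(spectrum.axis))


def total_absorbance(sl: HyperspectralSlice) -> float:
    """Sum over foreground pixels of the full-range spectral integral.

    This is the conserved quantity of the shape-correction step: it is
    computed before and after spectral redistribution to validate that no
    chemical information was created or destroyed.
    """
    if not sl.foreground.any():
        return 0.0
    areas = integrate_band_array(sl.absorbance, sl.axis, full_range_window(sl.axis))
    return float(areas[sl.foreground].sum())


def second_derivative(
    spectrum: Spectrum,
    window_pts: int = SG_WINDOW_DEFAULT,
    poly_order: int = SG_POLYORDER_DEFAULT,
) -> Spectrum:
    """Savitzky-Golay second derivative d^2 A / d nu^2 (a.u. cm^2 ... a.u./cm^-2).

    Absorbance peaks appear as negative lobes.  Edge channels come from the
    one-sided polynomial fits of the filter; output length equals input
    length.  Exact (to rounding) for polynomials of degree <= poly_order.
    """
    d = second_derivative_array(
        spectrum.absorbance, spectrum.axis, window_pts, poly_order
    )
    return Spectrum(spectrum.axis, d)


def second_derivative_array(
    values: np.ndarray,
    axis: SpectralAxis,
    window_pts: int = SG_WINDOW_DEFAULT,
    poly_order: int = SG_POLYORDER_DEFAULT,
) -> np.ndarray:
    """Vectorised SG second derivative along the trailing channel dimension."""
    if window_pts % 2 != 1:
        raise ValueError("window_pts must be odd")
    if window_pts < poly_order + 1:
        raise ValueError("window_pts must be at least poly_order + 1")
    if poly_order < 2:
        raise ValueError("second derivative needs poly_order >= 2")
    if window_pts > axis.n_channels:
        raise ValueError("window_pts exceeds channel count")
    # delta enters the derivative as delta**2, so the decreasing grid
    # direction does not change the sign of d2A/dnu2.
    return savgol_filter(
        np.asarray(values, dtype=float),
        window_length=window_pts,
        polyorder=poly_order,
        deriv=2,
        delta=axis.step,
        axis=-1,
        mode="interp",
    )


def _denominator_eps(axis: SpectralAxis) -> float:
    full_width = axis.start - axis.stop
    return DENOMINATOR_EPS_REL * full_width


def band_ratio(
    spectrum: Spectrum,
    numerator: BandWindow,
    denominator: BandWindow,
    scale: float = 1.0,
) -> float:
    """``scale * area(numerator) / area(denominator)``.

    Returns NaN (:data:`RATIO_UNDEFINED`) when the denominator area is at or
    below epsilon; a zero numerator over a valid denominator gives 0.
    """
    den = integrate_band(spectrum, denominator)
    if den <= _denominator_eps(spectrum.axis):
        return RATIO_UNDEFINED
    return scale * integrate_band(spectrum, numerator) / den


def band_ratio_array(
    values: np.ndarray,
    axis: SpectralAxis,
    numerator: BandWindow,
    denominator: BandWindow,
    scale: float = 1.0,
) -> np.ndarray:
    """Vectorised band ratio; NaN where the denominator area vanishes."""
    num = integrate_band_array(values, axis, numerator)
    den = integrate_band_array(values, axis, denominator)
    out = np.full(np.shape(num), RATIO_UNDEFINED)
    ok = den > _denominator_eps(axis)
    out[ok] = scale * num[ok] / den[ok]
    return out
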