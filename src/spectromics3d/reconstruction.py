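"""3D alignment and patching of corrected sections into a spectral cube.

After shape correction every section lives on the in-plane grid of the
reference volume, so alignment reduces to matching each slice's foreground
centroid (and checking its principal axis) against its virtual mask.  Only
integer translations are applied — no resampling beyond what correction
already did.  Alternating section series (IR vs histology) are reconstructed
at the full section count by giving each slice the z of its physical
section; missing planes are not duplicated or interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correction import MaskStack
from .spectral import (
    HyperspectralSlice,
    SpectralAxis,
    Spectrum,
    full_range_window,
    integrate_band_array,
)

__all__ = ["SpectralCube", "align_slices", "full_intensity_volume", "extract_region_spectra"]


@dataclass
class SpectralCube:
    """Aligned stack of corrected hyperspectral sections.

    ``slices`` share one axis and one in-plane grid; ``offsets`` records the
    integer (dy, dx) translation applied to each slice during alignment and
    ``section_indices`` the physical section of each slice, so cubes from
    alternating series keep their true z positions.
    """

    slices: list[HyperspectralSlice]
    thickness: float
    offsets: np.ndarray = None  # (n, 2) int
    section_indices: np.ndarray = None
    series: str = "IR"

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("cube needs at least one slice")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        axis = self.slices[0].axis
        shape = (self.slices[0].height, self.slices[0].width)
        for sl in self.slices:
            if sl.axis != axis:
                raise ValueError("all slices must share one spectral axis")
            if (sl.height, sl.width) != shape:
                raise ValueError("all slices must share one pixel grid")
        if self.offsets is None:
            self.offsets = np.zeros((len(self.slices), 2), dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if self.section_indices is None:
            self.section_indices = np.array([sl.section_index for sl in self.slices])
        self.section_indices = np.asarray(self.section_indices, dtype=int)

    @property
    def axis(self) -> SpectralAxis:
        return self.slices[0].axis

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.slices), self.slices[0].height, self.slices[0].width)

    def absorbance_stack(self) -> np.ndarray:
        """(n, h, w, channels) view of the stacked slice spectra."""
        return np.stack([sl.absorbance for sl in self.slices])

    def foreground_stack(self) -> np.ndarray:
        return np.stack([sl.foreground for sl in self.slices])


def _integer_shift_2d(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift with zero fill (no wrap-around)."""
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    yo = slice(max(-dy, 0), min(h, h - dy))
    xo = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = arr[yo, xo]
    return out


def align_slices(
    slices: list[HyperspectralSlice], masks: MaskStack, series: str = "IR"
) -> SpectralCube:
    """Center-align each slice on its virtual mask.

    The integer translation bringing the slice's foreground centroid onto
    the mask centroid is applied and recorded.  Empty masks paired with
    nonempty slices are an error; already-centred slices get offset (0, 0).
    """
    if len(slices) != len(masks):
        raise ValueError(
            f"slice count {len(slices)} != mask count {len(masks)}"
        )
    aligned: list[HyperspectralSlice] = []
    offsets = np.zeros((len(slices), 2), dtype=int)
    for i, (sl, mask) in enumerate(zip(slices, masks.masks)):
        if sl.foreground.any() and not mask.any():
            raise ValueError(f"section {sl.section_index}: empty mask, nonempty slice")
        if not sl.foreground.any():
            aligned.append(sl)
            continue
        c_slice = np.argwhere(sl.foreground).mean(axis=0)
        c_mask = np.argwhere(mask).mean(axis=0)
        dy, dx = np.rint(c_mask - c_slice).astype(int)
        if (dy, dx) == (0, 0):
            aligned.append(sl)
        else:
            from dataclasses import replace

            aligned.append(
                replace(
                    sl,
                    absorbance=_integer_shift_2d(sl.absorbance, dy, dx),
                    foreground=_integer_shift_2d(sl.foreground, dy, dx),
                )
            )
        offsets[i] = (dy, dx)
    thickness = slices[0].thickness
    return SpectralCube(
        slices=aligned,
        thickness=thickness,
        offsets=offsets,
        section_indices=np.array([sl.section_index for sl in slices]),
        series=series,
    )


def full_intensity_volume(cube: SpectralCube) -> np.ndarray:
    """Per-voxel full-range spectral intensity (a.u. * cm^-1), background 0.

    This is the scalar 3D image used for volume rendering: the integral of
    each voxel's absorbance over the whole wavenumber axis.
    """
    stack = cube.absorbance_stack()
    vol = integrate_band_array(stack, cube.axis, full_range_window(cube.axis))
    vol[~cube.foreground_stack()] = 0.0
    return vol


def extract_region_spectra(
    cube: SpectralCube, region: np.ndarray
) -> tuple[np.ndarray, Spectrum]:
    """Spectra of all foreground voxels inside a 3D region mask.

    Returns the (n_voxels, n_channels) spectra array and the channel-wise
    mean spectrum.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != cube.shape:
        raise ValueError(f"region shape {region.shape} != cube shape {cube.shape}")
    sel = region & cube.foreground_stack()
    if not sel.any():
        raise ValueError("region does not intersect the cube foreground")
    spectra = cube.absorbance_stack()[sel]
    return spectra, Spectrum(cube.axis, spectra.mean(axis=0))
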