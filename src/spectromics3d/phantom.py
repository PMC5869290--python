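"""Ground-truthed digital brain phantom.

Emulates everything the real experiment provides: a 3D reference volume of
the organ (the role played by an X-ray tomogram), per-section hyperspectral
images on a discrete IR wavenumber grid, per-section RGB label images with
the tumor in the green channel (fluorescent immunolabeling), and the section
distortions that cryomicrotomy introduces (anisotropic shrinkage, jitter,
tears).  Every stage of the pipeline can therefore be tested against known
ground truth.

The geometry is two hemisphere ellipsoids plus a cerebellum lobe; each
hemisphere carries an inner white-matter core (a modest fraction of the
hemisphere, as in the mouse brain) and the right hemisphere hosts an
ellipsoidal tumor.  Tissue chemistry is a sum of Gaussian absorption bands:
amide I/II for protein, a lipid ester band, and the glucose, glycogen and
lactate carbohydrate-region bands whose amplitudes scale linearly with the
ground-truth concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectral import HyperspectralSlice, SpectralAxis, Spectrum, default_axis
from .correction import ReferenceVolume

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "GroundTruth",
    "DistortionConfig",
    "DistortionParams",
    "TearParams",
    "default_tissue_classes",
    "generate_reference_volume",
    "class_spectrum",
    "generate_section_series",
    "apply_distortion",
    "draw_distortion_params",
]

# ---------------------------------------------------------------------------
# Spectral forward model
# ---------------------------------------------------------------------------

#: Gaussian band centers (cm^-1).
BAND_CENTERS = {
    "amide_i": 1655.0,
    "amide_ii": 1545.0,
    "lipid_ester": 1740.0,
    "glucose": 1031.0,
    "glycogen_1": 1024.0,
    "glycogen_2": 1162.0,
    "lactate": 1127.0,
}

#: Gaussian band widths (cm^-1): broad protein/lipid bands, narrower
#: carbohydrate-region metabolite bands.
BAND_SIGMA = {
    "amide_i": 12.0,
    "amide_ii": 12.0,
    "lipid_ester": 12.0,
    "glucose": 8.0,
    "glycogen_1": 8.0,
    "glycogen_2": 8.0,
    "lactate": 8.0,
}

#: Bands belonging to each quantified metabolite.
METABOLITE_BANDS = {
    "glucose": ("glucose",),
    "glycogen": ("glycogen_1", "glycogen_2"),
    "lactate": ("lactate",),
}

#: Peak absorbance per unit concentration (a.u. per umol/g), shared by the
#: three metabolites and split evenly over a metabolite's bands so that the
#: total carbohydrate-region absorbance stays proportional to concentration.
METABOLITE_ABSORPTIVITY = 0.05

#: Class label codes used in ground-truth volumes.
LABELS = {"background": 0, "healthy_gray": 1, "healthy_white": 2, "tumor": 3}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: RGB rendering of each class in label images; the tumor dominates the
#: green channel (fluorescent antibody labeling), healthy tissue is rendered
#: magenta with only a faint green bleed-through.
LABEL_COLORS = {
    "background": (0, 0, 0),
    "healthy_gray": (160, 10, 140),
    "healthy_white": (210, 10, 190),
    "tumor": (30, 220, 40),
}


@dataclass(frozen=True)
class TissueClass:
    """Chemical makeup of one tissue class.

    ``composition`` maps band name to peak amplitude (a.u.).  Metabolite band
    amplitudes are derived from ``metabolite_conc`` (umol/g) at construction
    unless given explicitly.
    """

    name: str
    composition: dict[str, float]
    metabolite_conc: dict[str, float]

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        for met, bands in METABOLITE_BANDS.items():
            conc = self.metabolite_conc.get(met, 0.0)
            amp = METABOLITE_ABSORPTIVITY * conc / len(bands)
            for b in bands:
                comp.setdefault(b, amp)
        if any(a < 0 for a in comp.values()):
            raise ValueError("band amplitudes must be nonnegative")
        object.__setattr__(self, "composition", comp)


def default_tissue_classes() -> dict[str, TissueClass]:
    """Default chemistry.

    Healthy tissue carries the cohort enzymatic-assay means (glucose 2.2,
    glycogen 5.1, lactate 1.2 umol/g); the tumor shows the Warburg-effect
    profile (glucose 0.8, glycogen 1.2, lactate 2.4 umol/g).  The tumor is
    protein-rich and lipid-poor relative to healthy tissue, which is what
    the protein-to-lipid ratio segmentation exploits.
    """
    healthy = {"glucose": 2.2, "glycogen": 5.1, "lactate": 1.2}
    tumor = {"glucose": 0.8, "glycogen": 1.2, "lactate": 2.4}
    return {
        "background": TissueClass("background", {}, {}),
        "healthy_gray": TissueClass(
            "healthy_gray",
            {"amide_i": 0.70, "amide_ii": 0.45, "lipid_ester": 0.15},
            dict(healthy),
        ),
        "healthy_white": TissueClass(
            "healthy_white",
            {"amide_i": 0.55, "amide_ii": 0.35, "lipid_ester": 0.45},
            dict(healthy),
        ),
        "tumor": TissueClass(
            "tumor",
            {"amide_i": 0.85, "amide_ii": 0.55, "lipid_ester": 0.08},
            dict(tumor),
        ),
    }


def class_spectrum(
    tissue: TissueClass,
    axis: SpectralAxis | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> Spectrum:
    """Forward-model spectrum of a tissue class: Gaussian bands plus
    additive Gaussian noise, clipped at zero absorbance."""
    axis = axis or default_axis()
    a = _class_base_spectrum(tissue, axis)
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    return Spectrum(axis, np.clip(a, 0.0, None))


def _class_base_spectrum(tissue: TissueClass, axis: SpectralAxis) -> np.ndarray:
    nu = axis.wavenumbers
    a = np.zeros(axis.n_channels)
    for band, amp in tissue.composition.items():
        if amp == 0.0:
            continue
        c, s = BAND_CENTERS[band], BAND_SIGMA[band]
        a += amp * np.exp(-0.5 * ((nu - c) / s) ** 2)
    return a


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates (z, y, x)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        if min(self.radii) <= 0:
            return np.zeros(shape, dtype=bool)
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        cz, cy, cx = self.center
        rz, ry, rx = self.radii
        return (
            ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        ) <= 1.0

    def scaled(self, factor: float) -> "Ellipsoid":
        return Ellipsoid(self.center, tuple(r * factor for r in self.radii))


@dataclass(frozen=True)
class DistortionConfig:
    """Statistical model of per-section cutting artifacts.

    Mean shrinkages default to the deviations observed when correcting real
    sections: 11% in height, 8% in width.
    """

    mean_height_scale: float = 0.11
    mean_width_scale: float = 0.08
    jitter_sd: float = 0.02
    rotation_sd_deg: float = 1.0
    shift_sd_px: float = 1.5
    tear_prob: float = 0.1
    tear_max_offset_px: int = 3


@dataclass(frozen=True)
class TearParams:
    orientation: str  # "h" (horizontal line, rows shifted) or "v"
    line_pos: int
    offset: int


@dataclass(frozen=True)
class DistortionParams:
    """Concrete transform of one section."""

    scale_h: float = 0.0
    scale_w: float = 0.0
    rotation_deg: float = 0.0
    shift_y: float = 0.0
    shift_x: float = 0.0
    tear: TearParams | None = None

    @property
    def is_identity(self) -> bool:
        return (
            self.scale_h == 0
            and self.scale_w == 0
            and self.rotation_deg == 0
            and self.shift_y == 0
            and self.shift_x == 0
            and self.tear is None
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom experiment."""

    shape: tuple[int, int, int] = (56, 48, 64)  # (sections z, height y, width x)
    voxel_size: float = 20.0  # um, isotropic
    section_thickness: float = 20.0  # um
    left_hemisphere: Ellipsoid = Ellipsoid((26.0, 24.0, 19.0), (22.0, 17.0, 14.0))
    right_hemisphere: Ellipsoid = Ellipsoid((26.0, 24.0, 45.0), (22.0, 17.0, 14.0))
    cerebellum: Ellipsoid = Ellipsoid((47.0, 24.0, 32.0), (8.0, 12.0, 16.0))
    tumor: Ellipsoid = Ellipsoid((24.0, 22.0, 44.0), (9.0, 7.0, 7.0))
    white_core_fraction: float = 0.45  # white-matter core radius / hemisphere radius
    classes: dict[str, TissueClass] = field(default_factory=default_tissue_classes)
    distortion: DistortionConfig = DistortionConfig()
    noise_sd: float = 0.014  # a.u.; 2% of the gray-matter amide I amplitude
    axis: SpectralAxis = field(default_factory=default_axis)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or self.section_thickness <= 0:
            raise ValueError("voxel size and thickness must be positive")
        if not (0 <= self.distortion.mean_height_scale < 1):
            raise ValueError("height scale must lie in [0, 1)")
        if not (0 <= self.distortion.mean_width_scale < 1):
            raise ValueError("width scale must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Everything the phantom knows that the pipeline must recover."""

    labels: np.ndarray  # (z, y, x) uint8, codes from LABELS
    concentrations: dict[str, np.ndarray]  # metabolite -> (z, y, x) float32
    tumor_mask: np.ndarray
    left_hemisphere_mask: np.ndarray
    right_hemisphere_mask: np.ndarray
    distortion_log: list[DistortionParams] = field(default_factory=list)
    section_planes: np.ndarray = None  # z plane of every physical section

    @property
    def ir_planes(self) -> np.ndarray:
        return self.section_planes[0::2]

    @property
    def label_planes(self) -> np.ndarray:
        return self.section_planes[1::2]

    @property
    def occupancy(self) -> np.ndarray:
        return self.labels != LABELS["background"]


def generate_reference_volume(spec: PhantomSpec) -> tuple[ReferenceVolume, GroundTruth]:
    """Build the binary organ volume and its voxel-level ground truth.

    Occupancy is the union of the two hemisphere ellipsoids and the
    cerebellum lobe; label priority inside is tumor > white core > gray.
    """
    shape = spec.shape
    left = spec.left_hemisphere.mask(shape)
    right = spec.right_hemisphere.mask(shape)
    cereb = spec.cerebellum.mask(shape)
    occupancy = left | right | cereb
    if not occupancy.any():
        raise ValueError("degenerate geometry: empty occupancy")

    labels = np.zeros(shape, dtype=np.uint8)
    labels[occupancy] = LABELS["healthy_gray"]
    white = (
        spec.left_hemisphere.scaled(spec.white_core_fraction).mask(shape)
        | spec.right_hemisphere.scaled(spec.white_core_fraction).mask(shape)
    )
    labels[white & occupancy] = LABELS["healthy_white"]
    tumor = spec.tumor.mask(shape) & occupancy
    labels[tumor] = LABELS["tumor"]

    conc = {}
    for met in METABOLITE_BANDS:
        grid = np.zeros(shape, dtype=np.float32)
        for name, code in LABELS.items():
            if name == "background":
                continue
            grid[labels == code] = spec.classes[name].metabolite_conc.get(met, 0.0)
        conc[met] = grid

    truth = GroundTruth(
        labels=labels,
        concentrations=conc,
        tumor_mask=tumor,
        left_hemisphere_mask=left & occupancy & ~tumor,
        right_hemisphere_mask=right & occupancy & ~tumor,
    )
    volume = ReferenceVolume(occupancy=occupancy, voxel_size=spec.voxel_size)
    return volume, truth


# ---------------------------------------------------------------------------
# Section series
# ---------------------------------------------------------------------------


def draw_distortion_params(
    cfg: DistortionConfig, rng: np.random.Generator
) -> DistortionParams:
    """Sample one section's distortion from the configured statistics."""
    scale_h = float(np.clip(rng.normal(cfg.mean_height_scale, cfg.jitter_sd), 0.0, 0.9))
    scale_w = float(np.clip(rng.normal(cfg.mean_width_scale, cfg.jitter_sd), 0.0, 0.9))
    tear = None
    if rng.random() < cfg.tear_prob and cfg.tear_max_offset_px > 0:
        tear = TearParams(
            orientation="h" if rng.random() < 0.5 else "v",
            line_pos=-1,  # resolved against the slice bounding box at apply time
            offset=int(rng.integers(1, cfg.tear_max_offset_px + 1))
            * (1 if rng.random() < 0.5 else -1),
        )
    return DistortionParams(
        scale_h=scale_h,
        scale_w=scale_w,
        rotation_deg=float(rng.normal(0.0, cfg.rotation_sd_deg)),
        shift_y=float(rng.normal(0.0, cfg.shift_sd_px)),
        shift_x=float(rng.normal(0.0, cfg.shift_sd_px)),
        tear=tear,
    )


def _ideal_slice(
    spec: PhantomSpec,
    truth: GroundTruth,
    z: int,
    base_spectra: np.ndarray,
    rng: np.random.Generator,
) -> HyperspectralSlice:
    labels2d = truth.labels[z]
    fg = labels2d != LABELS["background"]
    absorbance = base_spectra[labels2d].astype(np.float32)
    if spec.noise_sd > 0 and fg.any():
        noise = rng.normal(0.0, spec.noise_sd, size=absorbance.shape).astype(np.float32)
        absorbance[fg] += noise[fg]
        np.clip(absorbance, 0.0, None, out=absorbance)
    absorbance[~fg] = 0.0
    return HyperspectralSlice(
        axis=spec.axis,
        absorbance=absorbance,
        foreground=fg,
        pixel_size=spec.voxel_size,
        section_index=z,
        thickness=spec.section_thickness,
    )


def _label_image(labels2d: np.ndarray) -> np.ndarray:
    img = np.zeros(labels2d.shape + (3,), dtype=np.uint8)
    for name, code in LABELS.items():
        img[labels2d == code] = LABEL_COLORS[name]
    return img


def generate_section_series(
    volume: ReferenceVolume,
    truth: GroundTruth,
    spec: PhantomSpec,
    distort: bool = True,
) -> tuple[list[HyperspectralSlice], list[np.ndarray], GroundTruth]:
    """Cut the phantom into a serial-section experiment.

    One section per ``section_thickness`` plane.  Sections alternate between
    the IR series (even section indices) and the histology/label series (odd
    indices), as when every other frozen section is kept for staining.  Each
    section is then individually distorted; the applied parameters are
    appended to the ground-truth distortion log (identity entries when
    ``distort`` is false).

    Returns the IR slices, the RGB label images (with their section index
    recoverable from the log ordering: entry ``k`` is section ``k``), and the
    updated ground truth.
    """
    if not truth.occupancy.any():
        raise ValueError("phantom volume is empty")
    step_vox = spec.section_thickness / spec.voxel_size
    if abs(step_vox - round(step_vox)) > 1e-9:
        raise ValueError("voxel_size must divide section_thickness")
    step_vox = int(round(step_vox))

    class_by_code = [
        spec.classes[LABEL_NAMES[code]] for code in sorted(LABEL_NAMES)
    ]
    base_spectra = np.stack(
        [_class_base_spectrum(c, spec.axis) for c in class_by_code]
    )

    ss = np.random.SeedSequence(spec.seed)
    rng_noise, rng_distort = [np.random.default_rng(s) for s in ss.spawn(2)]

    occupied = np.flatnonzero(truth.occupancy.any(axis=(1, 2)))
    ir_slices: list[HyperspectralSlice] = []
    label_images: list[np.ndarray] = []
    truth.distortion_log = []
    planes = list(range(occupied[0], occupied[-1] + 1, step_vox))
    truth.section_planes = np.array(planes, dtype=int)
    for k, z in enumerate(planes):
        params = (
            draw_distortion_params(spec.distortion, rng_distort)
            if distort
            else DistortionParams()
        )
        truth.distortion_log.append(params)
        if k % 2 == 0:
            sl = _ideal_slice(spec, truth, z, base_spectra, rng_noise)
            if not params.is_identity:
                sl = apply_distortion(sl, params)
            ir_slices.append(sl)
        else:
            img = _label_image(truth.labels[z])
            if not params.is_identity:
                img = _distort_label_image(img, params)
            label_images.append(img)
    return ir_slices, label_images, truth


# ---------------------------------------------------------------------------
# Distortion
# ---------------------------------------------------------------------------


def _inverse_map(
    shape: tuple[int, int], fg: np.ndarray, params: DistortionParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-neighbour source coordinates for every output pixel.

    The forward transform shrinks about the foreground centroid by
    ``(1-scale_h, 1-scale_w)``, rotates, then translates; here we evaluate
    its inverse on the output grid.
    """
    sy = 1.0 - params.scale_h
    sx = 1.0 - params.scale_w
    if sy <= 0 or sx <= 0:
        raise ValueError("distortion scales must stay below 1")
    cy, cx = (
        np.argwhere(fg).mean(axis=0) if fg.any() else ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    )
    th = np.deg2rad(params.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    fwd = rot @ np.diag([sy, sx])
    inv = np.linalg.inv(fwd)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    pts = np.stack([yy.ravel() - params.shift_y - cy, xx.ravel() - params.shift_x - cx])
    src = inv @ pts
    src_y = np.rint(src[0] + cy).astype(int)
    src_x = np.rint(src[1] + cx).astype(int)
    valid = (
        (src_y >= 0) & (src_y < shape[0]) & (src_x >= 0) & (src_x < shape[1])
    )
    return src_y, src_x, valid


def _apply_tear(arr: np.ndarray, fg: np.ndarray, tear: TearParams) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly offset one side of a straight line across the section."""
    if not fg.any():
        return arr, fg
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    out = arr.copy()
    out_fg = fg.copy()
    if tear.orientation == "h":
        r0 = tear.line_pos if tear.line_pos >= 0 else int(rows.mean())
        shifted = np.roll(out[r0:], tear.offset, axis=1)
        shifted_fg = np.roll(out_fg[r0:], tear.offset, axis=1)
        if tear.offset > 0:
            shifted[:, : tear.offset] = 0
            shifted_fg[:, : tear.offset] = False
        else:
            shifted[:, tear.offset:] = 0
            shifted_fg[:, tear.offset:] = False
        out[r0:] = shifted
        out_fg[r0:] = shifted_fg
    else:
        c0 = tear.line_pos if tear.line_pos >= 0 else int(cols.mean())
        shifted = np.roll(out[:, c0:], tear.offset, axis=0)
        shifted_fg = np.roll(out_fg[:, c0:], tear.offset, axis=0)
        if tear.offset > 0:
            shifted[: tear.offset] = 0
            shifted_fg[: tear.offset] = False
        else:
            shifted[tear.offset:] = 0
            shifted_fg[tear.offset:] = False
        out[:, c0:] = shifted
        out_fg[:, c0:] = shifted_fg
    return out, out_fg


def apply_distortion(
    sl: HyperspectralSlice, params: DistortionParams
) -> HyperspectralSlice:
    """Distort one hyperspectral section.

    Spectra are carried unchanged pixel-by-pixel (nearest resampling of the
    shrunken, jittered grid); the foreground mask is transformed with them.
    A tear, when present, rigidly offsets everything on one side of a
    straight line.
    """
    if params.is_identity:
        return sl
    shape = (sl.height, sl.width)
    src_y, src_x, valid = _inverse_map(shape, sl.foreground, params)
    fg = np.zeros(shape, dtype=bool)
    absorbance = np.zeros_like(sl.absorbance)
    sy, sx = src_y[valid], src_x[valid]
    oy, ox = np.mgrid[: shape[0], : shape[1]]
    oy, ox = oy.ravel()[valid], ox.ravel()[valid]
    inside = sl.foreground[sy, sx]
    fg[oy[inside], ox[inside]] = True
    absorbance[oy[inside], ox[inside]] = sl.absorbance[sy[inside], sx[inside]]
    if params.tear is not None:
        absorbance, fg = _apply_tear(absorbance, fg, params.tear)
        absorbance[~fg] = 0.0
    return replace(sl, absorbance=absorbance, foreground=fg)


def _distort_label_image(img: np.ndarray, params: DistortionParams) -> np.ndarray:
    """Apply the same geometric model to an RGB label image."""
    fg = img.any(axis=-1)
    shape = fg.shape
    src_y, src_x, valid = _inverse_map(shape, fg, params)
    out = np.zeros_like(img)
    sy, sx = src_y[valid], src_x[valid]
    oy, ox = np.mgrid[: shape[0], : shape[1]]
    oy, ox = oy.ravel()[valid], ox.ravel()[valid]
    inside = fg[sy, sx]
    out[oy[inside], ox[inside]] = img[sy[inside], sx[inside]]
    if params.tear is not None:
        out_fg = out.any(axis=-1)
        out, out_fg = _apply_tear(out, out_fg, params.tear)
        out[~out_fg] = 0
    return out
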