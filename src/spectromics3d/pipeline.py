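"""End-to-end pipeline: phantom generation and the full analysis chain
(correct -> align -> quantify -> segment -> compare), with YAML
configuration, JSON-lines logging and a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import compare as cmp
from . import io as sio
from . import phantom as ph
from . import quantify as qt
from .correction import (
    MaskStack,
    ReferenceVolume,
    correct_ir_slice,
    correct_label_slice,
    extract_slice_masks,
)
from .reconstruction import SpectralCube, align_slices
from .spectral import HyperspectralSlice, SpectralAxis

__all__ = ["PipelineConfig", "StageError", "run_phantom", "run_pipeline"]

#: Enzymatic-assay reference concentrations (umol per g fresh tissue) used
#: to anchor the calibration, measured on healthy left-hemisphere
#: homogenates of a parallel cohort.
DEFAULT_ASSAY_REFERENCES = {"glucose": 2.2, "glycogen": 5.1, "lactate": 1.2}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs, serialisable to/from YAML."""

    phantom_dir: str = "phantom"
    output_dir: str = "results"
    assay_references: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASSAY_REFERENCES)
    )
    sg_window_pts: int = 7
    sg_poly_order: int = 3
    segmentation_preset: str = "protein_to_lipid"
    segmentation_threshold: float | None = None  # None -> Otsu
    volume_difference_denominator: str = "ref"
    hausdorff_mode: str = "max"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def sg_params(self) -> qt.SGParams:
        return qt.SGParams(self.sg_window_pts, self.sg_poly_order)


class _Log:
    """Append-only JSON-lines stage log."""

    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("")

    def __call__(self, stage: str, **info) -> None:
        rec = {"t": round(time.time(), 3), "stage": stage, **info}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec) + "\n")


def _manifest(out: Path, config_like: dict, seed: int, extra: dict) -> None:
    blob = json.dumps(config_like, sort_keys=True, default=str).encode()
    manifest = {
        "package": "spectromics3d",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "numpy": np.__version__,
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------


def run_phantom(
    spec: ph.PhantomSpec, out_dir: str | Path, distort: bool = True
) -> dict:
    """Generate a phantom dataset on disk and return its manifest dict.

    Writes: reference volume (TIFF), virtual mask stack (TIFF), IR slices
    (HDF5), label images (TIFF), ground truth (HDF5), the phantom spec
    (YAML) and a manifest with the seed and section bookkeeping.
    """
    out = Path(out_dir)
    (out / "ir").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)

    volume, truth = ph.generate_reference_volume(spec)
    ir_slices, label_images, truth = ph.generate_section_series(
        volume, truth, spec, distort=distort
    )
    masks = extract_slice_masks(volume, "axial", spec.section_thickness)

    sio.save_reference_volume(volume, out / "reference_volume.tiff")
    sio.save_mask_stack_tiff(masks, out / "masks.tiff")
    sio.save_ground_truth_h5(truth, out / "ground_truth.h5")
    sio.save_phantom_spec_yaml(spec, out / "phantom_spec.yaml")
    for sl in ir_slices:
        sio.save_slice_h5(sl, out / "ir" / f"section_{sl.section_index:04d}.h5")
    for z, img in zip(truth.label_planes, label_images):
        sio.save_label_image(img, out / "labels" / f"section_{z:04d}.tiff")

    manifest = {
        "seed": spec.seed,
        "n_sections": len(truth.distortion_log),
        "n_ir": len(ir_slices),
        "n_labels": len(label_images),
        "shape": list(spec.shape),
        "voxel_size_um": spec.voxel_size,
    }
    _manifest(out, sio.phantom_spec_to_dict(spec), spec.seed, manifest)
    return manifest


# ---------------------------------------------------------------------------
# Analysis pipeline (in-memory core + on-disk wrapper)
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """In-memory results of one full analysis run."""

    cube: SpectralCube
    conservation: list
    label_volume: np.ndarray  # (n_label_sections, h, w, 3)
    label_sections: np.ndarray
    seg_ir: cmp.SegmentedVolume
    seg_ihc: cmp.SegmentedVolume
    comparison: dict
    calibrations: dict[str, qt.CalibrationModel]
    maps: dict[str, qt.ConcentrationMap]
    region_stats: dict
    healthy_mask: np.ndarray  # calibration region on the cube grid
    tumor_mask_cube: np.ndarray  # IR tumor segmentation on the cube grid


def _left_hemisphere_mask(volume: ReferenceVolume) -> np.ndarray:
    """Calibration region: occupied voxels left of the mid-sagittal plane.

    The divide is the centroid x of the occupancy — the longitudinal
    fissure of the symmetric phantom geometry.
    """
    occ = volume.occupancy
    cx = np.argwhere(occ)[:, 2].mean()
    xx = np.arange(occ.shape[2])
    return occ & (xx[None, None, :] < cx)


def run_analysis(
    ir_slices: list[HyperspectralSlice],
    label_images: list[np.ndarray],
    label_sections: np.ndarray,
    volume: ReferenceVolume,
    config: PipelineConfig,
    masks: MaskStack | None = None,
    log=None,
) -> PipelineResult:
    """The full analysis chain on in-memory inputs.

    Stages: mask extraction, per-section IR and label correction,
    alignment into a spectral cube, chemical tumor segmentation, IHC
    green-channel segmentation, volume/Hausdorff comparison, and calibrated
    metabolite mapping with healthy-vs-tumor statistics.
    """
    log = log or (lambda *a, **k: None)
    sg = config.sg_params()

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except (ValueError, KeyError) as e:
                raise StageError(name, e) from e

        return deco

    if masks is None:
        thickness = ir_slices[0].thickness
        masks = stage("extract_masks")(
            lambda: extract_slice_masks(volume, "axial", thickness)
        )
    mask_of = dict(zip(masks.section_indices.tolist(), masks.masks))
    log("extract_masks", n_masks=len(masks))

    def _correct():
        corrected, reports = [], []
        for sl in ir_slices:
            out, rep = correct_ir_slice(sl, mask_of[sl.section_index])
            corrected.append(out)
            reports.append(
                {
                    "section": sl.section_index,
                    "total_before": rep.total_before,
                    "total_after": rep.total_after,
                    "rel_error_before_norm": rep.rel_error_before_norm,
                    "renorm_factor": rep.renorm_factor,
                }
            )
        return corrected, reports

    corrected, conservation = stage("correct_ir")(_correct)
    log("correct_ir", n=len(corrected))

    def _correct_labels():
        return [
            correct_label_slice(img, mask_of[z])
            for img, z in zip(label_images, label_sections)
        ]

    corrected_labels = stage("correct_labels")(_correct_labels)
    label_volume = np.stack(corrected_labels)
    log("correct_labels", n=len(corrected_labels))

    ir_masks = MaskStack(
        masks=np.stack([mask_of[sl.section_index] for sl in corrected]),
        spacing=masks.spacing,
        section_indices=np.array([sl.section_index for sl in corrected]),
    )
    cube = stage("align")(lambda: align_slices(corrected, ir_masks, series="IR"))
    log("align", offsets_max=int(np.abs(cube.offsets).max()))

    preset = {
        "protein_to_lipid": cmp.PROTEIN_TO_LIPID,
        "lipid_to_protein_x100": cmp.LIPID_TO_PROTEIN_X100,
    }[config.segmentation_preset]
    seg_ir = stage("segment_ir")(
        lambda: cmp.segment_tumor_ir(cube, preset, config.segmentation_threshold)
    )
    z_label = (
        float(np.diff(label_sections).mean()) * cube.thickness
        if len(label_sections) > 1
        else cube.thickness
    )
    seg_ihc = stage("segment_ihc")(
        lambda: cmp.segment_tumor_ihc(label_volume, ir_slices[0].pixel_size)
    )
    seg_ihc.z_spacing = z_label
    log("segment", ir_voxels=int(seg_ir.mask.sum()), ihc_voxels=int(seg_ihc.mask.sum()))

    def _compare():
        v_ir = cmp.volume_mm3(seg_ir)
        v_ihc = cmp.volume_mm3(seg_ihc)
        s_ir = cmp.surface_points(seg_ir)
        s_ihc = cmp.surface_points(seg_ihc)
        hd, _, _ = cmp.hausdorff(s_ir, s_ihc, "max")
        hd95, _, _ = cmp.hausdorff(s_ir, s_ihc, "p95")
        return {
            "volume_ir_mm3": v_ir,
            "volume_ihc_mm3": v_ihc,
            "percent_difference_of_reference": cmp.volume_difference_percent(
                v_ihc, v_ir, "ref"
            ),
            "percent_difference_of_other": cmp.volume_difference_percent(
                v_ihc, v_ir, "other"
            ),
            "hausdorff_um": hd,
            "hausdorff_p95_um": hd95,
        }

    comparison = stage("compare")(_compare)
    log("compare", **{k: round(v, 3) for k, v in comparison.items()})

    # Calibration region: left hemisphere planes of the IR sections, minus
    # anything the chemical segmentation calls tumor.
    left = _left_hemisphere_mask(volume)[cube.section_indices]
    healthy_mask = left & cube.foreground_stack() & ~seg_ir.mask
    tumor_mask_cube = seg_ir.mask

    bands = qt.default_metabolite_bands()
    calibrations, maps, stats_out = {}, {}, {}

    def _quantify():
        fg = cube.foreground_stack()
        stack = cube.absorbance_stack()
        for met, band in bands.items():
            areas_healthy = qt.band_area_2d_array(
                stack[healthy_mask], cube.axis, band, sg
            )
            model, rej = qt.calibrate(
                areas_healthy, config.assay_references[met], met
            )
            cmap = qt.concentration_map(cube, band, model, sg)
            calibrations[met] = model
            maps[met] = cmap
            vals_h, rep_h = cmap.region_values(healthy_mask)
            vals_t, rep_t = cmap.region_values(tumor_mask_cube)
            t_stat, p = qt.welch_ttest(cmap, healthy_mask, tumor_mask_cube)
            stats_out[met] = {
                "healthy": {
                    "n": int(vals_h.size),
                    "mean": float(vals_h.mean()),
                    "sd": float(vals_h.std(ddof=1)),
                    "retained_fraction": rep_h.retained_fraction,
                },
                "tumor": {
                    "n": int(vals_t.size),
                    "mean": float(vals_t.mean()),
                    "sd": float(vals_t.std(ddof=1)),
                    "retained_fraction": rep_t.retained_fraction,
                },
                "welch_t": t_stat,
                "welch_p": p,
                "calibration_factor": model.factor,
                "calibration_mean_area": model.reference_mean_area,
                "whole_volume_retained_fraction": cmap.rejection.retained_fraction,
                "calibration_retained_fraction": rej.retained_fraction,
                "zero_fraction_of_rejected": cmap.rejection.zero_fraction_of_rejected,
            }

    stage("quantify")(_quantify)
    log("quantify", metabolites=list(bands))

    return PipelineResult(
        cube=cube,
        conservation=conservation,
        label_volume=label_volume,
        label_sections=np.asarray(label_sections),
        seg_ir=seg_ir,
        seg_ihc=seg_ihc,
        comparison=comparison,
        calibrations=calibrations,
        maps=maps,
        region_stats=stats_out,
        healthy_mask=healthy_mask,
        tumor_mask_cube=tumor_mask_cube,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """On-disk pipeline: read a phantom dataset directory, run the full
    analysis, write every artefact into the output directory."""
    phantom_dir = Path(config.phantom_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "log.jsonl")

    if not phantom_dir.exists():
        raise StageError("load", FileNotFoundError(phantom_dir))
    spec = sio.load_phantom_spec_yaml(phantom_dir / "phantom_spec.yaml")
    volume = sio.load_reference_volume(
        phantom_dir / "reference_volume.tiff", spec.voxel_size
    )
    ir_paths = sorted((phantom_dir / "ir").glob("section_*.h5"))
    ir_slices = [sio.load_slice_h5(p) for p in ir_paths]
    label_paths = sorted((phantom_dir / "labels").glob("section_*.tiff"))
    label_images = [sio.load_label_image(p) for p in label_paths]
    label_sections = np.array([int(p.stem.split("_")[1]) for p in label_paths])
    log("load", n_ir=len(ir_slices), n_labels=len(label_images))

    result = run_analysis(
        ir_slices, label_images, label_sections, volume, config, log=log
    )

    with (out / "conservation.jsonl").open("w") as fh:
        for rec in result.conservation:
            fh.write(json.dumps(rec) + "\n")
    sio.save_cube_h5(result.cube, out / "cube.h5")
    sio.save_volume_tiff(
        result.seg_ir.mask.astype(np.float32), out / "segmentation_ir.tiff"
    )
    sio.save_volume_tiff(
        result.seg_ihc.mask.astype(np.float32), out / "segmentation_ihc.tiff"
    )
    sio.save_surface_ply(cmp.surface_points(result.seg_ir), out / "tumor_ir.ply")
    sio.save_surface_ply(cmp.surface_points(result.seg_ihc), out / "tumor_ihc.ply")
    (out / "comparison.json").write_text(json.dumps(result.comparison, indent=2))
    for met, cmap in result.maps.items():
        sio.save_volume_tiff(cmap.values, out / f"concentration_{met}.tiff")
    (out / "region_stats.json").write_text(json.dumps(result.region_stats, indent=2))
    _manifest(out, dataclasses.asdict(config), config.seed, {"stages": "complete"})
    log("done")
    return out
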