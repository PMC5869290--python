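"""File formats: HDF5 hyperspectral containers, TIFF masks and volumes,
CSV spectra, PLY surfaces, YAML phantom specifications.

Hyperspectral slice container (HDF5)::

    /axis        (n_channels,) wavenumbers, decreasing
    /absorbance  (height, width, n_channels)
    /foreground  (height, width) uint8
    attrs: pixel_size_um, section_index, thickness_um

Cube container: ``/slices/<k>/...`` mirroring the slice schema, plus
``/offsets`` and ``/section_indices`` and series metadata.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import phantom as ph
from .correction import MaskStack, ReferenceVolume
from .reconstruction import SpectralCube
from .spectral import HyperspectralSlice, SpectralAxis, Spectrum


def axis_from_wavenumbers(nu: np.ndarray) -> SpectralAxis:
    nu = np.asarray(nu, dtype=float)
    if nu.size < 2 or not np.allclose(np.diff(nu), nu[1] - nu[0]):
        raise ValueError("wavenumbers must be a uniform grid")
    step = nu[0] - nu[1]
    if step <= 0:
        raise ValueError("wavenumbers must decrease")
    return SpectralAxis(float(nu[0]), float(step), int(nu.size))


# ---------------------------------------------------------------------------
# Spectra (CSV)
# ---------------------------------------------------------------------------


def save_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavenumber_cm-1": spectrum.axis.wavenumbers, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False)


def load_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    axis = axis_from_wavenumbers(df["wavenumber_cm-1"].to_numpy())
    return Spectrum(axis, df["absorbance"].to_numpy())


# ---------------------------------------------------------------------------
# Hyperspectral slices and cubes (HDF5)
# ---------------------------------------------------------------------------


def _write_slice_group(g: h5py.Group, sl: HyperspectralSlice) -> None:
    g.create_dataset("axis", data=sl.axis.wavenumbers)
    g.create_dataset("absorbance", data=sl.absorbance, compression="gzip", compression_opts=1)
    g.create_dataset("foreground", data=sl.foreground.astype(np.uint8))
    g.attrs["pixel_size_um"] = sl.pixel_size
    g.attrs["section_index"] = sl.section_index
    g.attrs["thickness_um"] = sl.thickness


def _read_slice_group(g: h5py.Group) -> HyperspectralSlice:
    return HyperspectralSlice(
        axis=axis_from_wavenumbers(g["axis"][()]),
        absorbance=g["absorbance"][()],
        foreground=g["foreground"][()].astype(bool),
        pixel_size=float(g.attrs["pixel_size_um"]),
        section_index=int(g.attrs["section_index"]),
        thickness=float(g.attrs["thickness_um"]),
    )


def save_slice_h5(sl: HyperspectralSlice, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        _write_slice_group(f, sl)


def load_slice_h5(path: str | Path) -> HyperspectralSlice:
    with h5py.File(path, "r") as f:
        return _read_slice_group(f)


def save_cube_h5(cube: SpectralCube, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("slices")
        for k, sl in enumerate(cube.slices):
            _write_slice_group(grp.create_group(str(k)), sl)
        f.create_dataset("offsets", data=cube.offsets)
        f.create_dataset("section_indices", data=cube.section_indices)
        f.attrs["thickness_um"] = cube.thickness
        f.attrs["series"] = cube.series


def load_cube_h5(path: str | Path) -> SpectralCube:
    with h5py.File(path, "r") as f:
        keys = sorted(f["slices"], key=int)
        slices = [_read_slice_group(f["slices"][k]) for k in keys]
        return SpectralCube(
            slices=slices,
            thickness=float(f.attrs["thickness_um"]),
            offsets=f["offsets"][()],
            section_indices=f["section_indices"][()],
            series=str(f.attrs["series"]),
        )


# ---------------------------------------------------------------------------
# Masks, label images, scalar volumes (TIFF/PNG)
# ---------------------------------------------------------------------------


def save_mask_stack_tiff(stack: MaskStack, path: str | Path) -> None:
    tifffile.imwrite(
        path, stack.masks.astype(np.uint8) * 255, photometric="minisblack"
    )


def load_mask_stack_tiff(path: str | Path, spacing: float, section_indices=None) -> MaskStack:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return MaskStack(masks=arr > 127, spacing=spacing, section_indices=section_indices)


def save_label_image(img: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(img, dtype=np.uint8), photometric="rgb")


def load_label_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def save_volume_tiff(volume: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(
        path, np.asarray(volume, dtype=np.float32), photometric="minisblack"
    )


def save_reference_volume(vol: ReferenceVolume, path: str | Path) -> None:
    tifffile.imwrite(
        path, vol.occupancy.astype(np.uint8) * 255, photometric="minisblack"
    )


def load_reference_volume(path: str | Path, voxel_size: float) -> ReferenceVolume:
    return ReferenceVolume(occupancy=tifffile.imread(path) > 127, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# Surfaces (PLY)
# ---------------------------------------------------------------------------


def save_surface_ply(surface, path: str | Path) -> None:
    import trimesh

    if surface.faces is not None:
        mesh = trimesh.Trimesh(vertices=surface.points, faces=surface.faces, process=False)
        mesh.export(path, file_type="ply", encoding="ascii")
    else:
        cloud = trimesh.PointCloud(surface.points)
        cloud.export(path, file_type="ply")


# ---------------------------------------------------------------------------
# Ground truth (HDF5) and phantom spec (YAML)
# ---------------------------------------------------------------------------


def save_ground_truth_h5(truth: ph.GroundTruth, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=truth.labels, compression="gzip")
        f.create_dataset("tumor_mask", data=truth.tumor_mask.astype(np.uint8))
        f.create_dataset("left_hemisphere", data=truth.left_hemisphere_mask.astype(np.uint8))
        f.create_dataset("right_hemisphere", data=truth.right_hemisphere_mask.astype(np.uint8))
        cg = f.create_group("concentrations")
        for met, grid in truth.concentrations.items():
            cg.create_dataset(met, data=grid, compression="gzip")
        if truth.section_planes is not None:
            f.create_dataset("section_planes", data=truth.section_planes)
        f.attrs["distortion_log"] = json.dumps(
            [dataclasses.asdict(p) for p in truth.distortion_log]
        )


def load_ground_truth_h5(path: str | Path) -> ph.GroundTruth:
    with h5py.File(path, "r") as f:
        log = []
        for d in json.loads(f.attrs["distortion_log"]):
            tear = d.pop("tear", None)
            log.append(
                ph.DistortionParams(**d, tear=ph.TearParams(**tear) if tear else None)
            )
        return ph.GroundTruth(
            labels=f["labels"][()],
            concentrations={k: f["concentrations"][k][()] for k in f["concentrations"]},
            tumor_mask=f["tumor_mask"][()].astype(bool),
            left_hemisphere_mask=f["left_hemisphere"][()].astype(bool),
            right_hemisphere_mask=f["right_hemisphere"][()].astype(bool),
            distortion_log=log,
            section_planes=f["section_planes"][()] if "section_planes" in f else None,
        )


def _ellipsoid_to_dict(e: ph.Ellipsoid) -> dict:
    return {"center": list(e.center), "radii": list(e.radii)}


def phantom_spec_to_dict(spec: ph.PhantomSpec) -> dict:
    return {
        "shape": list(spec.shape),
        "voxel_size_um": spec.voxel_size,
        "section_thickness_um": spec.section_thickness,
        "left_hemisphere": _ellipsoid_to_dict(spec.left_hemisphere),
        "right_hemisphere": _ellipsoid_to_dict(spec.right_hemisphere),
        "cerebellum": _ellipsoid_to_dict(spec.cerebellum),
        "tumor": _ellipsoid_to_dict(spec.tumor),
        "white_core_fraction": spec.white_core_fraction,
        "classes": {
            name: {
                "composition": dict(c.composition),
                "metabolite_conc": dict(c.metabolite_conc),
            }
            for name, c in spec.classes.items()
        },
        "distortion": dataclasses.asdict(spec.distortion),
        "noise_sd": spec.noise_sd,
        "axis": {
            "start": spec.axis.start,
            "step": spec.axis.step,
            "n_channels": spec.axis.n_channels,
        },
        "seed": spec.seed,
    }


def phantom_spec_from_dict(d: dict) -> ph.PhantomSpec:
    def ell(key):
        return ph.Ellipsoid(tuple(d[key]["center"]), tuple(d[key]["radii"]))

    classes = {
        name: ph.TissueClass(name, c.get("composition", {}), c.get("metabolite_conc", {}))
        for name, c in d.get("classes", {}).items()
    } or ph.default_tissue_classes()
    ax = d.get("axis")
    axis = (
        SpectralAxis(ax["start"], ax["step"], ax["n_channels"])
        if ax
        else SpectralAxis()
    )
    return ph.PhantomSpec(
        shape=tuple(d["shape"]),
        voxel_size=d.get("voxel_size_um", 20.0),
        section_thickness=d.get("section_thickness_um", 20.0),
        left_hemisphere=ell("left_hemisphere"),
        right_hemisphere=ell("right_hemisphere"),
        cerebellum=ell("cerebellum"),
        tumor=ell("tumor"),
        white_core_fraction=d.get("white_core_fraction", 0.45),
        classes=classes,
        distortion=ph.DistortionConfig(**d.get("distortion", {})),
        noise_sd=d.get("noise_sd", 0.014),
        axis=axis,
        seed=d.get("seed", 0),
    )


def save_phantom_spec_yaml(spec: ph.PhantomSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(phantom_spec_to_dict(spec), sort_keys=False))


def load_phantom_spec_yaml(path: str | Path) -> ph.PhantomSpec:
    return phantom_spec_from_dict(yaml.safe_load(Path(path).read_text()))
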