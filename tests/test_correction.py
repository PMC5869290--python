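"""Shape correction: atlas resizing, virtual masks, mask interpolation,
mask-guided label warping and mass-preserving IR re-pixelation."""

import numpy as np
import pytest

from spectromics3d import phantom as ph
from spectromics3d.correction import (
    MaskStack,
    ReferenceVolume,
    correct_ir_slice,
    correct_label_slice,
    extract_slice_masks,
    interpolate_masks,
    resize_atlas_volume,
)
from spectromics3d.spectral import HyperspectralSlice, default_axis, total_absorbance

from conftest import dice


def ball(shape, center, r):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2) <= r**2


def disk(shape, center, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= r**2


class TestResizeAtlas:
    def test_identity_target_returns_identical_volume(self):
        vol = ReferenceVolume(ball((30, 30, 30), (14, 14, 14), 10))
        out = resize_atlas_volume(vol, tuple(vol.extents_mm()))
        assert np.array_equal(out.occupancy, vol.occupancy)

    def test_doubling_one_extent_doubles_bounding_box(self):
        vol = ReferenceVolume(ball((30, 30, 30), (14, 14, 14), 10))
        ext = vol.extents_mm()
        out = resize_atlas_volume(vol, (2 * ext[0], ext[1], ext[2]))
        assert out.extents_mm()[0] == pytest.approx(2 * ext[0], abs=vol.voxel_size / 1000)
        assert out.extents_mm()[1] == pytest.approx(ext[1], abs=vol.voxel_size / 1000)

    def test_sphere_stretched_to_ellipsoid_volume(self):
        vol = ReferenceVolume(ball((40, 40, 40), (19, 19, 19), 14))
        ext = vol.extents_mm()
        out = resize_atlas_volume(vol, (2 * ext[0], ext[1], ext[2]))
        assert out.occupancy.sum() == pytest.approx(2 * vol.occupancy.sum(), rel=0.03)

    def test_empty_atlas_rejected(self):
        with pytest.raises(ValueError):
            resize_atlas_volume(
                ReferenceVolume(np.zeros((5, 5, 5), bool)), (1.0, 1.0, 1.0)
            )


class TestExtractSliceMasks:
    def test_370_masks_from_7p4_mm_extent(self):
        occ = np.zeros((372, 8, 8), bool)
        occ[1:371, 2:6, 2:6] = True  # 370 occupied planes at 20 um = 7.4 mm
        stack = extract_slice_masks(ReferenceVolume(occ, 20.0), "axial", 20.0)
        assert len(stack) == 370

    def test_equatorial_plane_of_sphere_is_full_disk(self):
        occ = ball((41, 41, 41), (20, 20, 20), 15)
        stack = extract_slice_masks(ReferenceVolume(occ, 20.0), "axial", 20.0)
        eq = stack.masks[np.argmax([m.sum() for m in stack.masks])]
        expected = disk((41, 41), (20, 20), 15)
        assert dice(eq, expected) == 1.0

    def test_plane_missing_the_organ_keeps_empty_mask(self):
        occ = np.zeros((20, 10, 10), bool)
        occ[2:5, 3:7, 3:7] = True
        occ[12:15, 3:7, 3:7] = True  # gap between two blocks
        stack = extract_slice_masks(ReferenceVolume(occ, 20.0), "axial", 20.0)
        assert len(stack) == 13
        assert not stack.masks[6].any()  # gap plane retained, empty

    def test_spacing_below_voxel_size_rejected(self):
        occ = ball((21, 21, 21), (10, 10, 10), 8)
        with pytest.raises(ValueError):
            extract_slice_masks(ReferenceVolume(occ, 20.0), "axial", 10.0)


class TestInterpolateMasks:
    def test_input_masks_returned_exactly_at_knots(self):
        rng = np.random.default_rng(5)
        masks = rng.random((3, 20, 20)) > 0.6
        sparse = MaskStack(masks, 20.0, section_indices=[0, 7, 14])
        out = interpolate_masks(sparse, [0, 7, 14])
        assert np.array_equal(out.masks, masks)

    def test_identical_masks_interpolate_to_themselves(self):
        m = disk((30, 30), (15, 15), 9)
        sparse = MaskStack(np.stack([m, m]), 20.0, section_indices=[0, 10])
        out = interpolate_masks(sparse, [5])
        assert np.array_equal(out.masks[0], m)

    def test_concentric_disks_midpoint_radius(self):
        m1 = disk((50, 50), (25, 25), 10)
        m2 = disk((50, 50), (25, 25), 20)
        sparse = MaskStack(np.stack([m1, m2]), 20.0, section_indices=[0, 10])
        mid = interpolate_masks(sparse, [5]).masks[0]
        # r = 15 +/- 1 px: nested between the 14- and 16-px disks
        assert np.all(disk((50, 50), (25, 25), 14) <= mid)
        assert np.all(mid <= disk((50, 50), (25, 25), 16))

    def test_monotone_for_nested_inputs(self):
        rng = np.random.default_rng(11)
        inner = [disk((40, 40), (20, 20), r) for r in (6, 12)]
        outer = [m | (rng.random((40, 40)) > 0.8) | disk((40, 40), (20, 20), 16)
                 for m in inner]
        targets = list(range(0, 11))
        a = interpolate_masks(MaskStack(np.stack(inner), 20.0, section_indices=[0, 10]), targets)
        b = interpolate_masks(MaskStack(np.stack(outer), 20.0, section_indices=[0, 10]), targets)
        for ma, mb in zip(a.masks, b.masks):
            assert np.all(ma <= mb)

    def test_unordered_indices_rejected(self):
        m = disk((10, 10), (5, 5), 3)
        sparse = MaskStack(np.stack([m, m]), 20.0, section_indices=[5, 0])
        with pytest.raises(ValueError):
            interpolate_masks(sparse, [2])


@pytest.fixture(scope="module")
def distorted_pair(phantom_run):
    """An ideal phantom section, its distorted version and its mask."""
    spec = phantom_run.spec
    truth = phantom_run.truth
    z = int(phantom_run.result.cube.section_indices[len(phantom_run.result.cube.slices) // 2])
    ideal_labels = truth.labels[z]
    img = ph._label_image(ideal_labels)
    params = ph.DistortionParams(scale_h=0.11, scale_w=0.08, rotation_deg=1.0,
                                 shift_y=1.5, shift_x=-1.0)
    distorted = ph._distort_label_image(img, params)
    mask = ideal_labels != 0
    return img, distorted, mask


class TestCorrectLabelSlice:
    def test_identity_when_foreground_equals_target(self, distorted_pair):
        img, _, mask = distorted_pair
        out = correct_label_slice(img, mask)
        assert np.array_equal(out, img)

    def test_output_foreground_fills_target(self, distorted_pair):
        _, distorted, mask = distorted_pair
        out = correct_label_slice(distorted, mask)
        assert dice(out.any(axis=-1), mask) >= 0.99

    def test_label_set_preserved(self, distorted_pair):
        _, distorted, mask = distorted_pair
        out = correct_label_slice(distorted, mask)
        in_colors = {tuple(c) for c in distorted.reshape(-1, 3)}
        out_colors = {tuple(c) for c in out.reshape(-1, 3)}
        assert out_colors <= in_colors | {(0, 0, 0)}

    def test_round_trip_recovers_ideal_labels(self, distorted_pair):
        img, distorted, mask = distorted_pair
        out = correct_label_slice(distorted, mask)
        assert (out == img).all(axis=-1).mean() >= 0.9
        tumor_in = (img[..., 1] > 100)
        tumor_out = (out[..., 1] > 100)
        assert dice(tumor_out, tumor_in) >= 0.9

    def test_empty_inputs_rejected(self):
        img = np.zeros((10, 10, 3), np.uint8)
        mask = disk((10, 10), (5, 5), 3)
        with pytest.raises(ValueError):
            correct_label_slice(img, mask)
        img[3:6, 3:6] = 50
        with pytest.raises(ValueError):
            correct_label_slice(img, np.zeros((10, 10), bool))


class TestCorrectIrSlice:
    def _uniform_slice(self, fg, value=1.0):
        axis = default_axis()
        a = np.zeros(fg.shape + (axis.n_channels,))
        a[fg] = value
        return HyperspectralSlice(axis, a, fg)

    def test_matching_foreground_leaves_spectra_unchanged(self):
        fg = disk((30, 30), (15, 15), 9)
        sl = self._uniform_slice(fg)
        out, report = correct_ir_slice(sl, fg)
        assert np.allclose(out.absorbance, sl.absorbance, rtol=1e-12)
        assert report.rel_error_before_norm == 0.0

    def test_total_absorbance_conserved_on_phantom_sections(self, phantom_run):
        for rec in phantom_run.result.conservation:
            rel = abs(rec["total_after"] - rec["total_before"]) / rec["total_before"]
            assert rel <= 1e-9

    def test_uniform_field_stays_uniform_after_correction(self):
        fg = np.zeros((40, 50), bool)
        fg[8:32, 10:40] = True
        sl = self._uniform_slice(fg)
        squashed = ph.apply_distortion(sl, ph.DistortionParams(scale_h=0.11, scale_w=0.08))
        out, _ = correct_ir_slice(squashed, fg)
        level = out.absorbance[fg][:, 100]
        assert level.std() / level.mean() <= 0.05

    def test_empty_inputs_rejected(self):
        fg = disk((20, 20), (10, 10), 5)
        sl = self._uniform_slice(np.zeros((20, 20), bool))
        with pytest.raises(ValueError):
            correct_ir_slice(sl, fg)
        with pytest.raises(ValueError):
            correct_ir_slice(self._uniform_slice(fg), np.zeros((20, 20), bool))
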