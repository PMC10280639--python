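"""Geometry and intensity contracts of the CT preprocessing pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from ctrecur.phantom import PhantomParams, generate_phantom
from ctrecur.preprocess import (
    PATCH_KEYS,
    CTVolume,
    TumorMask,
    augment,
    build_patchset,
    central_slice,
    crop_patch,
    rescale_patch,
    resample_isotropic,
    resize_plane,
    slice_indices,
    to_hounsfield,
    window_normalize,
)


def _vol(stored, spacing=(1, 1, 1), slope=1.0, intercept=-1024.0):
    return CTVolume(stored=np.asarray(stored), spacing_mm=spacing,
                    rescale_slope=slope, rescale_intercept=intercept)


class TestHounsfield:
    @pytest.mark.parametrize("stored,slope,intercept,expected", [
        (0, 1.0, -1024.0, -1024.0),
        (1024, 1.0, -1024.0, 0.0),
        (100, 2.0, -1000.0, -800.0),
    ])
    def test_affine_conversion(self, stored, slope, intercept, expected):
        vol = _vol(np.full((2, 2, 2), stored), slope=slope, intercept=intercept)
        assert to_hounsfield(vol)[0, 0, 0] == pytest.approx(expected)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            to_hounsfield(_vol(np.zeros((2, 2, 2)), slope=0.0))


class TestWindowNormalize:
    @pytest.mark.parametrize("hu,expected", [
        (-1000.0, 0.0),      # lower window bound
        (400.0, 255.0),      # upper window bound
        (-1300.0, 0.0),      # clipped below
        (900.0, 255.0),      # clipped above
        (-300.0, 128.0),     # 127.5 rounds half-even to 128
    ])
    def test_endpoints_and_clipping(self, hu, expected):
        assert window_normalize(np.array([hu]))[0] == expected

    def test_range_contract(self, rng):
        out = window_normalize(rng.uniform(-3000, 3000, (5, 6, 7)))
        assert out.min() >= 0 and out.max() <= 255


class TestResample:
    def test_shape_arithmetic(self, rng):
        hu = rng.normal(0, 1, (20, 40, 40))
        out = resample_isotropic(hu, (2.5, 1.0, 1.0))
        assert out.shape == (50, 40, 40)

    def test_isotropic_input_is_identity(self, rng):
        hu = rng.normal(-500, 100, (8, 12, 12)).astype(np.float32)
        out = resample_isotropic(hu, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(out, hu, atol=1e-5)

    def test_constant_volume_stays_constant(self):
        out = resample_isotropic(np.full((10, 12, 12), 37.0), (2.0, 1.5, 1.5))
        np.testing.assert_allclose(out, 37.0, atol=1e-4)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            resample_isotropic(np.zeros((1, 10, 10)), (5.0, 1.0, 1.0))


class TestCentralSlice:
    def test_argmax_and_tie_break(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        for z, area in enumerate([0, 5, 9, 3]):
            mask[z].flat[:area] = True
        assert central_slice(mask) == 2
        tie = np.zeros((4, 4, 4), dtype=bool)
        for z, area in enumerate([4, 7, 7, 1]):
            tie[z].flat[:area] = True
        assert central_slice(tie) == 1  # smallest index wins ties

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(100):
            mask = rng.random((6, 8, 8)) < 0.3
            if not mask.any():
                mask[rng.integers(6), 0, 0] = True
            areas = [int(mask[z].sum()) for z in range(mask.shape[0])]
            expected = max(range(len(areas)), key=lambda z: (areas[z], -z))
            assert central_slice(mask) == expected

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            central_slice(np.zeros((3, 3, 3), dtype=bool))


class TestSliceIndices:
    @pytest.mark.parametrize("center,depth,expected", [
        (50, 100, [40, 45, 50, 55, 60]),
        (3, 100, [0, 0, 3, 8, 13]),       # clamped low, with duplication
        (50, 53, [40, 45, 50, 52, 52]),   # clamped high
    ])
    def test_five_mm_spacing_with_clamping(self, center, depth, expected):
        assert slice_indices(center, depth) == expected


class TestCropAndRescale:
    def test_window_arithmetic(self, rng):
        plane = rng.uniform(0, 255, (512, 512)).astype(np.float32)
        patch = crop_patch(plane, (256, 256), 100)
        np.testing.assert_array_equal(patch, plane[206:306, 206:306])

    def test_out_of_bounds_zero_padded(self, rng):
        plane = rng.uniform(1, 255, (512, 512)).astype(np.float32)
        patch = crop_patch(plane, (10, 256), 100)
        assert patch.shape == (100, 100)
        assert (patch[:40] == 0).all() and (patch[40:] > 0).all()

    def test_150_patch_margin_of_25px_each_side(self, rng):
        plane = rng.uniform(0, 255, (512, 512)).astype(np.float32)
        p100 = crop_patch(plane, (256, 256), 100)
        p150 = crop_patch(plane, (256, 256), 150)
        np.testing.assert_array_equal(p150[25:125, 25:125], p100)

    def test_rescale_preserves_constants_and_identity(self):
        const = np.full((50, 50), 99.0, dtype=np.float32)
        np.testing.assert_allclose(rescale_patch(const, 100), 99.0, atol=1e-6)
        patch = np.arange(10000, dtype=np.float32).reshape(100, 100) / 50.0
        np.testing.assert_array_equal(rescale_patch(patch, 100), patch)

    def test_rescale_rejects_non_square(self):
        with pytest.raises(ValueError):
            rescale_patch(np.zeros((50, 60)))

    def test_upsample_downsample_round_trip_on_smooth_patch(self):
        yy, xx = np.mgrid[0:50, 0:50]
        smooth = 120 + 60 * np.sin(yy / 9.0) * np.cos(xx / 11.0)
        up = rescale_patch(smooth.astype(np.float32), 100)
        back = rescale_patch(up, 50)
        assert np.mean(np.abs(back - smooth)) < 2.0

    def test_resize_plane_identity_and_clipping(self, rng):
        plane = rng.uniform(0, 255, (512, 512)).astype(np.float32)
        np.testing.assert_allclose(resize_plane(plane), plane, atol=1e-6)
        out = resize_plane(rng.uniform(0, 255, (256, 256)))
        assert out.min() >= 0 and out.max() <= 255


class TestBuildPatchset:
    def test_shapes_label_and_determinism(self, small_params):
        vol, mask, label = generate_phantom(small_params, 1)
        ps1 = build_patchset(vol, mask, label)
        ps2 = build_patchset(vol, mask, label)
        for key in PATCH_KEYS:
            patch = getattr(ps1, key)
            assert patch.shape == (100, 100)
            assert patch.min() >= 0 and patch.max() <= 255
            np.testing.assert_array_equal(patch, getattr(ps2, key))
        assert ps1.label == 1

    def test_tumor_centered_in_medium_patch(self, small_params):
        vol, mask, label = generate_phantom(small_params, 0)
        ps = build_patchset(vol, mask, label)
        bright = ps.medium > 128  # soft-tissue tumor vs lung background
        assert bright.any()
        com = np.argwhere(bright).mean(axis=0)
        assert np.abs(com - 49.5).max() < 2.0

    def test_mismatched_shapes_rejected(self, small_params):
        vol, mask, _ = generate_phantom(small_params, 0)
        bad = TumorMask(np.ones((4, 5, 6), dtype=bool))
        with pytest.raises(ValueError):
            build_patchset(vol, bad, 0)


class _ForcedRng:
    """Deterministic stand-in driving augment's two flip decisions."""

    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


class TestAugment:
    def test_flip_is_involution_and_preserves_pixel_sum(self, rng):
        patch = rng.uniform(0, 255, (100, 100))
        once = augment(patch, _ForcedRng([0.1, 0.1]))   # flip both axes
        twice = augment(once, _ForcedRng([0.1, 0.1]))
        np.testing.assert_array_equal(twice, patch)
        assert once.sum() == pytest.approx(patch.sum())

    def test_no_flip_is_identity(self, rng):
        patch = rng.uniform(0, 255, (100, 100))
        np.testing.assert_array_equal(augment(patch, _ForcedRng([0.9, 0.9])), patch)
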