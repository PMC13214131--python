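"""Harmonization chain: sanitization, resampling, shape standardization,
normalization, body masking, cropping and intensity augmentation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from sinusct.core import LabelMask, Volume
from sinusct.phantoms import PhantomSpec, cohort_specs, generate_phantom
from sinusct.preprocess import (augment_intensity, body_mask_from_threshold,
                                mask_guided_crop, normalize_minmax,
                                resample_isotropic, sanitize, standard_chain,
                                standardize_shape)


def _vol(grid, spacing=(1, 1, 1), domain="HU"):
    return Volume(np.asarray(grid, np.float32), spacing, domain)


class TestSanitize:
    def test_finite_volume_unchanged(self, rng):
        v = _vol(rng.normal(size=(4, 4, 4)))
        assert np.array_equal(sanitize(v).grid, v.grid)

    def test_nan_and_inf_replaced_with_zero_others_untouched(self):
        g = np.ones((3, 3, 3), np.float32)
        g[0, 0, 0] = np.nan
        g[2, 2, 2] = np.inf
        out = sanitize(_vol(g)).grid
        assert out[0, 0, 0] == 0 and out[2, 2, 2] == 0
        mask = np.ones_like(g, bool)
        mask[0, 0, 0] = mask[2, 2, 2] = False
        assert np.all(out[mask] == 1)

    def test_all_nan_becomes_all_zero(self):
        out = sanitize(_vol(np.full((2, 2, 2), np.nan))).grid
        assert np.all(out == 0)


class TestResample:
    def test_identity_at_target_spacing(self, rng):
        v = _vol(rng.normal(size=(8, 8, 8)))
        out = resample_isotropic(v, 1.0)
        assert out.shape == v.shape
        assert np.allclose(out.grid, v.grid)

    def test_halving_spacing_halves_shape(self):
        v = _vol(np.zeros((64, 64, 64)), spacing=(0.5, 0.5, 0.5))
        out = resample_isotropic(v, 1.0)
        assert out.shape == (32, 32, 32)
        assert out.spacing_mm == (1.0, 1.0, 1.0)

    def test_constant_volume_stays_constant(self):
        v = _vol(np.full((10, 12, 14), 7.0), spacing=(0.8, 0.8, 0.8))
        out = resample_isotropic(v, 1.0)
        assert np.allclose(out.grid, 7.0, atol=1e-5)

    def test_labels_resampled_nearest_never_grow_label_set(self):
        g = np.zeros((20, 20, 20), np.int16)
        g[5:10, 5:10, 5:10] = 3
        m = LabelMask(g, (0.5, 0.5, 0.5))
        out = resample_isotropic(m, 1.0)
        assert set(np.unique(out.grid)) <= {0, 3}

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            resample_isotropic(_vol(np.zeros((4, 4, 4))), 0.0)

    def test_resample_round_trip_consistency(self):
        # smooth synthetic volume: down- then up-sampling is near-lossless
        x = np.linspace(0, np.pi, 32)
        g = np.sin(x)[:, None, None] * np.cos(x)[None, :, None] * np.sin(x)[None, None, :]
        v = _vol(g)
        down = resample_isotropic(v, 2.0)
        back = resample_isotropic(down, 1.0)
        assert back.shape == v.shape
        assert float(np.abs(back.grid - v.grid).mean()) < 0.03


class TestStandardizeShape:
    def test_identity(self, rng):
        v = _vol(rng.normal(size=(10, 10, 10)))
        assert np.array_equal(standardize_shape(v, (10, 10, 10)).grid, v.grid)

    def test_center_crop_indices_via_ramp_oracle(self):
        # index-valued ramp makes retained voxels directly readable
        ramp = np.arange(12, dtype=np.float32)[:, None, None] * np.ones((12, 3, 3), np.float32)
        out = standardize_shape(_vol(ramp), (8, 3, 3))
        assert np.array_equal(np.unique(out.grid[:, 0, 0]), np.arange(2, 10))

    def test_symmetric_pad_extra_on_high_side(self):
        ramp = np.arange(5, dtype=np.float32)[:, None, None] * np.ones((5, 3, 3), np.float32)
        out = standardize_shape(_vol(ramp + 1), (8, 3, 3))
        col = out.grid[:, 0, 0]
        assert np.array_equal(col, [0, 1, 2, 3, 4, 5, 0, 0])  # 1 low, 2 high


class TestNormalize:
    def test_window_endpoints_map_to_unit_interval(self):
        v = _vol([[[-1000.0, 2000.0]]])
        out = normalize_minmax(v, (-1000, 2000))
        assert out.grid[0, 0, 0] == 0.0 and out.grid[0, 0, 1] == 1.0
        assert out.intensity_domain == "normalized"

    def test_midpoint_and_clipping(self):
        v = _vol([[[500.0, -5000.0, 9000.0]]])
        out = normalize_minmax(v, (-1000, 2000))
        assert out.grid[0, 0, 0] == pytest.approx(0.5)
        assert out.grid[0, 0, 1] == 0.0 and out.grid[0, 0, 2] == 1.0

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            normalize_minmax(_vol(np.zeros((2, 2, 2))), (100, 100))


class TestBodyMask:
    def test_all_bone_gives_full_mask(self):
        v = _vol(np.full((4, 4, 4), 700.0))
        assert body_mask_from_threshold(v).all()

    def test_internal_cavities_inside_body_mask(self, clean_phantom):
        """Flood-fill oracle: sinus air is enclosed, so hole filling must
        keep every labeled cavity voxel inside the body mask."""
        mask = body_mask_from_threshold(clean_phantom.volume)
        cavity = clean_phantom.labels.grid > 0
        assert np.all(mask[cavity] == 1)
        # oracle: voxels reachable from the border through sub-threshold air
        # are outside; none of them may be inside the returned mask
        air = clean_phantom.volume.grid < -500
        outside = np.zeros_like(air)
        outside[0], outside[-1] = air[0], air[-1]
        outside = ndimage.binary_propagation(outside, mask=air)
        assert not np.any(mask.astype(bool) & outside)

    def test_largest_component_survives(self):
        g = np.full((12, 12, 12), -1000.0, np.float32)
        g[1:7, 1:7, 1:7] = 100.0   # 216 voxels
        g[9:11, 9:11, 9:11] = 100.0  # 8 voxels
        mask = body_mask_from_threshold(_vol(g))
        assert mask[2, 2, 2] == 1 and mask[9, 9, 9] == 0
        assert mask.sum() == 216

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            body_mask_from_threshold(_vol(np.full((3, 3, 3), -900.0)))


class TestMaskGuidedCrop:
    def test_full_mask_identity(self, rng):
        v = _vol(rng.normal(size=(5, 5, 5)))
        out, _ = mask_guided_crop(v, np.ones((5, 5, 5), np.uint8), 0)
        assert np.array_equal(out.grid, v.grid)

    def test_single_voxel_with_margin(self):
        m = np.zeros((11, 11, 11), np.uint8)
        m[5, 5, 5] = 1
        v = _vol(np.zeros((11, 11, 11)))
        out, _ = mask_guided_crop(v, m, 2)
        assert out.shape == (5, 5, 5)

    def test_margin_clamped_to_grid(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[3, 3, 3] = 1
        out, _ = mask_guided_crop(_vol(np.zeros((6, 6, 6))), m, 100)
        assert out.shape == (6, 6, 6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_guided_crop(_vol(np.zeros((4, 4, 4))), np.zeros((4, 4, 4)), 1)


class TestAugment:
    def test_unit_ranges_identity(self, rng):
        v = _vol(rng.random(size=(4, 4, 4)), domain="normalized")
        out = augment_intensity(v, (1, 1), (1, 1), seed=0)
        assert np.allclose(out.grid, v.grid)

    def test_seeded_determinism(self, rng):
        v = _vol(rng.random(size=(4, 4, 4)), domain="normalized")
        a = augment_intensity(v, (0.8, 1.2), (0.9, 1.1), seed=5)
        b = augment_intensity(v, (0.8, 1.2), (0.9, 1.1), seed=5)
        assert np.array_equal(a.grid, b.grid)

    def test_gamma_two_squares_intensities(self):
        v = _vol(np.full((2, 2, 2), 0.5), domain="normalized")
        out = augment_intensity(v, (2, 2), (1, 1), seed=0)
        assert np.allclose(out.grid, 0.25)

    def test_nonpositive_gamma_rejected(self):
        v = _vol(np.zeros((2, 2, 2)), domain="normalized")
        with pytest.raises(ValueError):
            augment_intensity(v, (-0.5, 1.0), (1, 1), seed=0)


def test_full_chain_maps_random_phantoms_into_unit_box():
    """sanitize -> resample -> standardize -> normalize lands any finite
    phantom at the configured shape with values in [0, 1]."""
    for i, sp in enumerate(cohort_specs(4, PhantomSpec(), 0.5, seed=17)):
        s = generate_phantom(sp)
        v, m = standard_chain(s.volume, 1.0, (40, 40, 40), labels=s.labels)
        assert v.shape == (40, 40, 40) and m.shape == (40, 40, 40)
        assert v.intensity_domain == "normalized"
        assert float(v.grid.min()) >= 0.0 and float(v.grid.max()) <= 1.0
        assert set(np.unique(m.grid)) <= set(np.unique(s.labels.grid))
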