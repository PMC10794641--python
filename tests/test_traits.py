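"""Trait computations: closed-form cases, brute-force oracles, scale
covariance, and end-to-end recovery on the shared phantom."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import scene_with, straight_branch
from rootct.phantom import PhantomConfig, render_volume, truth_mask, truth_traits
from rootct.segmentation import PotGeometry, Skeleton, skeletonize
from rootct.traits import (
    TraitOptions,
    calibrate_dry_weight,
    compute_all_traits,
    density_traits,
    form_fraction,
    quantile_depths,
    root_angles,
    root_length,
    root_volume,
    virtual_biomass_profile,
)
from rootct.volume_io import Volume3D


def open_pot(shape, spacing=(1.0, 1.0, 1.0)):
    """A pot covering the whole grid with the surface at depth 0."""
    nz = shape[0]
    return PotGeometry(
        center_mm=((shape[1] - 1) / 2 * spacing[1], (shape[2] - 1) / 2 * spacing[2]),
        radius_mm=shape[1] * spacing[1],
        surface_depth_mm=0.0,
        bottom_depth_mm=nz * spacing[0],
        interior_mask=np.ones(shape, dtype=bool),
        spacing_mm=spacing,
    )


class TestRootVolume:
    def test_empty_mask_is_zero(self):
        assert root_volume(np.zeros((4, 4, 4), dtype=bool), (0.5, 0.5, 0.5)) == 0.0

    def test_voxel_count_times_voxel_volume(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m.flat[:1000] = True
        assert root_volume(m, (0.5, 0.5, 0.5)) == pytest.approx(125.0)


class TestQuantileDepths:
    def test_uniform_vertical_stem_gives_closed_form_depths(self):
        shape = (160, 20, 20)
        vol = Volume3D(np.full(shape, 150.0, dtype=np.float32), (1.0, 1.0, 1.0))
        mask = np.zeros(shape, dtype=bool)
        mask[:, 9:11, 9:11] = True
        got = quantile_depths(vol, mask, open_pot(shape))
        assert got == pytest.approx([40.0, 80.0, 120.0, 144.0])

    def test_all_mass_in_one_slice_collapses_quantiles_there(self):
        shape = (100, 16, 16)
        vol = Volume3D(np.full(shape, 100.0, dtype=np.float32), (1.0, 1.0, 1.0))
        mask = np.zeros(shape, dtype=bool)
        mask[50, 5:10, 5:10] = True
        got = quantile_depths(vol, mask, open_pot(shape))
        for d in got:
            assert d == pytest.approx(50.0, abs=1.0)  # within the one-voxel bin

    def test_empty_mask_yields_undefined_markers_not_zero(self):
        shape = (10, 10, 10)
        vol = Volume3D(np.ones(shape, dtype=np.float32), (1, 1, 1))
        got = quantile_depths(vol, np.zeros(shape, dtype=bool), open_pot(shape))
        assert all(math.isnan(d) for d in got)

    def test_matches_prefix_sum_oracle_within_one_voxel(self, phantom_scene):
        from rootct.benchmark import quantile_oracle

        got = quantile_depths(phantom_scene["vol"], phantom_scene["mask"], phantom_scene["pot"])
        want = quantile_oracle(phantom_scene["vol"], phantom_scene["mask"], phantom_scene["pot"])
        for g, w in zip(got, want):
            assert abs(g - w) < 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_quantile_monotonicity_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = (24, 12, 12)
        vol = Volume3D(rng.uniform(50, 200, shape).astype(np.float32), (1, 1, 1))
        mask = rng.random(shape) < 0.2
        if not mask.any():
            return
        d25, d50, d75, d90 = quantile_depths(vol, mask, open_pot(shape))
        assert d25 <= d50 <= d75 <= d90


class TestRootAngles:
    def test_vertical_stem_is_zero_degrees(self):
        cfg = PhantomConfig(seed=0)
        c = cfg.center_mm
        tm = truth_mask(
            scene_with(cfg, branches=[straight_branch([10, c[0], c[1]], [1, 0, 0], 100, 3.0, 150)]), cfg
        )
        tmin, tmax, tmean = root_angles(skeletonize(tm, cfg.voxel_size_mm))
        assert tmean == pytest.approx(0.0, abs=2.0)
        assert tmin == pytest.approx(0.0, abs=2.0)
        assert tmax <= 10.0  # endpoint steps may wiggle, the mean must not

    def test_30_degree_stem_recovers_mean_within_2_degrees(self):
        cfg = PhantomConfig(seed=0)
        c = cfg.center_mm
        d = [math.cos(math.radians(30)), math.sin(math.radians(30)), 0]
        tm = truth_mask(
            scene_with(cfg, branches=[straight_branch([10, c[0] - 35, c[1]], d, 110, 3.0, 150)]), cfg
        )
        _, _, tmean = root_angles(skeletonize(tm, cfg.voxel_size_mm))
        assert tmean == pytest.approx(30.0, abs=2.0)

    def test_vertical_plus_horizontal_equal_length_averages_45(self):
        cfg = PhantomConfig(seed=0)
        c = cfg.center_mm
        branches = [
            straight_branch([20, c[0], c[1]], [1, 0, 0], 80, 3.0, 150),
            straight_branch([100, c[0], c[1]], [0, 1, 0], 80, 3.0, 150),
        ]
        tm = truth_mask(scene_with(cfg, branches=branches), cfg)
        _, _, tmean = root_angles(skeletonize(tm, cfg.voxel_size_mm))
        assert tmean == pytest.approx(45.0, abs=3.0)

    def test_empty_skeleton_gives_undefined_markers(self):
        skel = skeletonize(np.zeros((8, 8, 8), dtype=bool), (1, 1, 1))
        assert all(math.isnan(v) for v in root_angles(skel))


class TestDensityTraits:
    @staticmethod
    def _tube_scene():
        shape = (60, 40, 40)
        vol_arr = np.full(shape, 100.0, dtype=np.float32)
        mask = np.zeros(shape, dtype=bool)
        zz, yy, xx = np.mgrid[0:60, 0:40, 0:40]
        tube = ((yy - 20) ** 2 + (xx - 20) ** 2 <= 16) & (zz > 5) & (zz < 55)
        vol_arr[tube] = 150.0
        mask[tube] = True
        return Volume3D(vol_arr, (1, 1, 1)), mask

    def test_configured_grays_recovered_with_relation_factor(self):
        vol, mask = self._tube_scene()
        root, soil, relation = density_traits(vol, mask, open_pot(vol.shape))
        assert root == pytest.approx(150.0, abs=0.5)
        assert soil == pytest.approx(100.0, abs=0.5)
        assert relation == pytest.approx(100.0 * 100 / 150, abs=0.7)

    def test_constant_gray_offset_shifts_both_means(self):
        vol, mask = self._tube_scene()
        shifted = Volume3D(vol.voxels + 10.0, vol.spacing_mm)
        r0, s0, _ = density_traits(vol, mask, open_pot(vol.shape))
        r1, s1, _ = density_traits(shifted, mask, open_pot(vol.shape))
        assert r1 - r0 == pytest.approx(10.0, abs=1e-3)
        assert s1 - s0 == pytest.approx(10.0, abs=1e-3)

    def test_empty_mask_leaves_root_density_undefined(self):
        vol, _ = self._tube_scene()
        root, soil, relation = density_traits(vol, np.zeros(vol.shape, dtype=bool), open_pot(vol.shape))
        assert math.isnan(root) and math.isnan(relation)
        assert math.isfinite(soil)

    def test_mask_covering_whole_pot_leaves_soil_undefined(self):
        vol, _ = self._tube_scene()
        root, soil, relation = density_traits(vol, np.ones(vol.shape, dtype=bool), open_pot(vol.shape))
        assert math.isfinite(root)
        assert math.isnan(soil) and math.isnan(relation)


class TestFormFraction:
    def test_solid_sphere_is_near_100_percent(self):
        zz, yy, xx = np.mgrid[0:40, 0:40, 0:40]
        sphere = (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        f = form_fraction(sphere, (1, 1, 1))
        # voxel-corner hull slightly circumscribes the sphere at this radius
        assert 85.0 <= f <= 110.0

    def test_compact_tube_scores_high_and_spreading_branches_lower_it(self):
        m1 = np.zeros((60, 60, 60), dtype=bool)
        m1[5:55, 29:31, 29:31] = True  # a solid straight tube is its own hull
        f1 = form_fraction(m1, (1, 1, 1))
        m2 = m1.copy()
        m2[29:31, 5:55, 29:31] = True  # a crossing arm grows the hull far faster than the volume
        f2 = form_fraction(m2, (1, 1, 1))
        assert f1 == pytest.approx(100.0, abs=5.0)
        assert f2 < 0.5 * f1

    def test_two_distant_clusters_are_below_5_percent(self):
        m = np.zeros((120, 30, 30), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        m[115:118, 25:28, 25:28] = True
        assert form_fraction(m, (1, 1, 1)) < 5.0

    def test_degenerate_mask_is_undefined(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[5, 5, 5] = True
        assert math.isnan(form_fraction(m, (1, 1, 1)))


class TestVirtualBiomass:
    def test_uniform_organ_b_total_is_gray_times_volume(self):
        shape = (80, 20, 20)
        vol = Volume3D(np.full(shape, 140.0, dtype=np.float32), (1, 1, 1))
        mask = np.zeros(shape, dtype=bool)
        mask[10:70, 8:12, 8:12] = True
        prof = virtual_biomass_profile(vol, mask, open_pot(shape))
        v = root_volume(mask, (1, 1, 1))
        assert prof.b_total_au == pytest.approx(140.0 * v, rel=1e-12)

    def test_profile_conserves_the_voxel_sum(self, phantom_scene):
        vol, mask, pot = phantom_scene["vol"], phantom_scene["mask"], phantom_scene["pot"]
        prof = virtual_biomass_profile(vol, mask, pot)
        voxel_sum = float(vol.voxels[mask.mask].astype(np.float64).sum()) * vol.voxel_volume_mm3
        assert prof.b_total_au == pytest.approx(voxel_sum, rel=1e-9)
        assert prof.volume_mm3.sum() == pytest.approx(root_volume(mask.mask, vol.spacing_mm), rel=1e-9)

    def test_per_bin_biomass_matches_brute_force_voxel_sums(self):
        shape = (100, 30, 30)
        rng = np.random.default_rng(5)
        arr = rng.uniform(90, 110, shape).astype(np.float32)
        mask = np.zeros(shape, dtype=bool)
        mask[20:30, 10:20, 10:20] = True  # organ 1
        mask[60:75, 5:15, 5:15] = True  # organ 2, deeper
        arr[mask] = rng.uniform(140, 180, int(mask.sum()))
        vol = Volume3D(arr, (1, 1, 1))
        prof = virtual_biomass_profile(vol, mask, open_pot(shape), bin_height_mm=5.0)
        for i, (a, b) in enumerate(zip(prof.bin_edges_mm[:-1], prof.bin_edges_mm[1:])):
            zsel = np.zeros(shape, dtype=bool)
            zsel[int(a) : int(b)] = True
            want = float(arr[mask & zsel].astype(np.float64).sum())
            assert prof.biomass_au[i] == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_adding_soil_only_voxels_leaves_b_total_unchanged(self):
        shape = (50, 20, 20)
        arr = np.full(shape, 100.0, dtype=np.float32)
        mask = np.zeros(shape, dtype=bool)
        mask[10:40, 8:12, 8:12] = True
        arr[mask] = 150.0
        b1 = virtual_biomass_profile(Volume3D(arr, (1, 1, 1)), mask, open_pot(shape)).b_total_au
        arr2 = arr.copy()
        arr2[~mask] += 30.0  # soil change only
        b2 = virtual_biomass_profile(Volume3D(arr2, (1, 1, 1)), mask, open_pot(shape)).b_total_au
        assert b1 == b2

    def test_gray_rescale_scales_biomass_but_not_quantiles(self):
        shape = (60, 20, 20)
        rng = np.random.default_rng(2)
        arr = rng.uniform(80, 170, shape).astype(np.float32)
        mask = rng.random(shape) < 0.1
        vol, pot = Volume3D(arr, (1, 1, 1)), open_pot(shape)
        scaled = Volume3D(arr * 3.0, (1, 1, 1))
        b1 = virtual_biomass_profile(vol, mask, pot).b_total_au
        b2 = virtual_biomass_profile(scaled, mask, pot).b_total_au
        assert b2 == pytest.approx(3.0 * b1, rel=1e-6)
        q1 = quantile_depths(vol, mask, pot)
        q2 = quantile_depths(scaled, mask, pot)
        assert q1 == pytest.approx(q2, rel=1e-6)

    def test_sub_voxel_bin_height_is_rejected(self):
        shape = (20, 10, 10)
        vol = Volume3D(np.ones(shape, dtype=np.float32), (1, 1, 1))
        with pytest.raises(ValueError, match="bin height"):
            virtual_biomass_profile(vol, np.ones(shape, dtype=bool), open_pot(shape), bin_height_mm=0.5)


class TestCalibration:
    def test_exact_linear_pairs_recover_slope_intercept_r2(self):
        b = np.array([1e5, 2e5, 3.5e5, 5e5])
        pairs = list(zip(b, 0.002 * b))
        cal = calibrate_dry_weight(pairs)
        assert cal.slope == pytest.approx(0.002, rel=1e-9)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_pairs_recover_slope_within_2_standard_errors(self):
        rng = np.random.default_rng(7)
        b = rng.uniform(1e5, 8e5, 30)
        w = 0.002 * b + rng.normal(0, 20.0, 30)
        cal = calibrate_dry_weight(list(zip(b, w)))
        se = 20.0 / (np.std(b) * math.sqrt(30))
        assert abs(cal.slope - 0.002) < 2 * se

    def test_fewer_than_three_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="3"):
            calibrate_dry_weight([(1.0, 2.0), (2.0, 4.0)])

    def test_zero_spread_is_an_error(self):
        with pytest.raises(ValueError, match="spread"):
            calibrate_dry_weight([(1.0, 2.0), (1.0, 2.1), (1.0, 1.9)])


class TestComputeAllTraits:
    def test_phantom_end_to_end_recovers_every_trait(self, phantom_scene):
        cfg, truth = phantom_scene["cfg"], phantom_scene["truth"]
        rec = compute_all_traits(
            phantom_scene["vol"],
            phantom_scene["mask"],
            phantom_scene["skel"],
            phantom_scene["pot"],
            plant_id="p1",
            timestamp="2023-01-01T00:00:00",
        )
        want = truth_traits(truth, cfg)
        assert rec.v_root_mm3 == pytest.approx(want.v_root_mm3, rel=0.10)
        assert rec.l_root_mm == pytest.approx(want.l_root_mm, rel=0.10)
        assert rec.theta_mean_deg == pytest.approx(want.theta_mean_deg, abs=3.0)
        assert rec.d50_mm == pytest.approx(want.d50_mm, abs=3.0)
        assert rec.soil_root_density_relation_pct == pytest.approx(
            want.soil_root_density_relation_pct, rel=0.05
        )
        assert rec.b_total_au == pytest.approx(want.b_total_au, rel=0.12)

    def test_empty_mask_reports_zero_volume_and_undefined_rest(self, phantom_scene):
        empty = np.zeros(phantom_scene["vol"].shape, dtype=bool)
        skel = skeletonize(empty, phantom_scene["vol"].spacing_mm)
        rec = compute_all_traits(phantom_scene["vol"], empty, skel, phantom_scene["pot"])
        assert rec.v_root_mm3 == 0.0
        assert math.isnan(rec.d50_mm)
        assert math.isnan(rec.theta_mean_deg)
        assert math.isnan(rec.root_density_au)

    def test_grid_mismatch_is_rejected(self, phantom_scene):
        bad = np.zeros((8, 8, 8), dtype=bool)
        skel = skeletonize(bad, (1, 1, 1))
        with pytest.raises(ValueError, match="does not match"):
            compute_all_traits(phantom_scene["vol"], bad, skel, phantom_scene["pot"])

    def test_record_round_trips_through_trait_csv(self, tmp_path, phantom_scene):
        from rootct.volume_io import read_trait_table, write_trait_table

        rec = compute_all_traits(
            phantom_scene["vol"],
            phantom_scene["mask"],
            phantom_scene["skel"],
            phantom_scene["pot"],
            plant_id="p1",
            timestamp="t1",
        )
        path = write_trait_table([rec], tmp_path / "t.csv")
        back = read_trait_table(path)
        assert back["V_root_mm3"].iloc[0] == pytest.approx(rec.v_root_mm3)
        assert back["theta_mean_deg"].iloc[0] == pytest.approx(rec.theta_mean_deg, rel=1e-6)

    def test_calibration_option_fills_dry_weight(self, phantom_scene):
        b = np.array([1e5, 3e5, 6e5])
        cal = calibrate_dry_weight(list(zip(b, 0.002 * b)))
        rec = compute_all_traits(
            phantom_scene["vol"],
            phantom_scene["mask"],
            phantom_scene["skel"],
            phantom_scene["pot"],
            options=TraitOptions(calibration=cal),
        )
        assert rec.dry_weight_g == pytest.approx(0.002 * rec.b_total_au, rel=1e-9)
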