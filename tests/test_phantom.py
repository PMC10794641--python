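"""Phantom generator: analytic truths, determinism, rendering fidelity,
and the growth time series."""

import math
from dataclasses import replace

import numpy as np
import pytest

from conftest import make_tuber, scene_with, straight_branch
from rootct.phantom import (
    BranchingParams,
    OrganGrowth,
    PhantomConfig,
    generate_root_system,
    logistic_volume,
    render_time_series,
    render_volume,
    truth_mask,
)


class TestGenerateRootSystem:
    def test_single_vertical_stem_has_its_configured_length(self):
        cfg = PhantomConfig(
            seed=1,
            branching=BranchingParams(depth=0, segment_length_mm=(100.0, 100.0)),
            stem_tilt_deg=(0.0, 0.0),
        )
        truth = generate_root_system(cfg)
        assert len(truth.branches) == 1
        assert truth.total_length_mm == pytest.approx(100.0)
        assert truth.branches[0].angle_deg == pytest.approx(0.0)

    def test_same_config_and_seed_is_bit_identical(self):
        cfg = PhantomConfig(seed=9)
        t1, t2 = generate_root_system(cfg), generate_root_system(cfg)
        assert len(t1.branches) == len(t2.branches)
        for a, b in zip(t1.branches, t2.branches):
            np.testing.assert_array_equal(a.points, b.points)
        v1, v2 = render_volume(t1, cfg), render_volume(t2, cfg)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)

    def test_two_level_binary_tree_with_fixed_segments_sums_to_140mm(self):
        # 1 + 2 + 4 segments of 20 mm, nothing clipped near the pot center
        cfg = PhantomConfig(
            seed=3,
            branching=BranchingParams(depth=2, n_branches=2, segment_length_mm=(20.0, 20.0)),
        )
        truth = generate_root_system(cfg)
        brute = sum(
            float(np.linalg.norm(np.diff(b.points, axis=0), axis=1).sum()) for b in truth.branches
        )
        assert truth.total_length_mm == pytest.approx(brute)
        assert truth.total_length_mm == pytest.approx(140.0)

    def test_impossible_geometry_is_rejected_with_message(self):
        cfg = PhantomConfig(
            seed=0,
            grid_shape=(24, 160, 160),
            pot_height_mm=4.0,
            branching=BranchingParams(depth=0, segment_length_mm=(100.0, 100.0)),
        )
        with pytest.raises(ValueError, match="stem segment"):
            generate_root_system(cfg)

    def test_zero_contrast_config_is_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            PhantomConfig(seed=0, root_gray=100.0, soil_mean=100.0).validate()

    def test_all_organ_voxels_lie_inside_the_pot(self):
        cfg = PhantomConfig(seed=12)
        truth = generate_root_system(cfg)
        tm = truth_mask(truth, cfg)
        sz, sy, sx = cfg.voxel_size_mm
        cy, cx = cfg.center_mm
        idx = np.argwhere(tm)
        rad = np.hypot(idx[:, 1] * sy - cy, idx[:, 2] * sx - cx)
        assert rad.max() <= cfg.interior_radius_mm + max(sy, sx)
        z = idx[:, 0] * sz
        assert z.min() >= cfg.surface_mm - sz
        assert z.max() <= cfg.bottom_mm + sz


class TestRenderVolume:
    def test_rootless_noiseless_pot_is_pure_soil_texture(self):
        cfg = PhantomConfig(
            seed=5, noise_sd=0.0, branching=BranchingParams(depth=0, segment_length_mm=(0.0, 0.0))
        )
        truth = scene_with(cfg)
        v1 = render_volume(truth, cfg)
        v2 = render_volume(truth, cfg)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        cy, cx = cfg.center_mm
        probe = v1.voxels[40:100, int(cy) - 20 : int(cy) + 20, int(cx) - 20 : int(cx) + 20]
        assert probe.mean() == pytest.approx(cfg.soil_mean, abs=1.0)
        assert 0 < probe.std() < 3 * cfg.soil_sd
        assert v1.voxels[0].max() == 0.0  # air above the pot

    def test_rendered_sphere_volume_matches_analytic_within_3pct(self):
        cfg = PhantomConfig(
            seed=6,
            grid_shape=(96, 128, 128),
            voxel_size_mm=(0.5, 0.5, 0.5),
            pot_radius_mm=30.0,
            pot_height_mm=40.0,
            noise_sd=0.0,
        )
        tub = make_tuber(cfg, [24.0, cfg.center_mm[0], cfg.center_mm[1]], (10.0, 10.0, 10.0))
        truth = scene_with(cfg, tubers=[tub])
        vol = render_volume(truth, cfg)
        midpoint = 0.5 * (cfg.soil_mean + cfg.tuber_gray)
        below_wall = 0.5 * (cfg.tuber_gray + cfg.wall_gray)  # exclude the bright pot shell
        measured = (
            float(((vol.voxels > midpoint) & (vol.voxels < below_wall)).sum()) * vol.voxel_volume_mm3
        )
        analytic = 4.0 / 3.0 * math.pi * 10.0**3
        assert measured == pytest.approx(analytic, rel=0.03)

    def test_channel_core_is_darker_than_cortex(self):
        cfg = PhantomConfig(seed=7, noise_sd=0.0)
        c = cfg.center_mm
        tub = make_tuber(cfg, [80.0, c[0], c[1]], (25.0, 10.0, 10.0), axis=(0, 1, 0), channel_fraction=0.4)
        vol = render_volume(scene_with(cfg, tubers=[tub]), cfg)
        zz, yy, xx = np.mgrid[0:160, 0:160, 0:160].astype(float)
        d_axis = np.sqrt((zz - 80.0) ** 2 + (xx - c[1]) ** 2)  # distance from the y-axis line
        along = np.abs(yy - c[0])
        core = (d_axis <= 0.4 * 10 * 0.8) & (along < 20)
        cortex = (d_axis > 6.0) & (d_axis <= 9.0) & (along < 20)
        assert vol.voxels[core].mean() < vol.voxels[cortex].mean()

    def test_rasterized_volume_converges_to_analytic_with_resolution(self):
        # halving the voxel size should at least halve the volume error
        errs = []
        for spacing, shape in ((1.0, (96, 128, 128)), (0.5, (192, 256, 256))):
            cfg = PhantomConfig(
                seed=8,
                grid_shape=shape,
                voxel_size_mm=(spacing,) * 3,
                pot_radius_mm=55.0,
                pot_height_mm=80.0,
                noise_sd=0.0,
            )
            c = cfg.center_mm
            # an ellipsoid has an exact analytic volume with no end-cap
            # ambiguity, isolating pure voxelization error
            truth = scene_with(
                cfg, tubers=[make_tuber(cfg, [50.0, c[0] + 20, c[1]], (12.0, 9.0, 7.0), axis=(0.3, 1, 0.2))]
            )
            voxvol = float(truth_mask(truth, cfg).sum()) * spacing**3
            errs.append(abs(voxvol - truth.total_volume_mm3) / truth.total_volume_mm3)
        assert errs[1] <= 0.55 * errs[0] or errs[1] < 0.003


class TestTruthTraits:
    def test_uniform_vertical_stem_median_depth_is_midpoint(self):
        cfg = PhantomConfig(seed=0)
        c = cfg.center_mm
        stem = straight_branch([cfg.surface_mm, c[0], c[1]], [1, 0, 0], 160.0, 3.0, cfg.root_gray)
        truth = scene_with(replace(cfg, pot_height_mm=200.0, grid_shape=(220, 160, 160)), branches=[stem])
        truth = replace(truth, bottom_mm=cfg.surface_mm + 200.0)
        d = truth.quantile_depths_mm([0.5])
        assert d[0] == pytest.approx(80.0, abs=0.5)

    def test_inclined_stem_truth_angle(self):
        cfg = PhantomConfig(seed=0)
        c = cfg.center_mm
        d = [math.cos(math.radians(30)), math.sin(math.radians(30)), 0.0]
        stem = straight_branch([cfg.surface_mm, c[0] - 30, c[1]], d, 100.0, 3.0, cfg.root_gray)
        truth = scene_with(cfg, branches=[stem])
        assert truth.theta_stats()[2] == pytest.approx(30.0, abs=1e-6)

    def test_random_truth_quantiles_match_numeric_integration_oracle(self):
        cfg = PhantomConfig(seed=21)
        truth = generate_root_system(cfg)
        got = truth.quantile_depths_mm()
        # independent oracle: integrate mass along each segment on a very
        # fine 1D grid and invert the cumulative distribution
        ds = 0.01
        depths, masses = [], []
        for b in truth.branches:
            p0, p1 = b.points[0], b.points[-1]
            L = float(np.linalg.norm(p1 - p0))
            n = int(L / ds)
            t = (np.arange(n) + 0.5) / n
            depths.append(p0[0] + t * (p1[0] - p0[0]) - truth.surface_mm)
            masses.append(np.full(n, b.gray * math.pi * b.radius_mm**2 * L / n))
        depths, masses = np.concatenate(depths), np.concatenate(masses)
        order = np.argsort(depths)
        cum = np.cumsum(masses[order])
        want = [float(np.interp(q * cum[-1], cum, depths[order])) for q in (0.25, 0.5, 0.75, 0.9)]
        assert got == pytest.approx(want, abs=0.5)


class TestTimeSeries:
    G = OrganGrowth(k_mm3=60000.0, r_per_day=0.15, v0_mm3=1000.0)

    def test_stress_factor_zero_freezes_volume_inside_window(self):
        scans = render_time_series(
            PhantomConfig(seed=5), 40, tuber_growth=[self.G], stress_window=(10, 20), stress_factor=0.0
        )
        inside = [s.organ_volumes_mm3["tuber_1"] for s in scans if 10 <= s.day <= 20]
        assert max(inside) - min(inside) < 1e-6 * max(inside)

    def test_stress_factor_one_is_identical_to_unstressed(self):
        cfg = PhantomConfig(seed=5)
        a = render_time_series(cfg, 30, tuber_growth=[self.G], stress_window=(10, 20), stress_factor=1.0)
        b = render_time_series(cfg, 30, tuber_growth=[self.G])
        for sa, sb in zip(a, b):
            assert sa.organ_volumes_mm3 == sb.organ_volumes_mm3

    def test_volumes_follow_the_closed_form_logistic(self):
        scans = render_time_series(PhantomConfig(seed=5), 30, tuber_growth=[self.G])
        for s in scans:
            want = logistic_volume(self.G, s.day)
            assert s.organ_volumes_mm3["tuber_1"] == pytest.approx(want, rel=0.01)

    def test_stress_monotonicity_in_the_stress_factor(self):
        cfg = PhantomConfig(seed=5)
        ends = []
        for f in (0.0, 0.5, 1.0):
            scans = render_time_series(cfg, 30, tuber_growth=[self.G], stress_window=(6, 20), stress_factor=f)
            ends.append(scans[10].organ_volumes_mm3["tuber_1"])  # day 20
        assert ends[0] <= ends[1] <= ends[2]

    def test_invalid_stress_window_is_rejected(self):
        with pytest.raises(ValueError, match="stress window"):
            render_time_series(PhantomConfig(seed=5), 10, tuber_growth=[self.G], stress_window=(8, 20))

    def test_rendered_series_produces_volumes(self):
        cfg = PhantomConfig(
            grid_shape=(64, 64, 64),
            voxel_size_mm=(2.0, 2.0, 2.0),
            pot_radius_mm=40.0,
            pot_height_mm=90.0,
            branching=BranchingParams(depth=0, segment_length_mm=(40.0, 40.0), radius_mm=(3.0, 4.0)),
            seed=5,
        )
        g = OrganGrowth(k_mm3=8000.0, r_per_day=0.2, v0_mm3=1000.0)
        scans = render_time_series(cfg, 4, tuber_growth=[g], scan_every_days=4, render=True)
        assert all(s.volume is not None for s in scans)
        assert scans[1].volume.voxels.shape == (64, 64, 64)
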