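"""Shared fixtures: all inputs are generated programmatically.

The heavy 160^3 phantom scenes are session-scoped so the segmentation
and trait tests share one rendering + segmentation pass.
"""

from __future__ import annotations

import numpy as np
import pytest

from rootct.phantom import (
    Branch,
    PhantomConfig,
    RootSystemTruth,
    Tuber,
    generate_root_system,
    render_volume,
    truth_mask,
)
from rootct.segmentation import detect_pot, segment_roots, skeletonize


def make_tuber(cfg: PhantomConfig, center, semi_axes, axis=(0.0, 0.0, 1.0), channel_fraction=0.0):
    ax = np.asarray(axis, dtype=float)
    ax /= np.linalg.norm(ax)
    return Tuber(
        center_mm=np.asarray(center, dtype=float),
        semi_axes_mm=tuple(semi_axes),
        axis_dir=ax,
        gray=cfg.tuber_gray,
        channel_fraction=channel_fraction,
        channel_gray=cfg.tuber_gray * cfg.channel_gray_factor,
    )


def scene_with(cfg: PhantomConfig, branches=(), tubers=()) -> RootSystemTruth:
    """A hand-built phantom scene (no stochastic generation)."""
    return RootSystemTruth(
        branches=list(branches),
        tubers=list(tubers),
        surface_mm=cfg.surface_mm,
        bottom_mm=cfg.bottom_mm,
        center_mm=cfg.center_mm,
        interior_radius_mm=cfg.interior_radius_mm,
    )


def straight_branch(p0, direction, length, radius, gray, angle_deg=None):
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if angle_deg is None:
        angle_deg = float(np.degrees(np.arccos(abs(d[0]))))
    return Branch(np.stack([p0, p0 + length * d]), radius, gray, 0, angle_deg)


@pytest.fixture(scope="session")
def default_cfg() -> PhantomConfig:
    return PhantomConfig(seed=4)


@pytest.fixture(scope="session")
def phantom_scene(default_cfg):
    """One rendered noisy phantom (CNR 5) with its full measurement chain."""
    truth = generate_root_system(default_cfg)
    vol = render_volume(truth, default_cfg)
    tm = truth_mask(truth, default_cfg)
    pot = detect_pot(vol)
    mask = segment_roots(vol, pot)
    skel = skeletonize(mask)
    return {
        "cfg": default_cfg,
        "truth": truth,
        "vol": vol,
        "truth_mask": tm,
        "pot": pot,
        "mask": mask,
        "skel": skel,
    }


@pytest.fixture(scope="session")
def noiseless_scene():
    """Same phantom geometry rendered without additive noise."""
    cfg = PhantomConfig(seed=4, noise_sd=0.0)
    truth = generate_root_system(cfg)
    vol = render_volume(truth, cfg)
    tm = truth_mask(truth, cfg)
    pot = detect_pot(vol)
    mask = segment_roots(vol, pot)
    return {"cfg": cfg, "truth": truth, "vol": vol, "truth_mask": tm, "pot": pot, "mask": mask}


@pytest.fixture(scope="session")
def small_cfg() -> PhantomConfig:
    """Coarse, fast phantom configuration for pipeline-level tests."""
    from rootct.phantom import BranchingParams

    return PhantomConfig(
        grid_shape=(96, 96, 96),
        voxel_size_mm=(1.5, 1.5, 1.5),
        pot_radius_mm=60.0,
        pot_height_mm=120.0,
        branching=BranchingParams(
            depth=1, n_branches=2, segment_length_mm=(25.0, 45.0), radius_mm=(2.5, 4.0)
        ),
        seed=0,
    )
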