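"""Ground-truthed synthetic pot phantoms.

Generates cylindrical soil-filled pots containing branching root systems
and/or ellipsoidal storage organs (tubers), renders them into grayscale
voxel volumes with textured soil and additive noise, and records every
quantity the trait pipeline later estimates — length, volume, insertion
angles, mass-depth distribution — analytically from the generating
geometry. Growth time series with a stress window emulate longitudinal
scanning experiments.

Geometry lives in millimetres; the depth axis is axis 0 of the grid with
``depth_mm = index * spacing`` and index 0 at the top (air above the
soil surface). Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from rootct.volume_io import Volume3D

__all__ = [
    "BranchingParams",
    "PhantomConfig",
    "Branch",
    "Tuber",
    "RootSystemTruth",
    "OrganGrowth",
    "DailyScan",
    "generate_root_system",
    "render_volume",
    "truth_mask",
    "truth_traits",
    "render_time_series",
    "logistic_volume",
]

_SUB = np.array(
    [(dz, dy, dx) for dz in (-1 / 3, 0, 1 / 3) for dy in (-1 / 3, 0, 1 / 3) for dx in (-1 / 3, 0, 1 / 3)]
)  # 3x3x3 supersampling offsets, in units of one voxel edge


@dataclass(frozen=True)
class BranchingParams:
    """Recursive branching model: ``depth`` levels below the stem, each
    node spawning ``n_branches`` children deflected by an insertion angle
    drawn from ``angle_range_deg`` relative to the parent direction."""

    depth: int = 2
    n_branches: int = 2
    angle_range_deg: tuple[float, float] = (20.0, 50.0)
    segment_length_mm: tuple[float, float] = (30.0, 60.0)
    radius_mm: tuple[float, float] = (2.0, 3.5)


@dataclass(frozen=True)
class PhantomConfig:
    """Scene description for one synthetic pot.

    Gray values are arbitrary attenuation units. ``noise_sd`` is the SD
    of additive Gaussian noise inside the pot; the contrast-to-noise
    ratio is ``|root_gray - soil_mean| / noise_sd``. ``channel_fraction``
    is the relative cross-sectional radius of the low-density channel
    rendered inside storage organs (0 disables it).
    """

    grid_shape: tuple[int, int, int] = (160, 160, 160)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pot_radius_mm: float = 70.0
    pot_height_mm: float = 150.0
    pot_wall_mm: float = 3.0
    air_gap_mm: float = 4.0
    soil_mean: float = 100.0
    soil_sd: float = 5.0
    texture_corr_vox: float = 3.0
    root_gray: float = 150.0
    tuber_gray: float = 160.0
    wall_gray: float = 200.0
    noise_sd: float = 10.0
    branching: BranchingParams = field(default_factory=BranchingParams)
    stem_tilt_deg: tuple[float, float] = (0.0, 8.0)
    n_tubers: int = 0
    tuber_semiaxis_mm: tuple[float, float] = (8.0, 12.0)
    tuber_axis_ratio: float = 1.0
    channel_fraction: float = 0.0
    channel_gray_factor: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        nz, ny, nx = self.grid_shape
        sz, sy, sx = self.voxel_size_mm
        if min(self.grid_shape) < 8:
            raise ValueError("grid_shape too small")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        if 2 * self.pot_radius_mm > min((ny - 1) * sy, (nx - 1) * sx):
            raise ValueError("pot cylinder does not fit inside the grid cross-section")
        if self.air_gap_mm >= (nz - 1) * sz:
            raise ValueError("air gap leaves no room for the pot")
        if self.root_gray == self.soil_mean:
            raise ValueError("root_gray must differ from soil_mean (nonzero contrast)")
        if self.branching.radius_mm[0] <= max(self.voxel_size_mm):
            raise ValueError("branch radii must exceed one voxel edge")
        if not (0.0 <= self.channel_fraction < 1.0):
            raise ValueError("channel_fraction must lie in [0, 1)")

    # derived pot frame --------------------------------------------------

    @property
    def center_mm(self) -> tuple[float, float]:
        """(y, x) of the pot axis, at the grid cross-section center."""
        _, ny, nx = self.grid_shape
        _, sy, sx = self.voxel_size_mm
        return ((ny - 1) / 2 * sy, (nx - 1) / 2 * sx)

    @property
    def surface_mm(self) -> float:
        return self.air_gap_mm

    @property
    def bottom_mm(self) -> float:
        nz = self.grid_shape[0]
        sz = self.voxel_size_mm[0]
        return min(self.surface_mm + self.pot_height_mm, (nz - 1) * sz - self.pot_wall_mm)

    @property
    def interior_radius_mm(self) -> float:
        return self.pot_radius_mm - self.pot_wall_mm


@dataclass
class Branch:
    """One straight root segment: a polyline of mm coordinates with a
    constant radius, its gray value, branching level, and the insertion
    angle from the vertical (gravitropic) axis in degrees."""

    points: np.ndarray  # (N, 3) mm, (z, y, x)
    radius_mm: float
    gray: float
    level: int
    angle_deg: float

    @property
    def length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def volume_mm3(self) -> float:
        return math.pi * self.radius_mm**2 * self.length_mm


@dataclass
class Tuber:
    """Ellipsoidal storage organ. ``semi_axes_mm[0]`` lies along
    ``axis_dir``; a coaxial low-density channel of relative radius
    ``channel_fraction`` and gray ``channel_gray`` may run through it."""

    center_mm: np.ndarray  # (3,)
    semi_axes_mm: tuple[float, float, float]
    axis_dir: np.ndarray  # (3,) unit
    gray: float
    channel_fraction: float = 0.0
    channel_gray: float = 0.0

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass
class RootSystemTruth:
    """Analytic ground truth for one phantom scene."""

    branches: list[Branch]
    tubers: list[Tuber]
    surface_mm: float
    bottom_mm: float
    center_mm: tuple[float, float]
    interior_radius_mm: float

    # ---- scalar truths -------------------------------------------------

    @property
    def total_length_mm(self) -> float:
        return float(sum(b.length_mm for b in self.branches))

    @property
    def branch_volume_mm3(self) -> float:
        return float(sum(b.volume_mm3 for b in self.branches))

    @property
    def tuber_volume_mm3(self) -> float:
        return float(sum(t.volume_mm3 for t in self.tubers))

    @property
    def total_volume_mm3(self) -> float:
        return self.branch_volume_mm3 + self.tuber_volume_mm3

    def theta_stats(self) -> tuple[float, float, float]:
        """(min, max, length-weighted mean) insertion angle in degrees."""
        if not self.branches:
            return (math.nan, math.nan, math.nan)
        angles = np.array([b.angle_deg for b in self.branches])
        lengths = np.array([b.length_mm for b in self.branches])
        mean = float(np.average(angles, weights=lengths)) if lengths.sum() > 0 else math.nan
        return float(angles.min()), float(angles.max()), mean

    def b_total_au(self) -> float:
        """Total virtual biomass: sum of gray x volume over all organs."""
        total = sum(b.gray * b.volume_mm3 for b in self.branches)
        for t in self.tubers:
            if t.channel_fraction > 0:
                # channel is a coaxial cylinder in normalized cross-section:
                # it occupies channel_fraction^2 of the ellipsoid volume
                f = t.channel_fraction**2
                total += t.volume_mm3 * ((1 - f) * t.gray + f * t.channel_gray)
            else:
                total += t.gray * t.volume_mm3
        return float(total)

    # ---- mass-depth distribution ---------------------------------------

    def mass_depth_samples(
        self, weighting: str = "attenuation", ds_mm: float = 0.25
    ) -> tuple[np.ndarray, np.ndarray]:
        """Fine samples of (depth below surface, mass element).

        Mass element per unit length of a branch is gray x pi r^2 under
        attenuation weighting, or pi r^2 under volume weighting. Tubers
        are integrated on a fine voxel grid.
        """
        depths: list[np.ndarray] = []
        masses: list[np.ndarray] = []
        for b in self.branches:
            for p0, p1 in zip(b.points[:-1], b.points[1:]):
                seg = p1 - p0
                L = float(np.linalg.norm(seg))
                if L <= 0:
                    continue
                n = max(2, int(math.ceil(L / ds_mm)))
                t = (np.arange(n) + 0.5) / n
                z = p0[0] + t * seg[0]
                dens = math.pi * b.radius_mm**2 * (L / n)
                if weighting == "attenuation":
                    dens *= b.gray
                depths.append(z - self.surface_mm)
                masses.append(np.full(n, dens))
        for t_org in self.tubers:
            d, m = _tuber_depth_mass(t_org, weighting, ds_mm=max(ds_mm, 0.5))
            depths.append(d - self.surface_mm)
            masses.append(m)
        if not depths:
            return np.empty(0), np.empty(0)
        return np.concatenate(depths), np.concatenate(masses)

    def quantile_depths_mm(
        self, quantiles: Sequence[float] = (0.25, 0.5, 0.75, 0.9), weighting: str = "attenuation"
    ) -> list[float]:
        """Ground-truth root-mass quantile depths below the soil surface."""
        d, m = self.mass_depth_samples(weighting)
        if d.size == 0:
            return [math.nan] * len(quantiles)
        order = np.argsort(d)
        d, m = d[order], m[order]
        cum = np.cumsum(m)
        total = cum[-1]
        return [float(np.interp(q * total, cum, d)) for q in quantiles]

    def scaled(self, s_root: float, s_tubers: Sequence[float] | None = None) -> "RootSystemTruth":
        """Uniformly scale branch geometry about the stem entry point and
        tuber semi-axes about their centers (volume scales as s^3)."""
        if not self.branches:
            origin = np.array([self.surface_mm, *self.center_mm])
        else:
            origin = self.branches[0].points[0]
        new_branches = [
            replace(
                b,
                points=origin + s_root * (b.points - origin),
                radius_mm=b.radius_mm * s_root,
            )
            for b in self.branches
        ]
        if s_tubers is None:
            s_tubers = [s_root] * len(self.tubers)
        new_tubers = [
            replace(t, semi_axes_mm=tuple(a * s for a in t.semi_axes_mm))
            for t, s in zip(self.tubers, s_tubers)
        ]
        return replace(self, branches=new_branches, tubers=new_tubers)


def _tuber_depth_mass(t: Tuber, weighting: str, ds_mm: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a tuber's mass over depth on a fine regular grid."""
    a = max(t.semi_axes_mm)
    lo = t.center_mm - a - ds_mm
    hi = t.center_mm + a + ds_mm
    axes = [np.arange(lo[i], hi[i], ds_mm) for i in range(3)]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([Z.ravel(), Y.ravel(), X.ravel()], axis=1) - t.center_mm
    u, v, w = _orthobasis(t.axis_dir)
    lu = pts @ u / t.semi_axes_mm[0]
    lv = pts @ v / t.semi_axes_mm[1]
    lw = pts @ w / t.semi_axes_mm[2]
    inside = lu**2 + lv**2 + lw**2 <= 1.0
    if not inside.any():
        return np.empty(0), np.empty(0)
    vol_el = ds_mm**3
    gray = np.full(inside.sum(), t.gray)
    if t.channel_fraction > 0:
        chan = np.sqrt(lv[inside] ** 2 + lw[inside] ** 2) <= t.channel_fraction
        gray[chan] = t.channel_gray
    mass = gray * vol_el if weighting == "attenuation" else np.full(inside.sum(), vol_el)
    return Z.ravel()[inside], mass


def _orthobasis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.asarray(d, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(d, helper)
    v /= np.linalg.norm(v)
    w = np.cross(d, v)
    return d, v, w


# ---------------------------------------------------------------------------
# generation


def generate_root_system(config: PhantomConfig) -> RootSystemTruth:
    """Grow a stochastic branching root system (plus optional tubers)
    inside the pot, recording analytic truth for every organ.

    The stem enters at the soil-surface center; each level spawns
    ``n_branches`` children deflected by a random insertion angle.
    Geometry is clipped to the pot interior. Raises ``ValueError`` if the
    pot cannot fit even one stem segment.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 101])
    bp = config.branching
    cy, cx = config.center_mm
    start = np.array([config.surface_mm, cy, cx])

    tilt = math.radians(rng.uniform(*config.stem_tilt_deg))
    az = rng.uniform(0, 2 * math.pi)
    direction = np.array([math.cos(tilt), math.sin(tilt) * math.cos(az), math.sin(tilt) * math.sin(az)])

    branches: list[Branch] = []
    min_seg = 2.0 * max(config.voxel_size_mm)

    def radius_for(level: int) -> float:
        r_lo, r_hi = bp.radius_mm
        if bp.depth == 0:
            return r_hi
        f = level / bp.depth
        return r_hi * (1 - f) + r_lo * f

    stack = [(start, direction, 0)]
    while stack:
        p0, d, level = stack.pop(0)
        length = float(rng.uniform(*bp.segment_length_mm))
        r = radius_for(level)
        t_max = _clip_to_pot(p0, d, length, r, config)
        if t_max < min_seg:
            if level == 0:
                raise ValueError(
                    "pot geometry cannot fit one stem segment; enlarge the pot or shorten segments"
                )
            # child cannot fit: still consume its angle draws for determinism
            if level < bp.depth:
                for _ in range(bp.n_branches):
                    rng.uniform(*bp.angle_range_deg)
                    rng.uniform(0, 2 * math.pi)
            continue
        p1 = p0 + t_max * d
        angle = math.degrees(math.acos(min(1.0, abs(float(d[0])))))
        branches.append(Branch(np.stack([p0, p1]), r, config.root_gray, level, angle))
        if level < bp.depth:
            _, u, v = _orthobasis(d)
            for _ in range(bp.n_branches):
                delta = math.radians(rng.uniform(*bp.angle_range_deg))
                caz = rng.uniform(0, 2 * math.pi)
                child = math.cos(delta) * d + math.sin(delta) * (math.cos(caz) * u + math.sin(caz) * v)
                child /= np.linalg.norm(child)
                stack.append((p1, child, level + 1))

    tubers = _generate_tubers(config, rng)
    return RootSystemTruth(
        branches=branches,
        tubers=tubers,
        surface_mm=config.surface_mm,
        bottom_mm=config.bottom_mm,
        center_mm=config.center_mm,
        interior_radius_mm=config.interior_radius_mm,
    )


def _clip_to_pot(p0: np.ndarray, d: np.ndarray, length: float, r: float, config: PhantomConfig) -> float:
    """Largest t in [0, length] keeping the tube inside the pot interior."""
    cy, cx = config.center_mm
    r_lim = config.interior_radius_mm - r - 0.5
    t_max = length
    # depth bounds: stay below the surface entry and above the bottom
    if d[0] < 0:
        t_max = min(t_max, (config.surface_mm - p0[0]) / d[0]) if d[0] != 0 else t_max
    else:
        lim = config.bottom_mm - r - p0[0]
        if d[0] > 1e-12:
            t_max = min(t_max, lim / d[0])
    # radial bound: |p0_r + t d_r| <= r_lim  (quadratic in t)
    pr = np.array([p0[1] - cy, p0[2] - cx])
    dr = np.array([d[1], d[2]])
    a = float(dr @ dr)
    b = 2.0 * float(pr @ dr)
    c = float(pr @ pr) - r_lim**2
    if a > 1e-12:
        disc = b * b - 4 * a * c
        if disc >= 0:
            t_exit = (-b + math.sqrt(disc)) / (2 * a)
            if t_exit >= 0:
                t_max = min(t_max, t_exit)
        else:
            t_max = 0.0
    elif c > 0:
        t_max = 0.0
    return max(0.0, t_max)


def _generate_tubers(config: PhantomConfig, rng: np.random.Generator) -> list[Tuber]:
    tubers: list[Tuber] = []
    depth_span = config.bottom_mm - config.surface_mm
    cy, cx = config.center_mm
    for _ in range(config.n_tubers):
        minor = float(rng.uniform(*config.tuber_semiaxis_mm))
        major = minor * config.tuber_axis_ratio
        z = config.surface_mm + rng.uniform(0.3, 0.75) * depth_span
        rad = rng.uniform(0, max(0.0, config.interior_radius_mm - major - 2.0) * 0.6)
        az = rng.uniform(0, 2 * math.pi)
        center = np.array([z, cy + rad * math.cos(az), cx + rad * math.sin(az)])
        # keep inside vertically
        center[0] = float(np.clip(center[0], config.surface_mm + major + 1, config.bottom_mm - major - 1))
        tilt = rng.uniform(0, 2 * math.pi)
        axis = np.array([0.2, math.cos(tilt), math.sin(tilt)])
        axis /= np.linalg.norm(axis)
        tubers.append(
            Tuber(
                center_mm=center,
                semi_axes_mm=(major, minor, minor),
                axis_dir=axis,
                gray=config.tuber_gray,
                channel_fraction=config.channel_fraction,
                channel_gray=config.tuber_gray * config.channel_gray_factor,
            )
        )
    return tubers


# ---------------------------------------------------------------------------
# rendering


def _index_grid(lo_mm: np.ndarray, hi_mm: np.ndarray, shape, spacing) -> tuple[slice, ...] | None:
    idx_lo = np.maximum(np.floor(lo_mm / spacing).astype(int), 0)
    idx_hi = np.minimum(np.ceil(hi_mm / spacing).astype(int) + 1, shape)
    if np.any(idx_lo >= idx_hi):
        return None
    return tuple(slice(int(a), int(b)) for a, b in zip(idx_lo, idx_hi))


def _bbox_points(sl: tuple[slice, ...], spacing: np.ndarray) -> np.ndarray:
    axes = [np.arange(s.start, s.stop) * sp for s, sp in zip(sl, spacing)]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    return np.stack([Z.ravel(), Y.ravel(), X.ravel()], axis=1)


def _segment_coverage(cov: np.ndarray, p0, p1, radius, spacing, chunk_mm: float = 8.0) -> None:
    """Accumulate supersampled tube coverage into ``cov`` (max-combine).

    The segment is processed in short chunks so bounding boxes stay
    compact even for long diagonal segments; distances are always taken
    to the full segment, so chunking does not change the result.
    """
    seg = p1 - p0
    L = float(np.linalg.norm(seg))
    L2 = L * L
    margin = radius + float(max(spacing))
    sub = _SUB * spacing  # (27, 3)
    n_chunks = max(1, int(math.ceil(L / chunk_mm)))
    for k in range(n_chunks):
        a = p0 + seg * (k / n_chunks)
        b = p0 + seg * ((k + 1) / n_chunks)
        sl = _index_grid(np.minimum(a, b) - margin, np.maximum(a, b) + margin, cov.shape, spacing)
        if sl is None:
            continue
        centers = _bbox_points(sl, spacing)
        pts = centers[:, None, :] + sub[None, :, :]
        rel = pts - p0
        if L2 > 1e-12:
            t = np.clip(np.einsum("nkj,j->nk", rel, seg) / L2, 0.0, 1.0)
            closest = t[..., None] * seg
        else:
            closest = np.zeros_like(rel)
        dist2 = np.sum((rel - closest) ** 2, axis=-1)
        cover = np.mean(dist2 <= radius * radius, axis=1)
        flat = cov[sl].ravel()
        cov[sl] = np.maximum(flat, cover).reshape(cov[sl].shape)


def _paint_tuber(grid, t: Tuber, spacing, mode="blend", out_cov=None) -> None:
    a = max(t.semi_axes_mm) + float(max(spacing))
    shape = grid.shape if mode == "blend" else out_cov.shape
    sl = _index_grid(t.center_mm - a, t.center_mm + a, shape, spacing)
    if sl is None:
        return
    centers = _bbox_points(sl, spacing)
    sub = _SUB * spacing
    pts = centers[:, None, :] + sub[None, :, :] - t.center_mm
    u, v, w = _orthobasis(t.axis_dir)
    lu = np.einsum("nkj,j->nk", pts, u) / t.semi_axes_mm[0]
    lv = np.einsum("nkj,j->nk", pts, v) / t.semi_axes_mm[1]
    lw = np.einsum("nkj,j->nk", pts, w) / t.semi_axes_mm[2]
    inside = lu**2 + lv**2 + lw**2 <= 1.0
    if mode == "max":
        cover = np.mean(inside, axis=1)
        flat = out_cov[sl].ravel()
        out_cov[sl] = np.maximum(flat, cover).reshape(out_cov[sl].shape)
        return
    if t.channel_fraction > 0:
        chan = inside & (np.sqrt(lv**2 + lw**2) <= t.channel_fraction)
        cov_chan = np.mean(chan, axis=1)
        cov_cortex = np.mean(inside & ~chan, axis=1)
        flat = grid[sl].ravel()
        new = cov_chan * t.channel_gray + cov_cortex * t.gray + (1 - cov_chan - cov_cortex) * flat
        grid[sl] = new.reshape(grid[sl].shape)
        return
    cover = np.mean(inside, axis=1)
    flat = grid[sl].ravel()
    grid[sl] = (cover * t.gray + (1 - cover) * flat).reshape(grid[sl].shape)


def _pot_masks(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """(interior mask, wall mask) boolean grids."""
    nz, ny, nx = config.grid_shape
    sz, sy, sx = config.voxel_size_mm
    cy, cx = config.center_mm
    yy = (np.arange(ny) * sy - cy)[:, None]
    xx = (np.arange(nx) * sx - cx)[None, :]
    rad = np.sqrt(yy**2 + xx**2)
    z_mm = np.arange(nz) * sz
    in_depth = (z_mm >= config.surface_mm) & (z_mm < config.bottom_mm)
    wall_depth = (z_mm >= config.surface_mm) & (z_mm < config.bottom_mm + config.pot_wall_mm)
    interior = in_depth[:, None, None] & (rad <= config.interior_radius_mm)[None, :, :]
    shell = (rad > config.interior_radius_mm) & (rad <= config.pot_radius_mm)
    bottom_disk = (z_mm >= config.bottom_mm) & (z_mm < config.bottom_mm + config.pot_wall_mm)
    wall = (wall_depth[:, None, None] & shell[None, :, :]) | (
        bottom_disk[:, None, None] & (rad <= config.pot_radius_mm)[None, :, :]
    )
    return interior, wall


def render_volume(truth: RootSystemTruth, config: PhantomConfig) -> Volume3D:
    """Rasterize a phantom scene into a grayscale volume.

    Soil is a correlated Gaussian gray field inside the pot, the wall a
    bright cylindrical shell with bottom, organs are painted with
    3x3x3-supersampled partial-volume coverage, additive Gaussian noise
    is applied inside the pot, and air outside the pot stays at gray 0.
    """
    config.validate()
    spacing = np.array(config.voxel_size_mm)
    grid = np.zeros(config.grid_shape, dtype=np.float32)
    interior, wall = _pot_masks(config)

    tex_rng = np.random.default_rng([int(config.seed), 201])
    if config.soil_sd > 0:
        noise = tex_rng.standard_normal(config.grid_shape).astype(np.float32)
        field_ = gaussian_filter(noise, sigma=config.texture_corr_vox)
        sd = float(field_.std())
        field_ = field_ / sd * config.soil_sd if sd > 0 else field_
        grid[interior] = config.soil_mean + field_[interior]
    else:
        grid[interior] = config.soil_mean
    grid[wall] = config.wall_gray

    # branches: accumulate coverage per gray value, blend once
    by_gray: dict[float, np.ndarray] = {}
    for b in truth.branches:
        cov = by_gray.setdefault(b.gray, np.zeros(config.grid_shape, dtype=np.float32))
        for p0, p1 in zip(b.points[:-1], b.points[1:]):
            _segment_coverage(cov, p0, p1, b.radius_mm, spacing)
    surf_idx = int(math.ceil(config.surface_mm / config.voxel_size_mm[0]))
    for gray, cov in by_gray.items():
        cov[:surf_idx] = 0.0  # organs live below the soil surface
        touched = cov > 0
        grid[touched] = cov[touched] * gray + (1 - cov[touched]) * grid[touched]
    for t in truth.tubers:
        _paint_tuber(grid, t, spacing)

    if config.noise_sd > 0:
        noise_rng = np.random.default_rng([int(config.seed), 202])
        grid[interior] += noise_rng.normal(0.0, config.noise_sd, size=int(interior.sum())).astype(
            np.float32
        )

    return Volume3D(grid, config.voxel_size_mm)


def truth_mask(truth: RootSystemTruth, config: PhantomConfig) -> np.ndarray:
    """Boolean organ mask: voxels whose supersampled organ coverage >= 0.5."""
    spacing = np.array(config.voxel_size_mm)
    cov = np.zeros(config.grid_shape, dtype=np.float32)
    for b in truth.branches:
        for p0, p1 in zip(b.points[:-1], b.points[1:]):
            _segment_coverage(cov, p0, p1, b.radius_mm, spacing)
    for t in truth.tubers:
        _paint_tuber(cov, t, spacing, mode="max", out_cov=cov)
    cov[: int(math.ceil(config.surface_mm / config.voxel_size_mm[0]))] = 0.0
    return cov >= 0.5


def truth_traits(truth: RootSystemTruth, config: PhantomConfig, weighting: str = "attenuation"):
    """Ground-truth TraitRecord computed analytically from the geometry.

    Density traits come from the configured gray values; the form
    fraction is evaluated on finely sampled organ points via the convex
    hull (the same operational definition the trait module uses).
    """
    from rootct.traits import TraitRecord, _hull_volume

    th_min, th_max, th_mean = truth.theta_stats()
    qd = truth.quantile_depths_mm(weighting=weighting)
    v_root = truth.total_volume_mm3
    # volume-weighted organ gray
    organ_mass = truth.b_total_au()
    root_density = organ_mass / v_root if v_root > 0 else math.nan
    relation = 100.0 * config.soil_mean / root_density if v_root > 0 else math.nan
    pts = _sample_truth_points(truth)
    hull_v = _hull_volume(pts) if len(pts) >= 4 else math.nan
    ff = 100.0 * v_root / hull_v if hull_v and hull_v > 0 else math.nan
    return TraitRecord(
        v_root_mm3=v_root,
        l_root_mm=truth.total_length_mm,
        d25_mm=qd[0],
        d50_mm=qd[1],
        d75_mm=qd[2],
        d90_mm=qd[3],
        form_fraction_pct=ff,
        theta_min_deg=th_min,
        theta_max_deg=th_max,
        theta_mean_deg=th_mean,
        root_density_au=root_density,
        soil_density_au=config.soil_mean,
        soil_root_density_relation_pct=relation,
        b_total_au=organ_mass,
    )


def _sample_truth_points(truth: RootSystemTruth) -> np.ndarray:
    pts: list[np.ndarray] = []
    for b in truth.branches:
        for p0, p1 in zip(b.points[:-1], b.points[1:]):
            seg = p1 - p0
            L = np.linalg.norm(seg)
            n = max(2, int(L))
            t = np.linspace(0, 1, n)[:, None]
            axis_pts = p0 + t * seg
            _, u, v = _orthobasis(seg / L if L > 0 else np.array([1.0, 0, 0]))
            for ang in (0, math.pi / 2, math.pi, 3 * math.pi / 2):
                off = b.radius_mm * (math.cos(ang) * u + math.sin(ang) * v)
                pts.append(axis_pts + off)
    for t_org in truth.tubers:
        u, v, w = _orthobasis(t_org.axis_dir)
        phi = np.linspace(0, 2 * math.pi, 16, endpoint=False)
        theta = np.linspace(0, math.pi, 8)
        P, T = np.meshgrid(phi, theta)
        a, b_, c = t_org.semi_axes_mm
        surf = (
            t_org.center_mm
            + a * (np.cos(T) * np.ones_like(P)).ravel()[:, None] * u
            + b_ * (np.sin(T) * np.cos(P)).ravel()[:, None] * v
            + c * (np.sin(T) * np.sin(P)).ravel()[:, None] * w
        )
        pts.append(surf)
    return np.concatenate(pts) if pts else np.empty((0, 3))


# ---------------------------------------------------------------------------
# growth time series


@dataclass(frozen=True)
class OrganGrowth:
    """Logistic growth parameters for one organ.

    Volume follows ``V(tau) = K / (1 + (K/V0 - 1) exp(-r tau))`` where
    ``tau`` is effective time: real days scaled by the stress factor
    inside the stress window and by ``post_stress_factor`` after it
    (``post_stress_factor=0`` keeps an organ stalled — a "victim").
    ``k_mm3`` is also the organ's rendered full size, so geometry stays
    inside the pot.
    """

    k_mm3: float
    r_per_day: float
    v0_mm3: float
    post_stress_factor: float = 1.0


def logistic_volume(g: OrganGrowth, tau: float) -> float:
    """Closed-form logistic volume at effective time tau (days)."""
    if g.v0_mm3 <= 0:
        return 0.0
    return g.k_mm3 / (1.0 + (g.k_mm3 / g.v0_mm3 - 1.0) * math.exp(-g.r_per_day * tau))


def _effective_time(
    day: float, stress_window: tuple[float, float] | None, stress_factor: float, post_factor: float
) -> float:
    if stress_window is None:
        return day
    d0, d1 = stress_window
    if day <= d0:
        return day
    if day <= d1:
        return d0 + stress_factor * (day - d0)
    return d0 + stress_factor * (d1 - d0) + post_factor * (day - d1)


@dataclass
class DailyScan:
    """One time point of a synthetic growth series."""

    day: int
    truth: RootSystemTruth
    volume: Volume3D | None
    organ_volumes_mm3: dict[str, float]


def render_time_series(
    config: PhantomConfig,
    n_days: int,
    root_growth: OrganGrowth | None = None,
    tuber_growth: Sequence[OrganGrowth] = (),
    stress_window: tuple[float, float] | None = None,
    stress_factor: float = 1.0,
    scan_every_days: int = 2,
    render: bool = False,
) -> list[DailyScan]:
    """Simulate a scanning campaign: organs grow logistically, the
    growth rate is multiplied by ``stress_factor`` inside the stress
    window, and each organ's ``post_stress_factor`` governs whether it
    resumes afterwards. Returns one scan per ``scan_every_days`` days;
    volumes are rendered only when ``render=True`` (truths are always
    recorded).
    """
    if stress_window is not None:
        d0, d1 = stress_window
        if not (0 <= d0 < d1 <= n_days):
            raise ValueError(f"stress window {stress_window} must satisfy 0 <= start < end <= n_days")
    cfg = config if config.n_tubers == len(tuber_growth) else replace(config, n_tubers=len(tuber_growth))
    base = generate_root_system(cfg)
    # normalize the base geometry so each organ's full size equals its K:
    # per-day truth volumes then match the closed-form logistic exactly
    if root_growth is not None and base.branches and base.branch_volume_mm3 > 0:
        s0_root = (root_growth.k_mm3 / base.branch_volume_mm3) ** (1.0 / 3.0)
    else:
        s0_root = 1.0
    s0_tubers = [
        (g.k_mm3 / t.volume_mm3) ** (1.0 / 3.0) if t.volume_mm3 > 0 else 1.0
        for g, t in zip(tuber_growth, base.tubers)
    ]
    base = base.scaled(s0_root, s0_tubers or None)
    scans: list[DailyScan] = []
    for day in range(0, n_days + 1, scan_every_days):
        organ_volumes: dict[str, float] = {}
        if root_growth is not None and base.branches:
            tau = _effective_time(day, stress_window, stress_factor, root_growth.post_stress_factor)
            v = logistic_volume(root_growth, tau)
            s_root = (v / root_growth.k_mm3) ** (1.0 / 3.0)
        else:
            s_root = 1.0
        s_tubers = []
        for i, g in enumerate(tuber_growth):
            tau = _effective_time(day, stress_window, stress_factor, g.post_stress_factor)
            v = logistic_volume(g, tau)
            s_tubers.append((v / g.k_mm3) ** (1.0 / 3.0))
        truth_t = base.scaled(s_root, s_tubers or None)
        if root_growth is not None and base.branches:
            organ_volumes["roots"] = truth_t.branch_volume_mm3
        for i, t_org in enumerate(truth_t.tubers):
            organ_volumes[f"tuber_{i + 1}"] = t_org.volume_mm3
        vol = render_volume(truth_t, cfg) if render else None
        scans.append(DailyScan(day=day, truth=truth_t, volume=vol, organ_volumes_mm3=organ_volumes))
    return scans
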