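"""Root-architecture traits, the virtual-biomass depth profile, and the
dry-weight calibration.

The trait set per scan: total root volume V_root (mm^3), total root
length L_root (mm), root-mass quantile depths d25/d50/d75/d90 (mm below
the soil surface), form fraction F (%), root angles theta_min/max/mean
(degrees from vertical), mean root and soil densities (gray a.u.), the
soil/root density relation factor (%), and the total virtual biomass
B_total (a.u., optionally calibrated to grams).

"Root mass" defaults to attenuation weighting (each voxel weighted by
its gray value, true to the virtual-biomass reading); volume weighting
is available by flag. Undefined traits are NaN, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import linregress

from rootct.segmentation import PotGeometry, RootMask, Skeleton
from rootct.volume_io import Volume3D

__all__ = [
    "TraitRecord",
    "DepthProfile",
    "DryWeightCalibration",
    "root_volume",
    "root_length",
    "quantile_depths",
    "root_angles",
    "density_traits",
    "form_fraction",
    "virtual_biomass_profile",
    "calibrate_dry_weight",
    "compute_all_traits",
]


@dataclass
class TraitRecord:
    """One scan's trait set. NaN marks an undefined trait."""

    plant_id: str | None = None
    timestamp: str | None = None
    v_root_mm3: float = math.nan
    l_root_mm: float = math.nan
    d25_mm: float = math.nan
    d50_mm: float = math.nan
    d75_mm: float = math.nan
    d90_mm: float = math.nan
    form_fraction_pct: float = math.nan
    theta_min_deg: float = math.nan
    theta_max_deg: float = math.nan
    theta_mean_deg: float = math.nan
    root_density_au: float = math.nan
    soil_density_au: float = math.nan
    soil_root_density_relation_pct: float = math.nan
    b_total_au: float = math.nan
    dry_weight_g: float = math.nan

    def to_row(self) -> dict:
        d = asdict(self)
        return {
            "plant_id": d["plant_id"],
            "timestamp": d["timestamp"],
            "V_root_mm3": d["v_root_mm3"],
            "L_root_mm": d["l_root_mm"],
            "d25_mm": d["d25_mm"],
            "d50_mm": d["d50_mm"],
            "d75_mm": d["d75_mm"],
            "d90_mm": d["d90_mm"],
            "form_fraction_pct": d["form_fraction_pct"],
            "theta_min_deg": d["theta_min_deg"],
            "theta_max_deg": d["theta_max_deg"],
            "theta_mean_deg": d["theta_mean_deg"],
            "root_density_au": d["root_density_au"],
            "soil_density_au": d["soil_density_au"],
            "soil_root_density_relation_pct": d["soil_root_density_relation_pct"],
            "B_total_au": d["b_total_au"],
            "dry_weight_g": d["dry_weight_g"],
        }

    def check_invariants(self) -> None:
        qd = [self.d25_mm, self.d50_mm, self.d75_mm, self.d90_mm]
        if all(math.isfinite(q) for q in qd) and not (qd[0] <= qd[1] <= qd[2] <= qd[3] + 1e-9):
            raise ValueError(f"quantile depths not monotone: {qd}")
        th = [self.theta_min_deg, self.theta_mean_deg, self.theta_max_deg]
        if all(math.isfinite(t) for t in th) and not (
            -1e-9 <= th[0] <= th[1] + 1e-9 and th[1] <= th[2] + 1e-9 and th[2] <= 90 + 1e-9
        ):
            raise ValueError(f"root angles out of order: {th}")


@dataclass
class DepthProfile:
    """Depth-binned root volume, mean attenuation, and virtual biomass.

    Bins partition [soil surface, pot bottom]; depths are mm below the
    surface; ``biomass_au`` is mean attenuation x root volume per bin.
    """

    bin_edges_mm: np.ndarray
    volume_mm3: np.ndarray
    mean_attenuation_au: np.ndarray
    biomass_au: np.ndarray

    @property
    def bin_centers_mm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_mm[:-1] + self.bin_edges_mm[1:])

    @property
    def b_total_au(self) -> float:
        return float(self.biomass_au.sum())


def _as_mask(mask: np.ndarray | RootMask) -> np.ndarray:
    return mask.mask if isinstance(mask, RootMask) else np.asarray(mask, dtype=bool)


def root_volume(mask: np.ndarray | RootMask, spacing_mm: Sequence[float]) -> float:
    """Total root volume: voxel count x voxel volume, in mm^3."""
    m = _as_mask(mask)
    return float(m.sum()) * float(np.prod(spacing_mm))


def root_length(skel: Skeleton) -> float:
    """Total root length: sum of skeleton edge lengths after pruning."""
    return skel.total_length_mm


def quantile_depths(
    vol: Volume3D,
    mask: np.ndarray | RootMask,
    pot: PotGeometry,
    quantiles: Sequence[float] = (0.25, 0.5, 0.75, 0.9),
    weighting: str = "attenuation",
) -> list[float]:
    """Root-mass quantile depths below the soil surface.

    Root mass is accumulated slice by slice from the surface downward,
    with per-voxel mass equal to the gray value (attenuation weighting,
    the default) or 1 (volume weighting); the quantile depth is located
    by linear interpolation inside its depth bin. An empty mask yields
    NaN markers, not zeros.
    """
    m = _as_mask(mask)
    if not m.any():
        return [math.nan] * len(quantiles)
    sz = vol.spacing_mm[0]
    if weighting == "attenuation":
        w = np.where(m, vol.voxels, 0.0)
    elif weighting == "volume":
        w = m.astype(np.float64)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    slice_mass = w.reshape(w.shape[0], -1).sum(axis=1).astype(np.float64)
    cum = np.cumsum(slice_mass)
    total = cum[-1]
    if total <= 0:
        return [math.nan] * len(quantiles)
    out = []
    # slice i covers depths [i*sz, (i+1)*sz); cumulative mass at the left
    # edge is cum[i-1]
    for q in quantiles:
        target = q * total
        i = int(np.searchsorted(cum, target))
        i = min(i, len(cum) - 1)
        cum_left = cum[i - 1] if i > 0 else 0.0
        frac = (target - cum_left) / slice_mass[i] if slice_mass[i] > 0 else 0.0
        depth = (i + frac) * sz - pot.surface_depth_mm
        out.append(float(depth))
    return out


def root_angles(
    skel: Skeleton, min_branch_length_mm: float | None = None
) -> tuple[float, float, float]:
    """(theta_min, theta_max, theta_mean) in degrees, 0 = vertical.

    Per-step angles come from the smoothed path tangents; theta_mean is
    the length-weighted mean over all steps; min/max are taken over
    paths longer than ``min_branch_length_mm`` (default: three times the
    median local radius) so single-voxel stubs cannot dominate.
    """
    if skel.is_empty or not skel.paths:
        return (math.nan, math.nan, math.nan)
    if min_branch_length_mm is None:
        med_r = float(np.median(skel.node_radius_mm)) if len(skel.node_radius_mm) else 0.0
        min_branch_length_mm = 3.0 * med_r
    angles_all, weights_all = [], []
    path_means = []
    for p in skel.paths:
        t = p["tangents"]
        w = p["step_lengths_mm"]
        ang = np.degrees(np.arccos(np.clip(np.abs(t[:, 0]), 0.0, 1.0)))
        angles_all.append(ang)
        weights_all.append(w)
        if p["length_mm"] >= min_branch_length_mm and w.sum() > 0:
            path_means.append(float(np.average(ang, weights=w)))
    angles = np.concatenate(angles_all)
    weights = np.concatenate(weights_all)
    if weights.sum() <= 0:
        return (math.nan, math.nan, math.nan)
    mean = float(np.average(angles, weights=weights))
    if path_means:
        tmin, tmax = float(min(path_means)), float(max(path_means))
    else:
        tmin, tmax = float(angles.min()), float(angles.max())
    tmin = min(tmin, mean)
    tmax = max(tmax, mean)
    return (tmin, tmax, mean)


def density_traits(
    vol: Volume3D,
    mask: np.ndarray | RootMask,
    pot: PotGeometry,
    erode_core_vox: int = 1,
    soil_clearance_vox: int = 2,
) -> tuple[float, float, float]:
    """(mean root density, mean soil density, soil/root relation in %).

    Root density is measured over the mask eroded by ``erode_core_vox``
    (falling back to the full mask when erosion empties it) so that
    partial-volume voxels at tube surfaces do not dilute the organ gray
    level. Soil density is the mean gray over the pot interior excluding
    the mask dilated by ``soil_clearance_vox``. The relation factor is
    oriented soil/root x 100.
    """
    m = _as_mask(mask)
    interior = pot.interior_mask
    if not m.any():
        soil = float(vol.voxels[interior].mean()) if interior.any() else math.nan
        return (math.nan, soil, math.nan)
    core = ndimage.binary_erosion(m, iterations=erode_core_vox) if erode_core_vox else m
    if not core.any():
        core = m
    root_mean = float(vol.voxels[core].mean())
    soil_region = interior & ~ndimage.binary_dilation(m, iterations=soil_clearance_vox)
    soil_mean = float(vol.voxels[soil_region].mean()) if soil_region.any() else math.nan
    relation = 100.0 * soil_mean / root_mean if math.isfinite(soil_mean) and root_mean != 0 else math.nan
    return (root_mean, soil_mean, relation)


def _hull_volume(points_mm: np.ndarray) -> float:
    try:
        return float(ConvexHull(points_mm).volume)
    except (QhullError, ValueError):
        return math.nan


def form_fraction(mask: np.ndarray | RootMask, spacing_mm: Sequence[float]) -> float:
    """Form fraction F: 100 x V_root / V_convex_hull of the mask.

    This is the toolkit's operational definition of the compactness
    descriptor: a solid blob scores near 100%, a sparse pot-spanning
    system scores low. NaN for degenerate (near-coplanar) masks.
    """
    m = _as_mask(mask)
    coords = np.argwhere(m)
    if len(coords) < 4:
        return math.nan
    # hull the corners of the surface voxels (centers alone collapse
    # one-voxel-thin structures to a degenerate hull)
    surface = m & ~ndimage.binary_erosion(m)
    scoords = np.argwhere(surface if surface.any() else m).astype(float)
    offsets = np.array(
        [(dz, dy, dx) for dz in (-0.5, 0.5) for dy in (-0.5, 0.5) for dx in (-0.5, 0.5)]
    )
    corners = (scoords[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    pts = corners * np.asarray(spacing_mm, dtype=float)
    hull_v = _hull_volume(pts)
    if not math.isfinite(hull_v) or hull_v <= 0:
        return math.nan
    return 100.0 * root_volume(m, spacing_mm) / hull_v


def virtual_biomass_profile(
    vol: Volume3D,
    mask: np.ndarray | RootMask,
    pot: PotGeometry,
    bin_height_mm: float = 5.0,
) -> DepthProfile:
    """Virtual biomass as a function of pot depth.

    Per depth bin, B(d) = mean root attenuation x root volume in the
    bin — equivalently the sum over root voxels of gray x voxel volume —
    in arbitrary units (gray values are not normalized to a physical
    density). Bins of ``bin_height_mm`` partition [surface, bottom].
    """
    sz = vol.spacing_mm[0]
    if bin_height_mm < sz:
        raise ValueError(f"bin height {bin_height_mm} mm is below one voxel ({sz} mm)")
    m = _as_mask(mask)
    voxel_mm3 = vol.voxel_volume_mm3
    span = pot.bottom_depth_mm - pot.surface_depth_mm
    n_bins = max(1, int(math.ceil(span / bin_height_mm)))
    edges = pot.surface_depth_mm + np.arange(n_bins + 1) * bin_height_mm
    idx = np.argwhere(m)
    vol_bins = np.zeros(n_bins)
    mass_bins = np.zeros(n_bins)
    if len(idx):
        depths = idx[:, 0] * sz
        grays = vol.voxels[tuple(idx.T)].astype(np.float64)
        which = np.clip(((depths - pot.surface_depth_mm) // bin_height_mm).astype(int), 0, n_bins - 1)
        np.add.at(vol_bins, which, voxel_mm3)
        np.add.at(mass_bins, which, grays * voxel_mm3)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_att = np.where(vol_bins > 0, mass_bins / vol_bins, 0.0)
    return DepthProfile(
        bin_edges_mm=edges - pot.surface_depth_mm,
        volume_mm3=vol_bins,
        mean_attenuation_au=mean_att,
        biomass_au=mass_bins,
    )


@dataclass
class DryWeightCalibration:
    """Linear map from virtual biomass (a.u.) to dry weight (g)."""

    slope: float
    intercept: float
    r_squared: float

    def apply(self, b_total_au: float) -> float:
        return self.slope * b_total_au + self.intercept


def calibrate_dry_weight(pairs: Sequence[tuple[float, float]]) -> DryWeightCalibration:
    """Ordinary least squares of measured dry weight (g) on virtual
    biomass (a.u.) from sampled reference plants.

    Requires at least 3 pairs with non-degenerate biomass spread.
    """
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 (B_total, dry weight) pairs, got {len(pairs)}")
    b = np.array([p[0] for p in pairs], dtype=float)
    w = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(b) == 0 or b.std() == 0:
        raise ValueError("virtual biomass values have zero spread; calibration is degenerate")
    fit = linregress(b, w)
    return DryWeightCalibration(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


@dataclass
class TraitOptions:
    """Knobs for trait computation."""

    weighting: str = "attenuation"  # root-mass weighting for quantiles
    bin_height_mm: float = 5.0
    erode_core_vox: int = 1
    calibration: DryWeightCalibration | None = None


def compute_all_traits(
    vol: Volume3D,
    mask: np.ndarray | RootMask,
    skel: Skeleton,
    pot: PotGeometry,
    options: TraitOptions | None = None,
    plant_id: str | None = None,
    timestamp: str | None = None,
) -> TraitRecord:
    """Fill every trait field from a volume + mask + skeleton.

    Degenerate inputs yield NaN markers, never silent zeros; an empty
    mask still reports V_root = 0 (a true measurement).
    """
    options = options or TraitOptions()
    m = _as_mask(mask)
    if m.shape != vol.shape:
        raise ValueError(f"mask grid {m.shape} does not match volume grid {vol.shape}")
    rec = TraitRecord(plant_id=plant_id, timestamp=timestamp)
    rec.v_root_mm3 = root_volume(m, vol.spacing_mm)
    rec.l_root_mm = root_length(skel) if not skel.is_empty else (0.0 if m.any() else math.nan)
    if m.any():
        qd = quantile_depths(vol, m, pot, weighting=options.weighting)
        rec.d25_mm, rec.d50_mm, rec.d75_mm, rec.d90_mm = qd
        rec.form_fraction_pct = form_fraction(m, vol.spacing_mm)
        profile = virtual_biomass_profile(vol, m, pot, options.bin_height_mm)
        rec.b_total_au = profile.b_total_au
        if options.calibration is not None:
            rec.dry_weight_g = options.calibration.apply(rec.b_total_au)
    rec.theta_min_deg, rec.theta_max_deg, rec.theta_mean_deg = root_angles(skel)
    rec.root_density_au, rec.soil_density_au, rec.soil_root_density_relation_pct = density_traits(
        vol, m, pot, erode_core_vox=options.erode_core_vox
    )
    rec.check_invariants()
    return rec
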