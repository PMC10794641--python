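# Methods

This note documents the models, numerical choices, and defaults behind
`rootct`, and what the synthetic validation does and does not show
about real CT data.

## Conventions

Volumes are `(z, y, x)` arrays with axis 0 the depth axis; voxel `i`
sits at `depth_mm = i × spacing`. Index 0 is the top of the scan (air
above the soil surface). Gray values are attenuation in arbitrary
units — they correlate with material density but are not normalized to
a physical scale, which is why the virtual biomass is reported in a.u.
unless calibrated. Timestamps are ISO-8601, UTC assumed when no zone is
given; CSV output is locale-independent.

## Synthetic phantom

The phantom emulates a cylindrical pot (default 70 mm radius, 150 mm
height, 3 mm bright wall) filled with textured soil, scanned at
desk-scale resolution (160³ voxels, 1 mm edge; production root scanners
work at ~75 µm, so the default grid is a scaled stand-in that keeps the
whole test suite within minutes on one CPU).

* **Root system** — recursive branching from a single stem entering at
  the soil-surface center: each level spawns `n_branches` straight
  segments (default 2 levels × 2 branches) deflected by an insertion
  angle drawn from 20–50°, lengths 30–60 mm, radii tapering 3.5→2 mm.
  Geometry is clipped to the pot interior. Every derived truth (length,
  frustum volume, insertion angles, mass-depth distribution) is
  computed analytically from the polylines, so the generator is an
  oracle, not a fixture.
* **Tubers / storage roots** — ellipsoids with an optional coaxial
  low-density channel occupying a configurable fraction (default 0.4 of
  the cross-sectional radius when enabled) at 0.6× the cortex gray, the
  structural signature that distinguishes storage from fiber roots.
* **Soil texture** — a correlated Gaussian gray field (σ=5 a.u.,
  correlation length 3 voxels). Flat soil would make thresholding
  degenerate; correlated texture keeps segmentation honest.
* **Rasterization** — each organ voxel's value is the coverage-weighted
  blend of organ and soil gray, with coverage from 3×3×3 subvoxel
  supersampling; long segments are processed in short chunks with
  distances always measured to the full segment, so chunking does not
  change the result. Organ coverage is clipped below the soil surface.
* **Noise** — additive Gaussian (default σ=10 a.u.) inside the pot;
  air outside stays at 0. With the default 50 a.u. root/soil contrast
  the contrast-to-noise ratio is 5.
* **Determinism** — all randomness derives from `(seed, role)` child
  streams of one seed; equal config + seed gives bit-identical volumes.

What the phantom does **not** emulate: beam hardening, ring artifacts,
scatter, moisture gradients, root/soil contact contrast loss, or real
soil heterogeneity. Passing recovery tests therefore demonstrates the
correctness of the measurement chain, not field-ready segmentation
accuracy on arbitrary substrates.

### Growth time series

Each organ follows logistic growth `V(τ) = K / (1 + (K/V₀ − 1)e^{−rτ})`
where τ is *effective* time: real days are multiplied by the stress
factor inside the stress window (0 = fully frozen) and by a per-organ
`post_stress_factor` after it. `post_stress_factor = 0` produces a
"victim" organ that never resumes. The base geometry is normalized so
each organ's rendered full size equals its K, hence recorded truth
volumes match the closed form exactly and the series stays inside the
pot.

## Segmentation

**Pot detection** fits the cylinder from the depth-averaged slice
(centroid and area of the bright footprint against near-zero air), then
locates the soil surface and bottom from the in-cylinder axial gray
profile (0.5–1.6× the median soil level). All traits are restricted to
the resulting interior mask.

**Root segmentation** is a vesselness pipeline with every threshold in
`RootSegParams`:

1. robust normalization inside the pot (median/MAD z-scores), sign
   flipped if roots are configured darker than soil;
2. a contrast gate: under pure Gaussian soil+noise the fraction of
   voxels above 4σ equals the normal survival function (~3.2 × 10⁻⁵);
   if the observed tail is below 5× that, the scan is declared
   contrast-free and an **empty mask with a warning status** is
   returned rather than noise dressed up as roots;
3. multiscale Hessian vesselness (scales 1 and 2 mm). The Hessian is
   built from Gaussian derivative filters, scale-normalized by σ²; a
   voxel responds with √(e₁e₂) when its two most negative eigenvalues
   are both negative. Eigenvalues come from a closed-form trigonometric
   solver for symmetric 3×3 matrices, fully vectorized — per-voxel
   LAPACK calls are orders of magnitude too slow at volume scale;
4. hysteresis thresholding at the 0.9995 / 0.998 quantiles of the
   in-pot response;
5. retention of components connected (within a 2-voxel dilation, to
   bridge partial-volume breaks in thin roots) to a seed disk at the
   soil-surface center where the stem enters;
6. boundary refinement: vesselness under-represents junctions and the
   tube surface, so the kept voxels are grown by the gap tolerance and
   re-thresholded at half the detected root z-level — approximately the
   50 % partial-volume surface, which is the voxelization that matches
   the analytic organ volume;
7. removal of components below 100 mm³.

**Tuber segmentation** thresholds inside the pot ("midpoint" default:
soil median + half the distance to the 99.9th percentile — Otsu is
available but degenerates when tubers occupy <1 % of the pot), applies
a 1-voxel morphological opening, labels 26-connected components, and
drops labels below 500 mm³. Labels are renumbered by decreasing volume
for deterministic output.

**Label matching** across re-scans aligns the overall foreground
centroids, then assigns greedily by voxel overlap; ties break by larger
overlap, then smaller centroid distance, then lower label id. Unmatched
labels are reported as lost/new rather than guessed.

**Skeletonization** thins the mask to 1-voxel center lines
(3D thinning; a shift-intersect fallback handles the degenerate case
where perfectly mirror-symmetric objects vanish under thinning), builds
the 26-connectivity voxel graph with anisotropy-aware step weights
(1, √2, √3 × spacing), and takes its minimum spanning forest — for a
tubular object this is exactly the center-line path set. Leaf branches
shorter than 4× the local radius (distance-transform estimate) are
pruned as spurs. Center-line runs between junctions are smoothed with a
5-point moving average (endpoints pinned) before measuring length —
raw voxel stairsteps otherwise inflate arc length by several percent —
and local tangents are chords over a ±7-step window, which suppresses
the upward bias that voxel-scale wiggle induces in angle estimates.

**Low-density channel**: the organ's principal axis comes from the
PCA of its labeled voxels; organs with elongation < 1.5 are
"not assessable". Twelve cross-sections over the central 80 % of the
axis are sampled **from the full volume** within the per-section radius
(95th percentile of labeled-voxel radii) — the channel itself usually
falls below the segmentation threshold and would be invisible if only
labeled voxels were sampled. A section votes "channel" when the mean
gray of the core (relative radius ≤ 0.3) is < 0.8× the cortex annulus
(0.5–0.95); the organ is channel-positive when ≥ 60 % of sections vote.

## Traits

* **Quantile depths** accumulate root mass slice by slice from the soil
  surface downward and interpolate linearly inside the crossing bin.
  Mass defaults to attenuation weighting (per-voxel gray), consistent
  with the virtual-biomass reading of "root mass"; volume weighting is
  a flag. A uniform stem over 0–160 mm yields exactly
  (40, 80, 120, 144) mm.
* **Angles** use 0° = vertical (the gravitropic axis); θ_mean is the
  length-weighted mean over all skeleton steps; θ_min/θ_max are taken
  over per-path means of paths longer than the pruning length so
  single-voxel stubs cannot set the extremes.
* **Density traits**: root density is measured over the 1-voxel-eroded
  mask core (falling back to the full mask when erosion empties it) —
  at millimetre voxels a large fraction of tube voxels are
  partial-volume boundary voxels whose blended gray would bias the
  organ density toward soil by ~10 %. Soil density excludes a 2-voxel
  dilation of the mask. The relation factor is oriented soil/root ×
  100, as recorded in the CSV header.
* **Form fraction** is implementation-defined here as 100 × V_root over
  the volume of the convex hull of the mask's surface-voxel corners
  (corners, not centers — center hulls collapse one-voxel-thin
  structures). A compact organ scores ≈100 %; spread-out architectures
  score low.
* **Virtual biomass** per 5 mm depth bin is Σ gray × voxel volume over
  root voxels in the bin, identical to mean attenuation × bin volume;
  B_total is its sum and is conserved against the direct voxel sum to
  1e-9 relative (float64 accumulation).
* **Dry-weight calibration** is ordinary least squares of measured dry
  weight on B_total, requiring ≥ 3 reference pairs with nonzero spread;
  slope/intercept/R² are reported and the mapping is optionally applied
  to trait records.
* Undefined traits are NaN in memory and empty cells in CSV — never 0.

## Kinetics

Growth rates are raw forward finite differences over observed days (no
smoothing, by design; smoothing choices belong downstream). Intervals
spanning a missing observation are flagged. Phase rates (pre / during /
post stress) average the intervals whose midpoints fall in the phase.
The stress classes are this toolkit's operational definitions, with the
threshold ρ (default 0.5) exposed in config: *resumed* if
rate_post ≥ ρ·rate_pre; *stalled* if positive but below that; *victim*
if rate_post ≤ 0 while the plant-level total post-stress rate is
positive. Days are relative to sowing when the manifest provides a
sowing date, else to the first scan.

## Pipeline

The batch runner executes detect-pot → segment → skeletonize → traits
per scan and kinetics per plant, sequentially in one process. Every
step appends a record (status pending→running→done/failed, input/output
SHA-256 prefixes) to an append-only JSON-lines ledger; status
transitions are forward-only. A failing scan is recorded and skipped —
the batch never aborts on one bad volume — and re-runs on unchanged
inputs are byte-identical. Config files are validated against the
parameter dataclasses before any processing; unknown keys at any level
are rejected.

## Validation problem sizes

The recovery benchmark uses 20 phantoms at 160³ × 1 mm and CNR 5 (the
generator defaults). Observed medians: V_root and L_root relative error
well under 10 %, quantile depths within one voxel of the brute-force
prefix-sum oracle, θ_mean within 3°, density relation within 5 % —
these are the bounds asserted by the acceptance suite, each computed at
run time, never stored. Unit tests use coarser grids (64³–96³) where
the property under test does not depend on resolution.

## Known limitations

* Lateral roots thinner than ~2 voxels are not recovered — they are at
  or below the resolution limit of the volumes this pipeline targets.
* The skeleton shortens slightly at tips (thinning retracts by roughly
  one radius) and through junctions; spur pruning compensates on
  average but individual branch lengths carry a few percent bias.
* The channel criterion assumes a roughly straight organ; strongly
  curved storage roots would need curved-axis resampling.
* Label matching assumes the pot is re-scanned in a similar pose; it
  compensates global translation only, not rotation.
* Form fraction and the relation-factor orientation are operational
  definitions of this toolkit, documented above and in the CSV headers.
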