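# rootct

Non-destructive root phenotyping from X-ray CT. `rootct` takes
reconstructed grayscale CT volumes of soil-filled plant pots — the kind
produced by automated scanning facilities that image potato, cassava, or
maize roots every other day for weeks — and turns them into standardized
root-architecture traits, depth-resolved virtual-biomass profiles, and
per-organ growth kinetics under stress. A ground-truthed synthetic
phantom generator makes the entire measurement chain testable with no
scanner and no data download.

It is written for plant scientists and breeders who already have
reconstructed volumes (MHD/RAW or TIFF stacks) and need objective,
reproducible below-ground traits, and for image-analysis developers who
want a benchmarkable reference pipeline.

## What it computes

Per scan, from a volume plus a segmented root mask:

| trait | unit | definition |
|---|---|---|
| V_root | mm³ | voxel count × voxel volume of the root mask |
| L_root | mm | total center-line length of the 3D skeleton |
| d25, d50, d75, d90 | mm | root-mass quantile depths below the soil surface (attenuation-weighted by default) |
| F | % | form fraction: 100 · V_root / V(convex hull of the mask) |
| θ_min, θ_max, θ_mean | ° | root angles from the vertical axis (0° = vertical), length-weighted mean |
| root / soil density | a.u. | mean gray value of root core / surrounding soil |
| relation factor | % | 100 · soil density / root density |
| B_total | a.u. | total virtual biomass Σ gray × voxel volume over root voxels |

The virtual biomass as a function of depth d is

```
B(d) = mean root attenuation in bin(d) × root volume in bin(d)
```

in arbitrary units, optionally calibrated to dry weight (grams) by
ordinary least squares against sampled reference plants. Storage roots
are distinguished from fiber roots by an internal low-density channel:
cross-sections perpendicular to the organ's principal axis are
channel-positive when the core/cortex gray ratio falls below 0.8 in at
least 60 % of sections.

Time series of scans yield per-organ growth rates (forward finite
differences, units/day) and a stress-response class per organ —
`resumed`, `stalled`, or `victim` (an organ that never restarts after a
stress window while its siblings on the same plant do).

## Worked example

Generate a phantom pot (160³ voxels at 1 mm; a 70 mm-radius pot with a
stochastic two-level branching root system at contrast-to-noise 5),
then measure it:

```python
from rootct.phantom import PhantomConfig, generate_root_system, render_volume, truth_traits
from rootct.segmentation import detect_pot, segment_roots, skeletonize
from rootct.traits import compute_all_traits

cfg = PhantomConfig(seed=4)
truth = generate_root_system(cfg)       # analytic ground truth
vol = render_volume(truth, cfg)         # grayscale CT-like volume

pot = detect_pot(vol)
mask = segment_roots(vol, pot)
skel = skeletonize(mask)
rec = compute_all_traits(vol, mask, skel, pot)

want = truth_traits(truth, cfg)
print(f"V_root {rec.v_root_mm3:.0f} mm^3 (truth {want.v_root_mm3:.0f})")
print(f"L_root {rec.l_root_mm:.0f} mm   (truth {want.l_root_mm:.0f})")
print(f"theta_mean {rec.theta_mean_deg:.1f} deg (truth {want.theta_mean_deg:.1f})")
print(f"d50 {rec.d50_mm:.1f} mm (truth {want.d50_mm:.1f})")
```

prints

```
V_root 6407 mm^3 (truth 6446)
L_root 301 mm   (truth 309)
theta_mean 30.5 deg (truth 29.5)
d50 75.8 mm (truth 74.6)
```

i.e. volume and length within a few percent of the generating geometry,
the mean insertion angle within one degree, and the median root-mass
depth within about one voxel.

The same chain runs from the shell:

```bash
rootct phantom --seed 4 --out demo/          # volume + truth JSON
rootct segment --in demo/phantom.mhd --out demo/mask.mhd --mode roots
rootct traits --in demo/phantom.mhd --out demo/traits.csv
rootct plan 6 3 42                            # -> total scans: 756
rootct run --config pipeline.yaml             # manifest-driven batch run
```

A batch run writes `traits.csv`, `rates.csv`, and an append-only
JSON-lines job ledger with one status record per processing step per
scan; a failing scan is isolated and the rest of the batch continues.

## Scope

The toolkit consumes reconstructed volumes: scanner control, CT
reconstruction, and raw-projection artifact corrections are out of
scope, as are machine-learned segmentation and recovery of lateral
roots below about two voxels radius (at or below the resolution limit
of desk-scale volumes). See `docs/methods.md` for the model and
parameter choices.
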