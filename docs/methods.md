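# Methods

`pcleval` evaluates instance-level detection of pancreatic cystic lesions
(PCLs) on CT. This note records the model behind each stage, the parameters
that matter, the design choices made where more than one reasonable option
existed, and what the synthetic phantoms do and do not demonstrate.

## Coordinate conventions

Voxel indices are 0-based `(i, j, k)`; world coordinates are millimetres in
RAS+ (`+x` right, `+y` anterior, `+z` superior). Images are reoriented to the
closest canonical frame on load, and the last axis is the axial/slice axis.
Voxel spacing equality between grids is tested at relative tolerance 1e-4
(header round-off); write→read round-trips preserve labels exactly and
spacing to better than 1e-6 mm.

## Synthetic phantom

The generator emulates the geometry that drives the evaluation, not the
appearance of a real abdomen:

- **Parenchyma**: a curved tube along a polyline (default ~108 mm long,
  the length scale of a human pancreas), radius tapering 13 → 9 mm from the
  head (patient's right, larger `x`) to the tail, at 50 HU in a fat-like
  −80 HU background.
- **Main pancreatic duct**: a coaxial tube (default radius 1 mm, ~5 HU)
  along the same centerline. Duct truth voxels swallowed by a cyst belong to
  the cyst, so every truth voxel carries exactly one pre-noise HU value.
- **Cysts**: spheres/ellipsoids voxelized by voxel-center inclusion
  (the same rule used for reader spheres), hypodense at 10 HU by default.
  The realized volume — voxel count × voxel volume — is catalogued as ground
  truth and differs from the target volume by at most the surface-voxel
  error of voxelization. Cysts must fit inside the local tube radius and may
  never overlap; violations raise a placement error naming the cyst.
- **Confounders**: optional blobs or duct-like short tubes outside the
  parenchyma, mimicking the structures (bile duct, choledochal cyst,
  duodenal diverticula) that confound detectors near the pancreatic head.
- **Noise**: additive Gaussian only (`noise_sigma_hu`, 10 HU is a realistic
  magnitude for portal-venous abdominal CT). No beam hardening, streaks,
  texture, or contrast-phase variation are simulated.

Identical spec + seed gives bit-identical output (one `numpy` generator,
seed recorded in the truth object). `place_volume_groups` draws target
volumes uniformly within the four evaluation volume groups — 10–50, >50–200,
>200–600, >600 mm³, capped at 5000 mm³ for the open-ended group — and spreads
cysts largest-first along the centerline with clearance so no two voxelized
instances touch under 26-connectivity.

Because the phantoms are geometrically ideal (sharp boundaries, homogeneous
parenchyma, spherical lesions), passing the end-to-end checks demonstrates
correctness of the *evaluation machinery* — cropping, instance extraction,
matching, stratification, regional attribution — not clinical detection
performance on real CT.

## Candidate detector (surrogate)

The detection stage in the studied design is a trained segmentation network;
here a transparent classical surrogate produces the identical interface (a
binary candidate mask aligned to the CT) so the evaluation pipeline runs at
desk scale and real model output can be substituted directly.

The surrogate is a hysteresis segmentation inside the organ:

1. Restrict to the pancreas mask dilated by `pancreas_dilation_mm`
   (default 2 mm, to retain exophytic lesions at the organ surface).
2. *Seeds*: voxels whose Gaussian-smoothed HU (`smoothing_radius_mm`,
   default 1 mm) falls in the cyst window `[hu_low, hu_high]`
   (defaults −20 to +25 HU, bracketing fluid against enhancing parenchyma).
   Smoothing makes seeds robust to noise but erodes lesion boundaries.
3. *Extent*: 26-connected components of voxels whose **raw** HU falls in the
   same window; a component is kept iff it contains a seed. This recovers
   the sharp boundary the smoothing eroded, and simultaneously suppresses
   the partial-volume shell at the organ surface (where smoothing drags the
   parenchyma→background transition through the window but raw values never
   sit inside it).
4. Remove duct voxels when `suppress_duct` (the analogue of training the
   duct as a separate class), then drop components under `min_volume_mm3`
   (default 10 mm³, mirroring the ground-truth exclusion floor).

A 1 mm-radius duct is below the resolving power of the 1 mm smoothing (its
smoothed core stays above the window), so duct-confusion behaviour is
exercised with a pathologically dilated 2.5 mm duct.

Organ cropping keeps the axial slices spanning the organ's nonzero extent
(± an optional slice margin) and reports the slice range for mapping results
back; an empty organ mask raises a "segmentation failed" error, mirroring
first-stage failures in a two-step system.

## Instance extraction and matching

- Connectivity is 26-neighbourhood in 3D (standard for blob-like lesions).
- Instances are id'd in descending volume, ties broken by lexicographic
  centroid, so numbering is independent of scan order.
- Matching computes all pairwise DSCs and accepts pairs greedily in
  descending DSC (ties: smaller GT id, then smaller prediction id) subject
  to one-to-one use and DSC ≥ threshold (0.30 for model evaluation, 0.10 for
  reader spheres). Greedy matching is deterministic and order-independent;
  on configurations whose DSC matrix has at most one above-threshold entry
  per row and column it equals the exhaustive optimum (verified against
  brute-force enumeration in the tests).
- GT lesions under the 10 mm³ floor are *excluded*: they are neither FN nor
  matchable, and predictions whose only above-threshold overlap is with
  excluded GT are dropped rather than counted as FP — penalizing the
  detection of a lesion that evaluation deliberately ignores would be
  inconsistent.
- A false positive is attributed to the main pancreatic duct when strictly
  more than 50% of its voxels lie on duct labels. The >50% rule is this
  package's operationalization; percentages are reported to one decimal.

## Equal-volume regions along the centerline

1. 3D thinning skeleton of the pancreas mask (largest 26-connected
   component, with a warning, if disconnected).
2. Longest geodesic path through the skeleton graph (edges weighted by
   physical distance; endpoints found by a double Dijkstra sweep).
3. Moving-average smoothing (window 5) and tangent extrapolation of both
   ends to the mask boundary — thinning retracts from blunt tube ends by
   roughly one radius, and the extension restores full arc-length coverage.
4. Orientation: the proximal end (head + uncinate) is the endpoint with the
   larger RAS `x` (the head lies to the patient's right); overridable.
5. Every pancreas voxel gets the arc length of its nearest centerline point;
   the two cuts are placed at the arc lengths whose cumulative voxel volume
   is closest to 1/3 and 2/3 of the total. On phantom-like masks the three
   regions balance to well within 2% of total/3 (0.2% typical).

Lesion→region attribution uses the plurality of lesion voxels; exophytic
voxels outside the parenchyma are mapped through their nearest centerline
arc length; exact ties break toward the more proximal region. Equal
parenchyma *volume* per region is the implemented definition; equal arc
length would differ on tapering organs and is deliberately not the default.

## Reader protocol

An annotation is the lesion's greatest linear diameter (two world-mm
endpoints); the sphere is centered at the segment midpoint with radius =
half the diameter, voxelized by voxel-center inclusion (a sub-voxel diameter
still marks the voxel containing the center). Spheres are matched to GT
instances with the same one-to-one greedy matcher at DSC ≥ 0.10; per reader,
sensitivity = matched GT / all GT and FPs/case = unmatched spheres / cases.
The annotation CSV format is
`case_id, reader_id, x1_mm, y1_mm, z1_mm, x2_mm, y2_mm, z2_mm`.

A seeded synthetic reader annotates each catalogued cyst's
volume-equivalent diameter with Gaussian center jitter (default σ 0.5 mm),
relative diameter error (default σ 5%), and a per-lesion miss probability;
it generates no spurious annotations, so recovered sensitivity isolates the
miss rate.

## Metrics and statistics

- TP/FN are stratified by the ground-truth instance's volume group or
  region; FP by the predicted instance's. How FPs enter GT-volume strata is
  not uniquely defined by the evaluation design; stratifying FPs by their
  own (predicted) volume is this package's choice and is the main divergence
  risk when comparing against other implementations.
- Undefined ratios (empty strata) are reported as NaN, never coerced to 0.
- Cumulative curves at threshold v use GT instances ≥ v for sensitivity and
  predicted FP instances ≥ v for the FP rate; at the 10 mm³ floor they
  reproduce the unstratified metrics exactly. Sensitivity need not be
  monotone in v and is not assumed to be.
- Paired t-test on per-case counts (two-sided); zero-variance differences
  are flagged degenerate instead of producing an infinite statistic.
  Chi-square on the 3×2 regional detected/missed table is Pearson's without
  continuity correction, df = 2, with a small-sample warning when any
  expected cell < 1. McNemar's statistic is the continuity-corrected
  (|b−c|−1)²/(b+c); its p-value uses the exact two-sided binomial when
  b+c < 25. p-values are reported unadjusted.

## Problem sizes

Phantom-based checks run on 120×120×72 grids at 1 mm isotropic spacing (the
regime where the surrogate detector resolves the smallest evaluated volume
group) or 144×144×48 at 0.8×0.8×1.5 mm for anisotropic coverage. The
parameter-recovery experiment uses 20 phantoms with 8 cysts each (3+3+1+1
per volume group), an injected miss probability of 0.3 for lesions under
200 mm³ and 2 spurious blobs per case; recovery is asserted within 3
binomial standard errors. The reader simulation uses 10 phantoms × 4 cysts
at miss probability 0.25.

## Known limitations

- The surrogate detector is an evaluation harness, not a detection method:
  it exploits the phantom's piecewise-constant HU model and would not
  transfer to real CT; its numbers say nothing about network performance.
- Phantoms lack texture, artifacts, partial-volume blur at acquisition, and
  anatomically realistic neighbours; confounders are geometric stand-ins.
- The centerline orientation heuristic (head = larger RAS x) assumes
  roughly anatomical positioning; use the override for unusual geometry.
- Matching is per-instance: a single prediction covering two GT lesions can
  match only one (the other stays FN), and predictions are never compared
  against the union of the GT.
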