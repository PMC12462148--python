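# Methods

## Problem setting

Pre-TAVR cardiac CT analysis needs two geometric quantities per scan: a 3D
bounding box around the aortic root, and the acute angle between the root's
central axis and the axial (horizontal) plane. The detection step is a
learned component and is out of scope here; this package implements the
deterministic stages around it — coordinate handling, detection scoring, the
tilt-alignment algorithm, agreement statistics — and a phantom simulator
that provides ground truth for all of them.

## Coordinate conventions

Voxel indices are 0-based and boxes are half-open `[lo, hi)`, so a box with
integer corners covers exactly `prod(hi - lo)` voxels and voxel-count
oracles are exact. World coordinates follow the NIfTI affine: `world =
A @ [i, j, k, 1]`. Annotation tools disagree about LPS vs RAS, so boxes
carry an explicit `space` tag and conversion re-sorts the two transformed
corners per axis; under axis-aligned affines (scales, flips, permutations —
the realistic NIfTI family) box round trips are exact, while under general
rotations a transformed axis-aligned box is only represented by its
axis-aligned hull (boxes here are annotations, not oriented geometry).

The normalized text dialect stores fractions of the axis length in
depth-first `(z, x, y)` column order, matching 3D YOLO-style label files.
Fractional voxel corners are kept as reals; rasterization (floor of `lo`,
ceil of `hi`) happens only where a voxel mask is actually needed.

## Preprocessing

`normalize_intensity` applies `(v + 1024) / 2048` and clips to [0, 1].
Clipping is a deliberate addition: the affine map alone sends dense calcium
and metal (> 1024 HU) above 1, and detector preprocessing conventionally
saturates; it is exposed as `clip=True`. Re-normalizing a normalized volume
raises, preventing a silent double application.

`resize_cubic` resamples to an isotropic cube (default edge 350, the 3D
detector input convention). The stated requirement — resample the grid yet
"keep" voxel geometry — is contradictory for anisotropic inputs, so the
implementation standardizes on grid resampling with an affine update.
Sampling is corner-aligned (`align_corners` in resampling parlance): output
index `i` maps to source index `i·(n−1)/(edge−1)`. This makes resizing to
the source shape a bit-exact no-op, reproduces any trilinear field exactly
(a linear ramp stays a linear ramp to < 1e-6), and preserves the world-space
hull of voxel centers exactly, with the affine's spatial columns rescaled by
`(n−1)/(edge−1)`. Interpolation is trilinear with edge-value extension;
nearest-neighbor is available for label masks. Single-slice axes keep scale
1 so the affine stays invertible.

## Tilt alignment

Four stages, each independently exposed:

1. **Threshold** (`threshold_mask`): binary mask of ROI voxels ≥ the
   threshold. Default 200 HU — contrast-enhanced lumen is typically 300–500
   HU and myocardium 40–80 HU, so 200 splits the two with margin; when the
   volume is normalized the threshold is mapped to (200+1024)/2048 ≈ 0.598
   automatically. An empty mask is not an error at this stage.
2. **Largest connected component** (`largest_component`): scipy.ndimage
   labeling at 26-connectivity by default (the most permissive neighborhood,
   keeping thin contrast columns intact; 6 and 18 available). Size ties are
   broken toward the component whose first voxel in raster order is
   lexicographically smallest, which matches label-id order and is
   deterministic. An empty input raises `EmptySelectionError` carrying the
   threshold — the signal that it was set too high. Components below
   `min_component_voxels` (default 50) are rejected as specks.
3. **Principal axis** (`principal_axis`): PCA of the voxel-center point
   cloud (`index + 0.5`, mapped through the affine to millimetres), i.e. the
   leading eigenvector of the covariance. Working in mm rather than index
   space keeps the axis physically meaningful under anisotropic voxels.
   Points are unweighted by default; `intensity_weighted=True` weights the
   covariance by voxel intensity. Fewer than 3 voxels or a rank-0 cloud is
   degenerate; a tie within 1e-9 between the two leading eigenvalues raises
   `AmbiguousAxisError` rather than guessing an arbitrary direction. The
   axis sign is normalized so the superior (world z) component is ≥ 0, else
   the first nonzero component is made positive.
4. **Angle** (`tilt_angle`): default convention is the 3D elevation above
   the axial plane, `arcsin(|a_z|)` in degrees — acute by construction and
   invariant to rotation within the axial plane. The alternative
   `coronal_projection` convention, `arctan(|a_z| / |a_x|)` on the coronal
   projection as used by earlier 2D approaches, is available via
   `TiltConfig(convention=...)`.

The composed `align_tilt` reports the axis, angle, component size, the
threshold actually used and the component's world centroid; stage failures
carry a `stage` label (`threshold` / `component` / `pca`).

A known systematic effect, deliberately **not** corrected: an axis fitted to
the whole contrast-filled lumen follows the proximal ascending aorta's
curvature, whereas a manual angle referenced to the annular plane does not,
so automated estimates carry a bias on real anatomy. The phantom's
`curvature_radius_mm` option exists to probe this mechanism; no correction
term is applied.

## Detection evaluation

IoU is the ratio of intersection volume to union volume of two axis-aligned
boxes. NMS drops detections below the confidence threshold (default 0.5),
then greedily keeps the highest-confidence survivor and suppresses
same-label detections overlapping it at IoU ≥ 0.5; ties break by input
order, making the operation deterministic and idempotent. Matching follows
the COCO convention — detections in descending confidence order each claim
the unmatched ground truth of highest IoU at or above the threshold — rather
than optimal assignment; the greedy choice can differ from the
maximum-matching one and is asserted as such in the tests. Average
precision uses the monotone precision envelope read out at the 101 recall
points 0.00…1.00 (COCO); exact all-points integration (Pascal VOC) is
available via `interpolation="voc_all_points"`. mAP50-95 is the mean of AP
over the ten thresholds 0.50:0.05:0.95 and can never exceed mAP50.
Evaluation is single-class, so mAP equals AP. Degenerate 0/0 precision or
recall is reported as 0 with a flag and a warning instead of raising.

The baseline detector thresholds the full volume (default 200 HU), labels
components, and scores each component's bounding box by voxel count times
the bounding-box isotropy ratio (min extent / max extent), favoring large
compact structures over thin bright streaks; confidences are scores
normalized by the maximum. It is a deliberately naive, fully transparent
stand-in that lets the end-to-end pipeline run and be tested; it is not a
clinical detector.

## Agreement statistics

Classical Bland-Altman: differences `d = a − b` against means `(a + b)/2`,
bias = mean(d), sample SD (n−1 denominator), limits of agreement at
bias ± 1.96·SD, plus the count of pairs outside the limits. Because
published summaries sometimes report quartile intervals instead of limits of
agreement, Q1/Q3 of the differences are emitted alongside; quantiles use
linear interpolation between order statistics (conventions differ, so this
is stated). At least 3 pairs are required.

## Phantom generator

Each phantom is a capsule (hemispherically capped cylinder) of lumen
intensity 400 HU with a 2 mm wall shell at 80 HU on a 0 HU background,
centered in the grid, axis at elevation `tube_angle_deg` and azimuth
`tube_azimuth_deg`. Defaults: 128³ grid, 1 mm isotropic voxels, radius
10 mm, end-to-end length 80 mm — a lumen calibre and contrast level in the
range of an opacified aortic root, on a grid small enough to keep the suite
fast. The capsule cap avoids the PCA edge artifact a flat cut would add.
Partial-volume averaging is emulated by fading each boundary linearly over
one voxel (toggleable); Gaussian noise (default σ = 30 HU for the study
cohort, a plausible CT noise level) is added afterwards from a seeded
generator, so identical specs and seeds give bit-identical volumes.
Distractors (spheres, grid-z rods) are stamped after the tube to exercise
the largest-component filter. The ground truth — tight world-mm box over the
capsule, unit axis, generating angle, lumen voxel count — is analytic, and
`tilt_angle(truth.axis) == truth.angle_deg` to 1e-9 by construction.

`make_cohort` spaces angles evenly over a range and derives per-phantom
seeds from the master seed via `numpy.random.SeedSequence.spawn`, so cohorts
regenerate identically. The acceptance cohort is nine phantoms at 30°–70°
in 5° steps with σ = 30 HU noise.

What the phantom does **not** emulate: real aortic anatomy (sinuses,
leaflets, calcification), motion and beam-hardening artifacts, neighboring
contrast-filled chambers touching the root, and the annular-plane reference
used for manual measurements. Passing phantom tests therefore demonstrates
the correctness of the algorithmic contract — not clinical accuracy; on
patient data the lumen-axis vs annular-plane discrepancy alone introduces a
systematic bias that these tests cannot see.

## Numerical choices

* Eigenvalue tie tolerance 1e-9 (absolute, mm² units) for the ambiguous-axis
  guard; rank-0 clouds are rejected with the same tolerance.
* `arcsin` input is clamped to [0, 1] against rounding above unit norm;
  axis norms are validated to 1e-6.
* NMS and matching tie-breaks are by stable input order throughout.
* ROI rasterization is floor(lo)/ceil(hi) clipped to the grid; an ROI wholly
  outside the grid is a geometry error, an empty thresholded ROI is not.
* Box corner re-sorting after affine transforms guarantees `lo < hi` for
  every deserialized or transformed box.

## Scale of the shipped experiments

The test suite and the acceptance script run on 72³–128³ phantom grids and
cohorts of 2–9 volumes. These sizes were chosen as the package's own
desk-scale validation conditions: they are large enough that discretization
error in angle recovery is far below the acceptance bands (mean error
≲ 0.05° against a 2° band) while the whole suite stays fast. All operations
accept clinical-size volumes (e.g. 512×512×300) unchanged.
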