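# Methods

This document describes the geometric model, the estimators, their default
parameters, and the known limitations of `ciliomorph`.

## Coordinate conventions

Volumes are arrays in `(z, y, x)` order with isotropic voxels (default
9 nm). World coordinates are `(x, y, z)` in nm at voxel centers:
`world = index[::-1] * voxel_size_nm`. All reported lengths are nm, areas
nm², angles degrees.

## The mother-centriole model

The MC is modelled as a cylinder (default diameter 300 nm, length 500 nm)
with nine distal appendages (DAs) arranged every 40° around the distal end.
Each DA is a thin radial pin (default length 75 nm, half-width 10 nm) whose
tip lies at radius `mc_radius + da_length` (225 nm by default), 50 nm below
the distal face. A **DA tip** is operationally defined as the center of the
maximum-radius voxel of each 26-connected DA component in the fitted frame.
This definition has an inherent azimuthal quantization of
`atan(voxel / tip_radius)` ≈ 2.3° per tip at 9 nm voxels.

### Centriole frame fitting

The MC axis is the principal PCA eigenvector of the `mc_body` voxel cloud
(rejected if the eigenvalue ratio is < 1.2, i.e. the body is not elongated),
oriented so the DA centroid lies on the distal (+) side. The origin is
placed on the axis at the distal face: the perpendicular offset is estimated
from the distal 10% slab of body voxels, the axial position from the maximal
axial coordinate. The radius is the maximum radial voxel distance plus half
a voxel. Validation: over 20 random orientations, axis error ≤ 0.16° and
origin error ≤ 1.0 nm (tolerances: 2°, one voxel).

## Membrane component detection

`membrane` voxels are partitioned into 26-connected components. A component
is kept if

- its Feret diameter minus one voxel (a point-spread correction for the
  half-voxel dilation on each side) exceeds **30 nm**, and
- it spans at least **2** z-slices (single-slice blobs are section
  artifacts).

Exclusions are logged with reasons and reported.

## Surface area

Binary-mask isosurfaces overestimate area by ~20–25% (staircase bias). The
default `edt_offset` estimator instead runs marching cubes on the signed
Euclidean distance transform at ±1.5 voxels from the mask boundary, and
averages the two offset-leaflet areas; since each leaflet is a closed
surface around a thin shell, the half-sum approximates the mid-surface
area. Accuracy on analytic phantoms: sphere (r = 100 nm) +4.0% at 9 nm
voxels, +2.6% at 3 nm; torus (R = 160, r = 40 nm) +1.3%. The raw
`isosurface` mode is available for comparison.

## C-shape gap angle

Membrane points (mesh vertices by default, voxel centers optionally) are
projected to cylindrical azimuth θ about the fitted axis. The **gap** is the
largest circular spacing of the sorted θ multiset, including the
wrap-around arc — computed with the same floating-point expression as the
exhaustive pairwise definition, so the fast implementation is bit-identical
to the O(n²) oracle. Gap recovery on arc-torus phantoms with true gaps
0–270° is within 1.8° at 9 nm voxels (tolerance ±6°).

## Docking distance and rule

For each DA tip, the minimum distance from the tip point to the component's
0.5-level isosurface (point-to-triangle, exact barycentric projection) is
computed, then reduced by half the component's self-calibrated thickness
`t̂ = n_voxels · voxel³ / area` (clamped to [0.5, 3] voxels) to approximate
the distance to the membrane mid-surface. A component is **docked** when
the minimum over considered tips is ≤ **30 nm**. Tips whose azimuth falls
strictly inside the component's gap are excluded from the decision (a
C-shape should not be called docked via appendages it does not cover).

Validation with spheres at analytic standoffs {0, 10, 20, 50} nm (9 nm
voxels) and the boundary pair {29, 31} nm (3 nm voxels): all measured
distances within one voxel of truth, all docked/undocked decisions correct.
At standoff 0 the phantom's label precedence (`da` over `membrane` at
contact) removes the touching shell voxels, which floors the measured
distance near one voxel — still within tolerance.

Plasma-membrane docking uses the same machinery per tip against the `pm`
label and returns the list of docked DA ids.

## Stage classification

A most-advanced-wins ladder over the docked components:

| stage | rule |
|---|---|
| CILIUM | docked component with axial extent > 500 nm |
| CV | spherical-cap occupancy over the distal face ≥ 0.9 |
| TCV | component encircles the axis (min vertex radius ≥ 0.5·mc_radius) and gap ≤ closure tolerance (auto: one voxel of arc at the mean radius) |
| CCV | gap < 180° |
| DAV | any docked component |
| NAKED | otherwise |

The 180° CCV bound and 30 nm docking threshold are the biologically
motivated operating points; the CV occupancy (0.9), cap search window, and
CILIUM extent (500 nm) thresholds are package choices validated on
phantoms. Undocked structures never advance the stage. On 36 randomized
phantoms (6 per stage, random orientation and parameters) the classifier is
36/36 correct.

## Vesicle enlargement

A docked component is flagged *enlarged* when its surface area strictly
exceeds `mean + 1·SD` (ddof = 1) of the reference-group docked areas.
Reference {50, 60, 70}·10³ nm² gives threshold 70·10³; test areas
{75, 70, 65}·10³ flag {true, false, false}.

## Cohort statistics

- Two groups: Student's t (pooled variance) by default; Welch optional.
  Three or more: one-way ANOVA. Multiplicity: Holm–Bonferroni step-down
  adjusted p-values.
- Power: docked areas are simulated lognormal (`σ² = ln(1 + CV²)`,
  `μ = ln(mean) − σ²/2`); with a 2× mean difference, CV 0.3, n = 10/group,
  the t-test rejects in ≥ 99/100 replicates at α = 0.05 while the
  identical-distribution control stays at the nominal level.

## Phantoms: what they emulate, and what they don't

Phantoms voxelize analytic solids — MC cylinder, flat-ended DA pins,
membrane shells of spheres, arc/full tori (axis-centred; positioned
axially via `z_offset_nm`), spherical caps, and axial tubes — with 5 nm
shell half-thickness, optional global rotation, and optional tilted
plasma-membrane sheet. Ground truth (areas, gaps, per-tip distances,
stage) is closed-form. They emulate geometry and voxelization/partial-
coverage effects. They do **not** emulate imaging noise, anisotropic
sectioning, segmentation errors, membrane roughness, or contact-site
deformation; measured accuracies are therefore upper bounds on real-data
performance.

## Determinism

All randomness flows through seeded `numpy` generators; repeated
`analyze` and `phantom --seed` runs are byte-identical (MRC output and
JSON reports contain no timestamps).

## Known limitations

- DA tip azimuths are quantized by the voxel grid (≈ 2.3° at 9 nm).
- The `t̂/2` mid-surface correction assumes a locally plate-like membrane;
  it degrades for components thinner than one voxel or highly curved at
  the contact point.
- Feret-minus-one-voxel under-corrects diameters near the 30 nm filter
  bound at coarse voxel sizes; borderline vesicles (< ~1 voxel margin) may
  be filtered inconsistently across voxel sizes.
- The frame fit requires an elongated `mc_body`; daughter centrioles or
  severely truncated bodies must be excluded upstream.
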