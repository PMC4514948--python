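# Methods

This note documents the models, constructions and numerical choices behind
`syndesmo3d`, in the order the pipeline runs.

## Canonical frame and sides

All geometry lives in a right-ankle canonical frame: +x lateral,
+y anterior, +z proximal. Left ankles are mirrored across the sagittal
plane at ingest and the original side is kept as metadata. Operations that
need anatomical orientation (anterior/posterior disambiguation of tubercle
corners, the AP projection axis) take an optional 3x3 frame whose columns
are the lateral/anterior/proximal axes; distances themselves are
frame-free. Two frames matter for the phantom: the *anatomic* frame
(includes any plafond tilt — used by the measurement chain) and the *view*
frame (lab/detector axes, side mirroring only — used by the simulated
radiograph, so that plafond tilt produces genuine projection
foreshortening).

## Phantom generator

The phantom replaces patient CTs and owns the ground truth. Its design
goal is not visual realism but *analytic controllability*: every reported
parameter must be an exact closed-form function of the spec.

* **Tibia** — an extruded polygon. The shaft outline is fixed; the lateral
  face carries the incisura fibularis as a parabolic notch spanning
  y in [-6, +6] mm between an anterior tubercle corner at
  `A = (16, 6)` mm and a posterior corner at `C = (x_C, -6)`. The notch
  depth profile `d(z)` is the load-bearing construction:
  * quadratic with curvature 0.008 mm⁻¹, peaking at exactly
    `d = IFD_true` at `z = XY_true` — so the level of maximal incisura
    prominence *is* the intended measurement plane;
  * a gentle linear ramp above the level-search window, then a steep
    (1 mm/mm) closing ramp that crosses the 0.5 mm visibility threshold at
    exactly `z = IFH_true` — pinning the incisura's proximal tip. The
    steep final slope bounds the IFH error induced by any surface-position
    bias `b` to roughly `b` itself, which keeps the voxel path inside its
    2-voxel tolerance;
  * a residual 0.2 mm dent above the tip, kept nonzero so no cross-section
    ever has exactly collinear vertices (ear-clipping caps and convex-hull
    constructions stay non-degenerate).
* **Fibula** — a circular cylinder (radius 6 mm). A circle has exact
  nearest-point distances, so the requested gaps are realized in closed form:
  TFO pins the fibula's medial silhouette border
  (`c_x - r = 16 - TFO_true`), TCS-A then fixes `c_y` via
  `|A - c| = r + TCS_A_true`, and TCS-P fixes the posterior corner
  `x_C` via `|C - c| = r + TCS_P_true`. The fibular segment ends 2 mm
  below the incisura tip; where the notch becomes shallow the fibula
  (which sits inside the incisura mouth) would otherwise contact the
  tibia. An explicit feasibility check keeps the tibiofibular gap above
  1.3 mm at every level so voxelization never bridges the bones.
* **Talus** — an ellipsoid below the plafond, present only so segmentation
  has a bone to exclude.

Infeasible parameter combinations (overlap larger than the tubercle
geometry allows, plane height outside the search window, notch profile
dipping below visibility, fibula-tibia interference) raise
`PhantomInfeasibleError` with a specific message; nothing is clipped
silently.

Meshes are stacked cross-section rings (1 mm spacing plus rings at every
profile knot, including the exact plane-Y level) with ear-clipped end
caps; they are watertight by construction and deterministic functions of
the spec (the seed only drives voxel noise). Long straight outline edges
are subdivided with a 1 µm outward bulge so no three vertices are
collinear.

**Voxelization.** HU values are assigned from a signed-distance field:
`HU = soft + (bone - soft) * clip(f0 - sdf/ramp, 0, 1)` with
`f0 = (150 - soft)/(bone - soft)` and a two-voxel ramp. The anchor `f0`
places the 150 HU level *exactly on the analytic surface* — the package's
model of the fact that the clinical threshold is chosen to trace the
cortical edge. Without this anchoring every thresholded surface would
carry a constant ~0.2 mm dilation and all gaps a ~0.4 mm bias. The
two-voxel ramp width keeps the linear interpolation used by marching
cubes/marching squares close to the true crossing (a one-voxel ramp
leaves a ~0.15 mm clipping bias, measurable as a 4% error on a sphere's
surface area). Noise is additive Gaussian, clipped at air (-1000 HU);
debris blobs are deterministic sphere slots in the volume corners, at
least 5 mm clear of any bone. Defaults follow the imaging protocol:
0.625 mm isotropic spacing, bone 700 HU, soft tissue 40 HU.

## Segmentation

Threshold at 150 HU (>=, a voxel exactly at the threshold is bone),
remove 26-connected components with physical volume strictly below
500 mm³, extract one isosurface per remaining component at the 150 HU
level with linear interpolation (sub-voxel accuracy; components are meshed
on padded crops so each surface closes; a component touching the volume
boundary is capped and flagged open), and label bones by interior seed
points — the scripted stand-in for interactive bone picking. The labeler
trusts its seeds (swapped seeds yield swapped labels) and rejects seeds
that fall in no surface or share one. Surfaces are not smoothed by
default: smoothing systematically biases millimeter-scale gap distances.

## Measurement chain

* **Plane X** (tibial plafond): region growing over face adjacency from
  the seed's nearest face, keeping faces within 30° of the seed-face
  normal and within a 25 mm radius of the seed; total-least-squares fit
  (SVD) of the patch vertices; normal oriented toward the tibial bulk
  (proximal). The radius is measured as straight-line distance from the
  seed: within a 30° normal cone the patch is nearly flat, and
  accumulated center-to-center graph distance badly overestimates
  geodesics across skinny triangles. Patches under 50 faces are an error.
* **Incisura detection** on a cross-section contour: the contour is
  normalized CCW; for each convex-hull edge bridging non-adjacent contour
  vertices, the concavity depth is the maximal leftward deviation of the
  bridged arc from the chord; the incisura is the deepest such concavity,
  and is "present" above 0.5 mm depth. Because qhull keeps only extreme
  points, a notch cut into a straight edge yields a bridge that overshoots
  the true corners; leading/trailing arc points lying on the chord are
  trimmed so the bridge endpoints are the actual tubercle corners.
* **Tubercle corner**: the intersection of the two supporting lines of
  the tubercle (outer-flank hull edge and incisura-opening chord),
  snapped to the nearest contour vertex within 1 mm — the corner must lie
  on the bone. For discrete contours the two lines meet at the hull
  vertex itself, so the construction is exact and stable.
* **Point A / plane Y**: levels in a [4, 20] mm window above plane X are
  scanned at one reconstruction interval (0.625 mm default); the selected
  level maximizes incisura concavity depth, i.e. the level of maximal
  clear-space/incisura prominence, with ties broken distally. (Defining
  prominence as the corner's distance from the opening chord would be
  degenerate -- a hull-vertex corner lies on the chord -- so concavity
  depth is the implemented criterion.) XY is therefore quantized by the search step; the phantom's
  quadratic depth peak makes the maximizing level the grid point nearest
  the true one.
* **Landmarks B, D**: nearest points on the fibular contour evaluated on
  edges (not vertices); **E**: the notch-arc point at maximal
  perpendicular distance from line AC on the medial side. On a polyline
  the perpendicular distance is affine along each segment, so the vertex
  maximum equals the continuous maximum; dense-resampling oracles in the
  tests confirm agreement to 0.05 mm. E is constrained to the notch arc
  between A and C.
* **Point F**: the notch is tracked upward from plane Y in 0.25 mm
  sections; F is the deepest-point of the most proximal section whose
  depth still exceeds 0.5 mm. The worst-case height error is one section
  step (verified by a step-doubling test). A notch persisting to the top
  of the volume is an error, not a silent answer.
* **2-D axial path**: one oblique, one-voxel-thick section is resampled
  at plane Y (trilinear), re-segmented in-plane at 150 HU with sub-pixel
  contours (marching squares), bones identified by projected seeds, and
  the plane-Y landmark construction is repeated verbatim. The resampling
  grid is anchored so that a section through a slice center reproduces
  that axial slice exactly.

## Simulated radiograph

Orthographic projection along the anterior axis (no cone beam, no
magnification — the deterministic limit of the AP view; a stated fidelity
gap). Border queries at the height-`h` line above the projected plafond
edge are computed as exact extremes of the mesh section through the
line's pre-image plane — the limit of a dense ray scan, with no
resolution parameter. Two quantities cannot be read off a binary
silhouette because a rater sees them as density edges through overlap:
the posterior tubercle's lateral border (taken from the projection of the
posterior half of the tibia, split at its own anteroposterior midpoint)
and the incisura tip (the 3-D notch-ridge track is projected instead).
On tilted-plafond anatomy the projected incisura height is foreshortened
relative to the 3-D height, reproducing the qualitative 3-D > radiograph
ordering; the plafond line is drawn through the projected plane-X fit
point, which adds a small anchor ambiguity (~y-extent x sin(tilt)).

## Statistics

* **ICC(2,1)** — absolute agreement, two-way random, single measurement:
  `(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))` from the two-way
  ANOVA mean squares, with the exact F-based confidence interval
  (Satterthwaite degrees of freedom for the lower/upper F quantiles; the
  formula is spelled out in the docstring). Zero-variance tables are an
  explicit error; a perfect table reports ICC 1 with CI (1, 1). A caution
  for simulation studies: with k=3 raters the realized rater-panel
  variance has two degrees of freedom, so the estimate targets the ratio
  conditional on the realized panel, not the population ratio.
* **RMS-SD** — per-subject sample SD (n-1) across repeats, root mean
  square across subjects; inter-rater over a designated rater pair,
  intra-rater over sessions (repeat sessions are modeled as independent
  repeats).
* **ANCOVA** — `value ~ sex + height` by OLS (statsmodels), type-II F on
  the sex term, adjusted means at grand-mean height. Constant covariates
  are rejected naming the collinear term. Note that when height nearly
  separates the sexes the sex term loses power at small n — the phantom
  cohorts need a dozen subjects per group before the XY sex difference is
  significant *after* height adjustment.
* **Paired t** — closed form with exact reporting of zero-variance
  differences. No multiple-testing correction by default (a Bonferroni
  helper is provided).

## Workbench

`RunConfig` (flat YAML, schema-checked, defaults = the protocol constants
150 HU / 500 mm³ / 0.625 mm) drives `run_pipeline`: per-subject phantom
specs are drawn around the male/female preset means with between-subject
SDs set to one sixth of the reference normal ranges, heights from
sex-specific normals (1.73±0.04 / 1.61±0.03 m); each subject is measured
in all applicable modalities; failures are recorded per subject without
aborting; outputs (CSV with fixed float formatting, JSON report) are
byte-identical under a fixed seed.

## What the phantom does and does not show

Passing tests demonstrate that the *constructions* are correct and stable:
exact recovery of analytically known parameters through mesh, voxel,
2-D and projection paths, at the stated grids and tolerances. The phantom
has no trabecular texture, cartilage, soft-tissue contrast, metal
artifacts, anatomical covariance between parameters (presets treat them
as independent), or pathological shapes; real-data performance —
especially tibio-talar contact requiring morphological separation, and
rater-dependent radiographic edge reading — is outside what these tests
can show. The optional erosion-based bone split for fused joints is not
implemented; seeded labeling assumes threshold-separable bones.

## Problem sizes and grids

Defaults used throughout (and by the test suite): level search step
0.625 mm over [4, 20] mm; F-tracking step 0.25 mm (mesh) or one voxel
(volume); fibula ring 512 vertices (polygon-vs-circle error ~1e-4 mm);
notch arc 41 points (deepest point is an exact vertex); phantom volumes
about 100x90x120 voxels; property suites use 100 random feasible phantoms
on the mesh path and the two reference phantoms on the voxel path.
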