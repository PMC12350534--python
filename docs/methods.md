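# Methods

`depthreg` implements the full measurement chain of a depth-camera-based
markerless patient-registration system for image-guided surgery, together
with a synthetic tracked scene that makes every stage verifiable against
ground truth. This note documents the models, the conventions, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Frames and conventions

All transforms are elements of SE(3) stored as a 3×3 rotation matrix plus a
translation in millimetres, acting on column vectors: `p' = R p + t`. A
transform described as "A → B" re-expresses coordinates given in frame A in
frame B. Rotations are kept as matrices; unit quaternions appear only in
rotation averaging and in the pose-table file format. Image coordinates have
their origin at the top-left pixel center, x right, y down, in px.

The frames of the tracked scene:

* **tracking frame** — the world frame of the optical tracker, in which the
  rigid-body poses `m_camera` and `m_board` are reported;
* **camera rigid body / board rigid body** — the marker clusters attached to
  the depth camera and to the checkerboard;
* **optical frame** — the camera frame in which projection is defined by the
  intrinsics (z forward, x right, y down);
* **board (pattern) frame** — the checkerboard corner grid, z = 0 plane;
* **patient (phantom) frame** — the frame of the MR-derived surface.

## Camera model and intrinsic calibration

The camera is an ideal pinhole with Brown–Conrady distortion
(k1, k2, k3 radial; p1, p2 tangential). Calibration follows Zhang's method:
a normalized-DLT homography per view of the planar checkerboard, the
closed-form intrinsics from the homography constraints, per-view pose
decomposition, then a joint Levenberg–Marquardt least-squares refinement of
intrinsics + distortion + per-view poses minimizing total squared
reprojection error (scipy `least_squares`, `xtol = ftol = 1e-12`). The
default synthetic protocol produces eight views — four board tilts at each
of two depth planes — with the board covering the sensor edges, which is
what conditions the radial terms. The skew term of the closed form is
computed and then dropped; the refined model has no skew.

Single-view board pose (the `V` of the co-registration chain) undistorts the
corners by fixed-point inversion of the distortion map (25 iterations),
estimates the plane homography, decomposes it with the known intrinsics,
and refines the 6-d.o.f. pose against the full distorted projection.

## Hand-eye co-registration

Each capture provides the tracked poses of the two rigid bodies and the
board pose in the optical frame. With

* `M = m_board⁻¹ · m_camera` (camera rigid body → board rigid body),
* `E` = optical frame → camera rigid body (the unknown hand-eye mount),
* `V` = board pattern → optical frame (from the checkerboard image),

the product `M·E·V` maps pattern coordinates into the board-rigid-body frame
and is capture-independent at the true `E` — it is the physical mounting of
the pattern on its marker cluster. The closure relation `G = (M·E·V)⁻¹`
therefore defines `G` and is what the solver enforces. Only the 6 d.o.f. of
`E` are searched (axis-angle + translation): given the captures, `G` is a
deterministic function of `E` and is recovered afterwards as the
quaternion-chordal mean of the per-capture closures. A 12-d.o.f. joint mode
(`solve_eg(..., joint=True)`) exists for comparison and agrees at the
optimum.

The objective is the spread of the board corners pooled in the
board-rigid-body frame across captures: per corner, the 3-D standard
deviation (root of summed coordinate variances), averaged over corners.
Internally the solver minimizes the mean per-corner *variance* (mm²) — the
same minimizer, but smooth at a perfect solution where the mm spread has a
|·|-type kink that stalls quasi-Newton steps; the reported
`objective_value` is the mm spread. Optimization uses scipy's L-BFGS-B
(`ftol = 1e-18`, `gtol = 1e-14`, ≤ 500 iterations) from a closed-form
hand-eye initialization: capture pairs give the classic relation
`A X = X B` with `A = M_j⁻¹M_i`, `B = V_j V_i⁻¹`; the rotation comes from a
Procrustes fit of the rotation-axis vectors (Park–Martin style) and the
translation from the stacked linear system. Validation projects the virtual
board through the estimated chain onto each capture and reports the mean
per-corner pixel distance; the CLI's `--stop-at-px 0.25` reproduces the
operator practice of adding captures until the error is below a quarter
pixel.

Pooling in the board-rigid-body frame (rather than the raw tracking frame)
is deliberate: the two coincide when the board is static, and the former
stays correct when the board moves between captures.

## Rigid-geometry toolbox

Landmark and correspondence fits use the Kabsch/Umeyama closed form
(no scale), with the reflection branch rejected by sign correction and
collinear sources refused. Transform averaging uses the arithmetic mean for
translation and the quaternion chordal mean (largest eigenvector of the
outer-product sum after hemisphere alignment) for rotation — for the small
jitter between repeat captures at one position this agrees with an iterative
Karcher mean to well below 0.01°, at a fraction of the cost; sets spanning
more than ~120° are refused as ambiguous. Rotation distances are computed
through the rotation-vector magnitude, which keeps full precision near zero
where the arccos-of-trace form loses half the digits.

## Surface registration

Registration of a captured face cloud to the MR-derived face runs in four
stages:

1. **Voxel downsampling** of both clouds (default 5 mm, centroid per
   voxel).
2. **Congruent-triplet RANSAC**: well-spread, non-thin source triplets are
   matched against the target through pairwise-distance compatibility (the
   rotation-invariant descriptor). Candidate anchor pairs come from the
   target distance matrix, tightest distance matches first plus a random
   sample; the third point must lie on the intersection of the two
   remaining distance rings. Each congruent triplet yields a rigid fit
   scored by inlier fraction on a subsample; up to six mutually distinct
   candidates survive. Deterministic per seed.
3. **Feature-to-feature polish**: both clouds are reduced to their
   high-relief points (top 30% by distance from the local best-fit plane of
   12 neighbors — a cheap curvature proxy, computed on lightly
   voxel-averaged clouds so sensor noise does not swamp the relief signal),
   and each candidate is pulled into its basin by ICP restricted to those
   points, coarsely on the downsampled clouds and then at full resolution.
   Smooth, near-symmetric regions (the cranium dome) admit tangentially
   "slid" pseudo-alignments under plain point-to-point ICP; the distinctive
   points do not, which is what gives this stage its wide capture range.
4. **Point-to-point ICP** at full resolution from the best-ranked
   candidates (ranked by full-resolution truncated RMSE), with
   nearest-neighbor correspondence, distance-based rejection (threshold
   10 mm halving every 10 iterations to a floor of 2 mm), Kabsch updates,
   and an absolute convergence tolerance of 1e-10 mm on the RMSE
   improvement. The inlier RMSE is non-increasing across accepted
   iterations within one threshold epoch; the per-iteration
   `(threshold, rmse)` history is kept on the result. The final result is
   the candidate with the lowest inlier RMSE — on near-symmetric surfaces
   the surviving basins have similar coarse inlier counts but clearly
   different fine RMSEs.

The pipeline's purpose is global correctness on smooth anatomical surfaces
without learned features; learned backends (e.g. deep global registration)
can be benchmarked through the `BACKENDS` registry — any callable
`(source, target, seed) → RegistrationResult` — but none is implemented.

`chain_to_tracking` carries a camera-frame registration into the tracking
frame: `patient → tracking = m_camera · E · T_reg⁻¹`, with `T_reg` the
estimated optical → patient transform.

## Metrics and the benchmark protocol

FRE and TRE are both surface RMSEs over overlapping points — nearest-
neighbor distances truncated at a tolerance (default 5 mm, equal to the
registration voxel size, and recorded in every report): FRE on the face
clouds used to compute the alignment, TRE on the held-out craniotomy region
cropped by its bounding box plus a 10 mm margin (closed-box convention).
The overlap fraction is the share of source points with a target neighbor
within the tolerance; positions below the 95% threshold are flagged
excluded and never contribute to summary statistics — an all-excluded
configuration yields a report, not an exception.

The benchmark mirrors the clinical protocol: ten camera positions facing
the face with five captures each (registration phase; each capture is
registered and chained into the tracking frame, and the per-position mean
transform — quaternion chordal mean — gives that position's FRE and
overlap), then ten positions over the craniotomy with five captures each
(testing phase; TRE against the pooled patient registration, which is the
mean over non-excluded position transforms). Nominal standoffs are 442 mm
and 454 mm with per-capture wiggle, matching the mid-40-cm working distance
of such setups. The phantom pose in the tracking volume and all camera
placements derive from the run seed; tracker jitter defaults to 0.05° /
0.15 mm. By default the benchmark uses the true hand-eye mount (the
`coregister: true` config flag runs a simulated co-registration first);
hand-eye quality is measured by its own tests and the end-to-end closure
check.

The manual baseline digitizes the eight phantom fiducials, fits the first
four (FRE) and evaluates on the held-out four (TRE), reproducing the
fiducial-marker registration an experienced operator performs.

## The synthetic scene

The phantom head is parametric: a superellipsoid cranium (exponent 2.2,
half-axes 69.4 / 90 / 95–105 mm) with a nose wedge, brow ridge, eye-socket
depressions, cheekbones, lip ridge, chin boss, and twelve seeded random
relief bumps (±3.5 mm, σ 12–22 mm) outside the nose and measurement zones.
The relief matters: real faces are aperiodic and asymmetric, and that is
what gives surface registration a single deep optimum; a bare dome admits
sliding pseudo-solutions at every scale. The anthropometric targets —
bigonial width 118 mm, nose length 50 mm, alar base 35 mm — hold by
construction and are re-measured from the sampled cloud by
`measure_anthropometrics`. Shape parameters and sampling jitter use
independent random streams, so one seed describes the same head at every
sampling density. A circular craniotomy region (default 70 mm diameter) on
the parietal surface and eight well-spread fiducials complete the scene.
Cranium sampling is a Fibonacci sphere projected onto the superellipsoid at
one point per spacing²; halving the spacing quadruples the count.

Tracker jitter perturbs the rotation about the rigid body itself (not the
tracking-volume origin) with a half-normal angle and the translation with
an isotropic Gaussian — the body-frame model of marker-cluster noise.

Depth captures cull back-facing points and apply a z-buffer over a virtual
400×300 pixel grid (3 mm occlusion margin), then apply per-technology
noise: axial Gaussian along the viewing ray, lateral in-plane jitter,
i.i.d. dropout, optional depth quantization, and working-range clipping.
The seven built-in presets mirror the camera configurations of a
multi-camera comparison (two stereo-IR units with and without texture
projector, RGB stereo with and without neural refinement, RGB stereo short
range, structured light); working ranges follow the published sensor specs,
but the noise magnitudes are this package's own estimates — they are config
data, not code constants, and are chosen so that the projector/no-projector
and refined/unrefined contrasts reproduce the 95%-overlap exclusion pattern
in kind. The special preset name `"null"` denotes an ideal noise-free
sensor for closure tests.

## What the synthetic experiments show — and what they do not

Zero-noise closure tests show the chain algebra and the estimators are
exact: simulate → calibrate → co-register → register → chain reproduces the
phantom's tracking-frame pose to numerical precision, and FRE = TRE = 0.
Noise experiments show the estimators degrade gracefully and in the right
order (median TRE non-decreasing in axial noise; held-out TRE ≥ fitted FRE;
reprojection errors tracking injected pixel noise). The exclusion gate
reproduces the qualitative failure pattern of low-quality depth
configurations.

They do not show absolute accuracy on real hardware. The simulator has no
IR-projector physics, no stereo-matching artifacts, no specularity or skin
deformation, and its noise magnitudes are assumptions; absolute FRE/TRE
values here are typically smaller than on physical captures and should be
read as ordering/behavior, not as device specifications.

## Degenerate inputs and error behavior

Non-orthonormal rotations, reflections, non-finite points, collinear
landmark sets, sub-minimal capture counts, empty visible sets, out-of-range
standoffs, all-rejected ICP correspondences, empty crops and zero-overlap
clouds all raise typed exceptions (`depthreg.exceptions`). Configuration
files reject unknown keys outright so a typo cannot silently change a
tolerance. All stochastic stages take explicit seeds; re-running any CLI
command with its manifest reproduces outputs bit-identically.

## Problem sizes

Default phantom spacing is 1.5 mm for scene export and 2.0–2.5 mm in the
test suite and benchmark runs; the calibration session default is 15
captures; Monte-Carlo envelopes use 20–500 replicates depending on the
statistic. These sizes were chosen so the full verification suite runs on a
single CPU in minutes while leaving every statistical margin comfortable.
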