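# Methods

## Model and procedure

A face in the centered natural-head-position frame (x lateral, y vertical,
z anterior; Frankfort horizontal in XZ, nominal sagittal plane YZ; mm units)
is represented by a triangle mesh and 32 named anatomical landmarks
(10 midline + 11 bilateral pairs; facial thirds 4/17/11). All symmetry-plane
estimators share one pipeline:

1. **Mirroring.** Vertices and landmarks are reflected across the exact YZ
   plane (x = 0), regardless of where the face's true symmetry plane lies.
   Triangle winding is flipped, and left/right landmark *names* are swapped,
   so that same-named landmarks in the original and mirror sets are
   anatomical correspondents. This swap is what makes the post-alignment
   pair distance a per-landmark asymmetry measure: without it the distance
   between a left landmark and its reflected self conflates pose with shape.
2. **Initial global ICP.** The mirror copy is floated onto the fixed
   original with point-to-point ICP (nearest-neighbour correspondence over
   the fixed vertices via a k-d tree, uniform-weight rigid Kabsch update,
   centroid pre-alignment; defaults 100 iterations, relative RMS tolerance
   1e-6). Recorded per-iteration RMS values are measured after each update
   against that iteration's correspondences, which makes the history
   provably non-increasing.
3. **Refinement**, one of:
   * `pa` — uniform rigid Procrustes on the 32 landmark pairs;
   * `wpa` — weights wᵢ = 1/max(dᵢ, ε) from the post-ICP pair distances,
     then weighted rigid Procrustes. Weights are computed once; an
     iterative re-weighting mode exists (`SRPParams.reweight_iterations`)
     but is off by default;
   * `reference` — regional ICP restricted to a symmetric-region vertex
     mask, no landmark step (the professional ground-truth surrogate).
4. **Plane extraction.** The SRP is the mirror plane of the best
   orientation-reversing isometry mapping the original vertices onto the
   fully transformed mirror vertices (1:1 correspondence by construction).
   The improper Kabsch solve constrains det = −1 by flipping the smallest
   singular direction; the plane normal is the exact nullspace of A + I of
   the resulting linear part, and the offset is normal·translation / 2.

Both Procrustes objectives minimize *sums of squared* weighted distances:
the closed-form SVD solution exists only for the squared form, and the
weighted superimposition is a least-squares solve by construction. Scale is
fixed at 1 throughout; no similarity variant is exposed.

## Evaluation metrics

* **Angle error**: arccos |n₁·n₂| in degrees, orientation-independent,
  range [0°, 90°].
* **Mirrored-landmark position error**: the *same* original landmarks are
  reflected across the test plane and across the reference plane; the mean
  distance between same-named images is reported globally (32) and per
  facial third (4/17/11). The global value is identically the
  count-weighted mean of the three regional values.
* **FAI**: Σ midline point–plane distances + Σ |right − left| distance
  differences over the 11 pairs, unsigned distances throughout. The FAI
  error is test-FAI − reference-FAI; both the signed value and its absolute
  value are reported, since either convention appears in clinical
  summaries, and the absolute value is the magnitude comparison.

## Synthetic data

The generator emulates a mandibular-deviation cohort with exact ground
truth:

* **Template**: fixed (non-random) anthropometrically plausible landmark
  table — midline landmarks at x = 0, bilateral pairs mirror-exact — and a
  closed lat/long ellipsoid head (semi-axes 70/95/85 mm, 2342 vertices)
  with a midline nose bump, built so every vertex has an exact partner
  across x = 0. The mesh is centered on its centroid; the ground-truth
  plane is exactly x = 0.
* **Deviation**: lower-third landmarks displaced laterally so the pogonion
  offset equals the prescribed deviation — rigid lateral translation, or a
  rotation about an anterior axis through the subnasale ("rotate" mode).
  Mesh vertices follow with a chin-centred Gaussian falloff (σ = 40 mm) so
  ICP sees a smooth surface. Upper/middle landmarks and the true plane are
  untouched.
* **Noise**: isotropic Gaussian perturbation of each landmark, default
  sd 0.3 mm — the scanner's ~0.1 mm accuracy plus expert digitization
  variability; large enough to exercise the weighting without drowning the
  deviation signal. Mesh noise is available but off by default.
* **Pose**: a random rigid motion of mesh + landmarks + true plane,
  default rotation ≤ 5° and translation ≤ 10 mm per axis, modelling the
  residual error of clinician-guided natural head positioning.
* **Cohort**: n cases with deviations evenly spaced over the requested
  range (default 15 cases, 5–23 mm), alternating sides, per-case noise and
  pose seeds derived from the cohort seed; fully deterministic.

What the generator does **not** model: realistic craniofacial shape
variation (single template, no morphable model), soft-tissue texture,
scanner holes/artifacts, region-dependent landmark reliability, or expert
disagreement about the symmetric region. Passing synthetic tests therefore
demonstrates correctness and the intended *mechanism* of the weighting —
not clinical-grade accuracy on real scans.

## The reference region

The clinical reference workflow has experts hand-select a symmetric facial
region before regional ICP. Here that selection is replaced by a
programmatic mask: vertices whose nearest upper/middle-third landmark is
closer than their nearest lower-third landmark. This is a documented
stand-in for expert judgement, not a claim about which regions experts
would choose.

## Numerical choices

* Plane canonicalization: unit normal with the first component of
  magnitude > 1e-9 made positive, so equal planes serialize identically.
* Degenerate inputs: Procrustes solves require ≥ 3 non-collinear points
  (second singular value of the centered set > 1e-9 relative); reciprocal
  weights are clamped at d = 1e-6 mm (weight ≤ 1e6 mm⁻¹) with a warning;
  det corrections flip the singular direction with the smallest singular
  value, ties to the lowest index.
* The extracted plane is the projection of the best improper isometry onto
  pure reflections. A rotary component larger than 1e-3 (max-norm deviation
  of the linear part from the pure reflection about the extracted axis,
  ≈ rotary angle in radians) triggers a diagnostic warning; for pipeline
  outputs the component is tiny because the mirror correspondences are
  exact images of one improper map. For noisy, non-exact correspondences
  the projected plane is *not* exactly the minimizer over the 3-parameter
  plane manifold; it coincides with it in the exact-reflection limit.
* Cohort summaries use the arithmetic mean and the n−1 sample SD; rounding
  (half-even, 2 decimals) happens only at presentation.

## Problem sizes

Default experiment: 15 cases × (global ICP + regional ICP on a
2342-vertex mesh + two landmark Procrustes solves + plane fits) runs in a
few seconds on one core; solver-vs-optimizer oracle comparisons use 100
random instances of ≤ 10 points. These sizes make the full suite quick to
run while leaving every pipeline stage exercised end to end.

## Known limitations

* Single-template synthetic cohort: between-case variation comes only from
  deviation magnitude, noise and pose.
* The reference plane is itself an estimator (regional ICP), not an
  oracle; on synthetic data the construction plane is available as exact
  truth and is used wherever exactness matters.
* Hypothesis tests (normality, paired comparisons) are delegated to
  standard statistical routines and reported only descriptively; the
  package makes no inferential claims.
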