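# Methods

## Coordinate conventions

All computation happens in a fixed world frame in millimetres: x =
right-left (RL), y = anterior-posterior (AP), z = cranio-caudal (CC).
Array index `(i, j, k)` maps to world space as `origin + index * spacing`;
voxel centers carry the coordinates, indices are 0-based, grids are
axis-aligned. NIfTI images are reoriented to the canonical layout on load
and must have an axis-aligned affine; oblique acquisitions are rejected
rather than silently resampled.

## Rigid transform and its parametrization

A transform is `p' = R(q)(p - c) + c + t` with a versor (unit quaternion)
`q`, translation `t` and a fixed rotation center `c`. The six optimized
parameters are the versor vector part `(v1, v2, v3)` — the scalar part is
reconstructed as `w = sqrt(1 - |v|^2)` — and the translation. The
rotation center is the center of mass of the registration mask, which
approximately decouples rotation from translation in the optimizer;
composition, inversion and re-centering are exact (round-trip below
1e-9 mm) and are checked against 4x4 homogeneous-matrix algebra.

## Masked mean-square metric

The metric is the mean squared intensity difference over the mask voxels,
with the mask defined on the *moving* (reference, pre-treatment) image —
the delineation stays in its native space and is never resampled — and
mapped points sampled from the *fixed* (follow-up) image by trilinear
interpolation. Mapped points that leave the fixed grid are dropped from
the average rather than zero-padded (zero-padding manufactures metric
minima at the volume edge); if the surviving fraction falls below a floor
(default 0.5) the evaluation signals a lost overlap. Masks larger than
`max_samples` (default 30 000) are thinned by a deterministic even stride
over the voxel list — the standard sparse-sampling approach that makes
whole-grid registration tractable without introducing randomness.

The analytic gradient differentiates the trilinear interpolant exactly
(the derivative of the interpolation weights, divided by the voxel
spacing) and chains it through the versor parametrization with the closed
form for `d[R(v)u]/dv` under the constraint `w = w(v)`. It agrees with
central finite differences of the metric to ~1e-7 relative, except across
interpolation-cell faces where the interpolant's derivative is genuinely
discontinuous.

## Optimizer

Regular-step gradient descent. The gradient is rescaled into
step-comparable units (`rotation_scale = 0.01`: a 1 mm step along a pure
rotation direction changes the versor by 0.01 ≈ 1.1°), normalized, and a
step of the current length is taken against it; when the new direction
reverses against the previous one the step is multiplied by `relaxation`
(0.5); the run converges when the step underflows `min_step_mm` (0.01 mm)
or the gradient vanishes, and gives up (flagged, never raising) at
`max_iterations` (400). Defaults: `max_step_mm = 2`. Initialization is
the identity; an optional intensity-COM pre-alignment and an optional
two-level coarse-to-fine pass (Gaussian smoothing at 2 voxels) exist but
are off by default — keeping the failure mode of a mis-capture visible is
part of the protocol, and failures are retained in the study report
rather than discarded.

A result is flagged when it did not converge or its final metric exceeds
a caller-supplied threshold; flagged registrations stand in for the
failed-registration cases that visual inspection would catch in practice.

## Registration volumes

`RV0` is the prostate delineation; margins are added in world millimetres
by thresholding a spacing-aware Euclidean distance transform at the margin
(inclusive), so a 1 cm margin is isotropic on the anisotropic
1.17 x 1.17 x 1.7 mm grid. Expansions are clipped at the grid without
error — a 3 cm margin plausibly reaches the field-of-view edge. The full
grid serves as the whole-pelvis registration volume.

## Precision analysis

Per registered pair, the residual is the vector from the transformed
reference-prostate COM to the target-prostate COM — the residual couch
shift. Means and SDs (n−1) are computed per volume from the *signed*
components, matching the clinical reading of SD as positioning precision;
the norm is summarized alongside. Variance reductions are tested with
one-sided F-tests (`F = var_full / var_RV`, p from the upper tail), with
no multiple-testing correction, mirroring the directional question being
asked. Per-pair norm improvements over full-volume registration are
summarized by min/max/median/mean; "most precise volume" frequencies
break ties toward the smaller volume, which is deterministic and
conservative toward subvolume registration. The sample unit is the image
pair pooled across patients.

## The phantom

Analytic geometry rasterized with ~1-voxel anti-aliased edges: a
superelliptic body, femoral-head and sacrum bone shells (dark cortex,
bright marrow), an ellipsoidal bladder, a rectal tube, and an ellipsoidal
prostate with fixed internal Gaussian-blob texture. A static smooth
soft-tissue texture (Gaussian-filtered noise, SD 10 intensity units on a
0–90 scale, frozen per patient) gives the whole-volume metric something
to lock onto, as real anatomy does. Per repeat series:

* the prostate is displaced rigidly by a zero-mean draw with per-axis SDs
  (RL, AP, CC) = (0.5, 4.0, 2.5) mm and a 1° rotation SD — the
  AP-dominant, RL-minimal anisotropy of prostate motion relative to
  bone.  The motion is applied by evaluating the analytic prostate fields
  at rigidly pulled-back coordinates, so the ground-truth transform and
  the transported delineation are exact rather than resampled;
* rectum and bladder change size and content intensity (rectum radius
  ±15 %, content ±18 units; bladder ±10 %, ±8 units at
  `organ_variation_scale = 1`), emulating variable filling near the
  prostate — the mechanism that degrades the larger registration volumes;
* independent Rician noise (`sigma = 2`) is applied, the magnitude of a
  complex-Gaussian-perturbed signal.

Everything derives deterministically from `(config, seed)`. A drawn
displacement that would push the prostate against the grid edge raises a
field-of-view error rather than silently clipping anatomy.

The default grid is 96 x 96 x 60 voxels spanning the acquisition field of
view (449 x 407 x 204 mm, so ~4.7 / 4.2 / 3.4 mm voxels) — chosen so the
150-registration study runs in minutes on one CPU; the
acquisition-matched 384 x 348 x 120 grid at 1.17 / 1.17 / 1.7 mm is a
config switch away. At the coarse default spacing, prostate *rotation* is
weakly identifiable from the gland's interior (its COM displacement is
still recovered to well under half a voxel, and COM scoring is invariant
to rotation about the mask COM); sub-degree rotation recovery is
exercised in the tests at acquisition-like 1.17 mm spacing.

### What the phantom does and does not show

Passing tests demonstrate that the registration machinery recovers known
rigid motion under realistic geometry, anisotropic spacing, organ
appearance change and MR-magnitude noise, and that the precision analysis
ranks registration volumes correctly when prostate motion is truly rigid
and delineations are exact. The phantom does **not** model deformable
prostate shape change, seminal-vesicle anatomy, bias fields or coil
profiles, delineation variability (available as a noise knob, default
off), or the intensity statistics of real T2 tissue texture — so absolute
SD values from the synthetic study are cleaner than clinical ones, and
only the qualitative ordering and the machinery's correctness transfer to
real data.

## Numerical choices and degenerate inputs

* Trilinear sampling returns NaN out of bounds; exact voxel centers
  reproduce stored values to machine precision.
* Empty delineations, geometry mismatches, lost overlap, unpaired or
  incomplete analyses and degenerate (zero-variance) F-test denominators
  raise typed exceptions; inside a study run, per-registration failures
  are caught, flagged and retained.
* The versor vector part is kept strictly inside the unit ball during
  optimization (renormalized at 0.999) so `w` stays real.
* Determinism: the optimizer has no randomness; phantom and study derive
  all draws from seed sequences, so a study is bit-reproducible for a
  fixed config and seed on one platform.

## Problem sizes used by the test suite and acceptance script

The default study (10 patients x 3 follow-ups x 5 volumes = 150
registrations at the 96 x 96 x 60 grid) runs in roughly half a minute;
the dedicated motion-recovery check uses 20 independent single-pair
phantoms; oracle-equivalence checks use random 12³ instances with
~300-voxel masks.
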