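# Methods

This note documents the models behind `hybridnav`, the assumptions they
make, the synthetic study conditions, and the numerical choices a
maintainer would want to know about.

## Imaging model

The C-arm is modeled as a rotating projective imager. The world frame is
anchored at the gantry pivot, projected to the center of the reference 90°
view: x = detector horizontal at 90°, y = rotation axis (table direction),
z = beam direction at 90°; right-handed; angles in degrees at every
interface. The beam direction at angle θ is `(sin(θ−90°), 0, cos(θ−90°))`.

Two projection modes exist:

* **parallel** (default): each view is an orthographic projection along
  the beam; a pixel back-projects to a ray orthogonal to the detector.
  This is the model the three-view reconstruction uses, because the 3D
  position is defined as the intersection of orthogonal rays through the
  images.
* **pinhole** (optional): isocentric mounting with a configurable
  source–detector distance; the source sits halfway between source and
  detector from the pivot, and `px_per_mm` is the scale at the pivot
  plane, so parallel and pinhole agree exactly there. Points at or behind
  the source raise a degenerate-projection error.

Which of the two models produced any particular hardware measurement is
generally not knowable from navigation data alone; both are provided and
the parallel model is the documented default.

Pixels are 0-based `(column, row)` with sub-pixel values. Quantization to
integer pixels is applied only by the synthetic detector, which is the
noise model for 2D sensor detection (below).

## Calibration

* **Orb detection**: Gaussian smoothing (σ = 1 px) → intensity inversion
  against an absolute threshold → connected components → intensity-
  weighted centroid and equivalent radius, filtered to a radius band and
  sorted by x. At least three detections are required; fewer is an error
  because the pivot center is defined as an average of ≥ 3 orb centers.
  Any detector honouring the same contract (e.g. an external neural
  detector emitting bounding-box centers) can be swapped in.
* **Pivot model**: per-angle least-squares polynomials in gantry height
  (default degree 2 — the number of imaged heights is small, and a low
  degree resists overfitting), evaluated at unfitted angles by linear
  interpolation between neighboring fitted angles, clamped at the ends.
* **Pixel scale**: zero-intercept least-squares slope of caliper extents
  (px) on known lengths (mm). The fit is forced through the origin because
  the mapping is a physical proportionality.

## Reconstruction and registration

A navigation step's 3D position is the point minimizing the sum of squared
distances to the back-projected rays of its detections, solved in closed
form from the normal equations `Σ(I − d dᵀ) p = Σ(I − d dᵀ) o`. The same
path serves two, three or more views; the 75°/90°/105° triplet is the
standard acquisition. A singular system (all rays parallel) raises a
degenerate-geometry error. With the ±15° aperture, depth (z) uncertainty
is amplified by ≈ 1/sin 15° ≈ 3.9 relative to the per-view detection
noise — the dominant noise term in the X-ray references.

Rigid EMT-to-image registration is closed-form Kabsch: centroid alignment
followed by SVD orthogonal Procrustes with the determinant correction, so
the result is always a proper rotation. Correspondence is positional
(timestamp-ordered pairs); there is no ICP because each EMT sample is
acquired together with its triplet. The transform can be refit each time
new images arrive (window configurable; default all accumulated pairs).

Errors are reported per axis as RMSE, combined as
`RMSE = sqrt((E_X² + E_Y² + E_Z²)/3)` — the quadratic mean that makes
per-axis values (2.04, 1.68, 23.10) mm combine to 13.42 mm.

## Distortion compensation

Offline compensation is an ordinary-least-squares polynomial per output
axis over the full trivariate monomial basis of total degree ≤ d (4 terms
for d = 1, 20 for d = 3), mapping EMT-reported positions directly to
X-ray-derived references. The full 3D basis (rather than per-axis
univariate polynomials) reflects that the distortion is a 3D vector field
with cross-axis structure. Because the training pairs are (EMT sample,
detected position), the fitted map folds frame alignment and distortion
correction into one polynomial; a variant that rigidly pre-aligns and fits
only the residual is available (`align_rigid_first`) and reaches the same
model surface.

Numerics: inputs are centered and scaled to the training bounding box
before the monomials are formed (cubic monomials on raw mm coordinates are
badly conditioned); the normalization is stored with the model. A degree-d
fit requires at least C(d+3,3) training points; fewer raises an
underdetermined-fit error rather than silently returning a minimum-norm
solution, because rank-deficient fits extrapolate disastrously.

## Synthetic study conditions

The simulator replaces the hardware; its defaults define the study:

* **Detector**: 256×256 px, principal point centered, scale
  `1/(0.32·√12) ≈ 0.90 px/mm`, chosen so rounding to integer pixels
  produces exactly the canonical 0.32 mm quantization noise used
  throughout as the X-ray detection noise model.
* **Distortion field**: per axis, an affine trend plus 12 random
  sinusoids with wavelengths in [600, 1200] mm, normalized over the
  workspace (the 192×192 mm board ± sensor excursion, z ∈ [0, 48] mm) to
  per-axis RMS (2, 1.7, 23) mm — Z-dominant, the magnitude of
  metal-induced error along the beam axis. Distortion of this size varies
  on the scale of the C-arm, far larger than the workspace, so the trend
  is offset-dominated (97% of its variance in the constant term); this
  also caps displacement gradients at ≈ 0.3 × amplitude/halfwidth, which
  keeps the EMT map fold-free (invertible) for every seed — a folding map
  would admit no functional compensation at all. The sinusoid sum is
  orthogonalized against affine functions over the workspace so that
  `nonlinear_fraction` (default 0.05) is exactly the share of genuinely
  non-affine displacement variance, independent of the frequency draw.
  All of this is seeded and bitwise reproducible.
* **Training board**: 25×25 stud grid at 8 mm pitch (typical stud pitch;
  not a measured value), 100 training points on nodes raised by 0–3
  stacked 9.6 mm bricks — at least four distinct heights keep the cubic
  z-basis identifiable from board data — plus 32 validation points placed
  uniformly (off-node) in the board volume. References at the fixed 90°
  view take x, y from quantized pixels and z from board geometry.
* **Evaluation retraction**: 60 steps × 2 mm along a vessel-like helical
  bend (radius 35 mm) placed obliquely above the board, partly beyond the
  trained height range — compensation must extrapolate, as it would when
  trained on a board but deployed in a phantom. Steps are arc-length
  parameterized; chords of the gentle bend match the 2 mm step to < 1 µm.
* **EMT mounting**: the field generator frame is the image frame plus a
  residual misalignment of ~1° and ~2 mm (nominally aligned mounting).
* **Acquisition timing**: 1.0 s gantry setup per rotation, 4 °/s angular
  velocity, 100 ms minimum exposure; one 15° rotation therefore takes
  4.75 s and a full 75→90→105 sweep 9.8 s.

What the simulator does **not** emulate: X-ray attenuation physics and
anatomy rendering, detector pin-cushion distortion, sensor orientation
(only position is tracked), hardware drivers, and real dosimetry. Passing
tests therefore demonstrate the correctness and internal consistency of
the computational pipeline under a plausible distortion model — not the
absolute accuracies achievable on any particular C-arm/EMT combination.

## Trade-off Monte Carlo

For each `M ∈ {0…60}` and each of N = 200 iterations, M distinct steps are
drawn uniformly to be navigated on EMT; their error is the actual
EMT-vs-reference distance. The remaining X-ray-navigated steps carry a
modeled per-axis Gaussian error with σ = 0.32 mm. Per M the curve records
the pooled mean per-step error and the **CI-95 accuracy bound**: the 95th
percentile, across iterations, of the per-iteration combined RMSE. The
per-procedure RMSE is the right "sample" here — it is the quantity the
error tables report, and a single grossly wrong step (tens of mm) then
visibly disqualifies an operating point, whereas a pooled per-step
percentile would hide up to 5% of arbitrarily large errors and make even
an uncompensated stream look acceptable at small M. Radiation totals per
operating point are `FT = n_exposures × 0.95 s`,
`DAP = n_exposures × 0.28 cGy·cm²`, with one exposure per retained
navigation event by default (the accounting consistent with a 60 s
full-acquisition baseline; triplet accounting ×3 is available). The
operating point is the smallest FT whose bound meets the 1 mm threshold; a
curve with no qualifying point returns a not-achieved sentinel. A
full-imaging curve point (M = 0) contains no EMT navigation at all and
always qualifies by construction of the noise model, so statements about
compensation quality are read off the hybrid points M ≥ 1.

The training-reduction experiment subsamples k training points, refits the
compensation, reruns the leave-out study and records the percent FT saving
(zero when the threshold is never met), averaged over iterations. The
shipped tests and the acceptance script run it at 200 outer iterations
with a thinned inner grid (every 5th M, 40 inner iterations) — the
package's standard problem size for this study; the full-resolution
configuration is a parameter away.

## Known limitations and behavior at the edges

* On ~1 in 20 field seeds the evaluation trajectory happens to traverse a
  region where the *linear* fit's residual is locally small, and linear
  compensation then also meets the threshold everywhere; the cubic-beats-
  linear ordering of the threshold crossings holds for the remaining
  seeds. The per-board validation ordering (cubic < linear < none, with
  cubic at least ~10× better than uncompensated) held for every seed
  examined.
* `ft_at_threshold` does not interpolate between adjacent M points; its
  resolution is one exposure (0.95 s).
* The distortion field is stationary in time; sensor jitter, hysteresis
  and dynamic interference are out of scope.
* Compensation extrapolation degrades smoothly but genuinely outside the
  trained volume; the underdetermined-fit guard protects only against
  rank deficiency, not against extrapolation.
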