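# Methods

## Transformation model

The deformation is a uniform cubic B-spline free-form deformation.  A
regular lattice of control points with integer spacing δ_a ≥ 2 voxels
per axis carries displacement coefficients φ (in voxels); the dense
field at a voxel is the 4^D tensor-product blend of its neighbouring
coefficients.  Indexing convention: region `l = ⌊x/δ⌋`, local fraction
`u = x/δ − l`, supporting control points `l .. l+3`.  The lattice holds
`ceil(N/δ) + 3` points per axis, so voxels of a ragged last region
(when `N mod δ ≠ 0`) still have a full support; their fraction is
computed from the nominal spacing.  Coordinates are 0-based, axis order
(x, y[, z]) with axis 0 = x, everything in float64.

2-D images are first-class: every operation accepts D = 2 with 4×4
supports as well as D = 3 with 4×4×4.

## Similarity metric

`LSD = mean_x ln[(F(x+T(x)) − R(x))² + 1]` with the natural logarithm
(the analytic derivative `2d/(1+d²)` is only consistent with ln).  It
is non-negative, zero only for identical images, symmetric, and bounded
above by the mean squared difference.  Because `ln(d²+1)` is
scale-sensitive, images are used as loaded by default; the CLI offers
`--normalize` to min-max rescale both inputs to [0, 255] first.

The penalized form `C = (1−λ)·LSD − λ·C_smooth` is exposed, but only
λ = 0 is executable: no smoothness penalty is implemented, and a
positive λ raises `NotImplementedError` rather than silently ignoring
the term.

## Analytic gradient

The mesh gradient is assembled voxel-centrically:

* per voxel, `∂LSD/∂T = 2 ∇F(x) · d / (1 + d²)` where ∇F is the
  central-difference gradient of the **initial** moving image, held in
  a lookup table and *not* re-evaluated at the warped position.  This
  is a deliberate approximation: it turns the image gradient into a
  reusable constant table and is accurate while the displacement is
  smaller than the image's intensity-variation scale.
* per control point, the gather sums `∂LSD/∂T × basis product` over the
  supported voxels; the 1/N normalization of the metric is applied once
  here (the per-voxel formula above deliberately omits it).

Consequences of the frozen ∇F: a central finite difference of the full
cost agrees with the analytic gradient to ~1e-4 relative norm when the
evaluation point has integer-voxel displacements (there the symmetric
difference quotient of the multilinear warp coincides with the
central-difference table) and to a few percent at general sub-voxel
displacements; the discrepancy grows with deformation magnitude.  The
gradient-validation test therefore evaluates at the zero mesh on a
pre-deformed image pair with sub-voxel mean deformation.

## Warping

The moving image is resampled at `x + T(x)` with multilinear
interpolation (`scipy.ndimage.map_coordinates`, order 1).  Out-of-range
samples clamp to the nearest edge voxel, which avoids inventing
intensity differences at the border.  The interpolation order for
fractional coordinates was an open choice; multilinear is the cheapest
order consistent with the analytic gradient's linear model.

## Evaluation backends

Two organizations of the same arithmetic:

* `naive` — literal per-voxel tensor-product loops and per-control-point
  gathers, with basis weights computed from the spline polynomials at
  every use.  The testing oracle.
* `lut` — vectorized path driven by three precomputed tables: basis
  products per within-region offset, control-point index sets per
  region, and the initial moving-image gradient.

Both paths sum each voxel's 4^D contributions in the same tap order and
each control point's support in the same region/voxel order, so costs,
fields and gradients agree bit-for-bit in practice; the tests assert
agreement within 1e-10 per evaluation and identical fields over full
100-iteration runs.

## Optimizer

Nonlinear conjugate gradient on the flattened coefficient vector
(C-order ravel of the `cp_counts + (D,)` array):

* `d_1 = −g`; `d_i = −g_i + β_i d_{i−1}` with the hybrid
  `β = max(0, min(β_HS, β_DY))`, where
  `β_HS = gᵀy / dᵀy`, `β_DY = ‖g‖² / dᵀy`, `y = g_i − g_{i−1}`.
  A vanishing denominator, a zero clamp, or a non-descent direction
  (dᵀg ≥ 0) restarts with steepest descent.
* Inexact line search: backtracking with the Armijo condition
  (c₁ = 1e-4, halving, at most 20 backtracks).  The first trial step is
  scaled so no coefficient moves by more than `step_scale` voxels
  (default 1.0) — the raw LSD gradient can be orders of magnitude
  smaller than a useful step, so a fixed unit trial step would stall —
  and subsequent searches warm-start at twice the previously accepted
  step.  Failure to find sufficient decrease terminates the run.
* Stopping: 100 iterations by default, or `‖g‖∞ < 1e-6`, or line-search
  failure.  The lowest-cost iterate visited is returned, and the
  accepted cost sequence is non-increasing by construction.

With an exact line search substituted (the driver accepts a pluggable
line search), the hybrid scheme reduces to textbook linear conjugate
gradient on quadratics; the tests verify the iterate sequence matches
one to 1e-8.

## Synthetic evaluation protocol

A case is: a phantom reference image; a smooth random ground-truth
field with prescribed mean displacement magnitude; and the moving image
`moving = warp(reference, truth)`.  Because the moving image samples
the reference at `x + T_true(x)`, the field that deforms the *reference*
onto the moving image is exactly `T_true`; `recover_field` therefore
runs the registration with the moving image as the fixed target and the
reference as the deformed input, so the estimated field is directly
comparable to the truth (no field inversion, no systematic sign error).

Generator choices (fixed defaults, stated here once):

* **Phantoms**: "blobs" (default) sums ~`area/500` random Gaussians
  (clamped to 10–60) with widths 4–10% of the image size and centres
  kept 15% away from the border, min-max rescaled to [0, 255] — smooth,
  textured, near-flat at the edge.  "checkerboard" and "gradient" are
  available for degenerate-structure experiments.
* **Ground-truth fields**: unit-normal coefficients on a lattice
  coarser than the registration lattice (spacing = max(shape)/4, at
  least 8 voxels — representable-but-not-identical to the search
  space), interpolated densely, smoothly tapered to zero over a ~10%
  raised-cosine border margin (a deformation should not pull content in
  from outside the frame), then rescaled so the mean voxel displacement
  magnitude equals the request exactly.
* **Repetitions**: 8 fields per magnitude is the default repetition
  count for mean/std statistics.
* All randomness flows from one seed per case through
  `numpy.random.SeedSequence`.

Scoring: per-case field MSE is the mean squared Euclidean vector error
per voxel (the only symmetric, unit-consistent reading); summary
statistics use the sample (n−1) standard deviation; normalized RMSE
between two fields is `sqrt(Σ‖v_a − v_b‖² / Σ‖v_a‖²)` with the first
argument as reference.

What the synthetic protocol does *not* emulate: acquisition noise,
intensity inhomogeneity, multimodal contrast, occlusion/sliding
interfaces, and truly non-representable (e.g. discontinuous)
deformations.  Passing recovery tests shows the pipeline recovers
smooth deformations of well-textured images; it does not bound error on
clinical data.

## Problem sizes in the test suite

The recovery experiment runs at 128×128 (spacing 10, 100 iterations)
and the difficulty trend across mean magnitudes {2.0, 3.2, 4.4, 5.3}
at 64×64 with 8 seeds per magnitude; backend-equivalence runs use
32×32 and 16×16×16 instances.  These sizes were chosen as the smallest
at which the phantoms retain enough texture for the statistics to be
stable.

## Known limitations

* No smoothness penalty (λ must be 0); very large deformations can
  fold the grid.
* The frozen initial-image gradient degrades the gradient quality as
  displacement grows; recovery error rises accordingly with deformation
  magnitude (this is visible in the trend test).
* Single-resolution: no coarse-to-fine pyramid, so capture range is
  limited to deformations a single mesh can express.
* Monomodal metric only.
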