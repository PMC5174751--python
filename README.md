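# ffdreg

Deformable (nonrigid) registration of 2-D and 3-D scalar images with a
cubic B-spline free-form deformation (FFD) model, a log-squared-difference
similarity metric, and hybrid nonlinear conjugate-gradient optimization.

It is aimed at monomodal alignment problems — e.g. matching two MR slices
or volumes of the same subject that differ by a smooth local deformation —
and at methodological work that needs a transparent, fully tested FFD
registration pipeline with both a literal reference implementation and a
fast vectorized one that are verified against each other.

## The model

A coarse lattice of control points with spacing δ per axis carries
displacement coefficients φ.  The dense displacement at voxel **x** is the
cubic B-spline tensor product over its 4×4(×4) supporting control points:

    T(x) = Σ_{i,j(,k)=0..3} B_i(u) B_j(v) [B_k(w)] · φ(l+i, m+j [, n+k])

with region index `l = ⌊x/δ⌋` and local fraction `u = x/δ − l ∈ [0,1)`.
The lattice has `ceil(N/δ) + 3` control points per axis so every voxel has
a full support (a 512-voxel axis at spacing 16 → 32 regions, 35 control
points).

Similarity between the reference R and the warped moving image F∘(id+T)
is the **log squared difference**

    LSD = (1/N) Σ_x ln[ (F(x+T(x)) − R(x))² + 1 ]

a logarithmically compressed SSD that stays sensitive to small residuals
late in the optimization.  Its gradient with respect to the mesh is
assembled voxel-centrically via the chain rule,

    ∂LSD/∂T = 2 ∇F · d / (1 + d²),     d = F(x+T) − R(x),

gathered region-by-region with the B-spline basis products as weights;
∇F is the precomputed gradient of the initial moving image.  The basis
products, the per-region control-point index sets, and ∇F are held in
three lookup tables, which is what makes the vectorized `lut` backend
fast; the `naive` backend evaluates the same arithmetic with literal
per-voxel / per-control-point loops and serves as the testing oracle.

The cost is minimized by nonlinear conjugate gradient with the hybrid
mixing parameter `β = max(0, min(β_HS, β_DY))`, a descent-direction guard,
and a backtracking Armijo line search, for a default of 100 iterations.

## Worked example

Create a synthetic case — a 128×128 blob phantom deformed by a known
smooth random field with mean displacement 2 voxels — and recover the
deformation:

```python
import numpy as np
import ffdreg

case = ffdreg.make_case((128, 128), mean_magnitude=2.0, seed=1)
config = ffdreg.RegistrationConfig(spacing=10, max_iterations=100)
result = ffdreg.recover_field(case, config)

zero_mse = ffdreg.field_mse(np.zeros_like(case.true_field), case.true_field)
mse = ffdreg.field_mse(result.field, case.true_field)
print(f"initial cost : {result.history[0].cost:.4f}")
print(f"final cost   : {result.cost:.4f}")
print(f"zero-field MSE {zero_mse:.3f} -> recovered MSE {mse:.3f}")
```

prints

```
initial cost : 2.6573
final cost   : 0.0132
zero-field MSE 5.628 -> recovered MSE 0.467
```

The similarity cost drops by two orders of magnitude, and the mean
squared error of the estimated displacement field against the ground
truth falls to about 8% of the error of doing nothing (the zero field):
the registration recovers most of the deformation.

The same pipeline is available from the shell:

```sh
ffdreg synth --shape 128,128 --mean-magnitude 2.0 --seed 1 --out-dir case/
ffdreg register --reference case/moving.npy --moving case/reference.npy \
    --spacing 10 --out-field est.npy --out-warped warped.npy
ffdreg score --estimated est.npy --truth case/truth_field.npy
```

(`register` writes a per-iteration history CSV and a JSON manifest next
to the field; `--backend naive` switches to the loop-based oracle.)

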