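"""Log-squared-difference similarity metric and its analytic gradient.

The metric is the mean over voxels of ``ln((F_warped - R)^2 + 1)``
(natural log), a logarithmically compressed SSD.  Compared with plain
SSD it stays sensitive to small residual differences late in the
optimization, when most of the misalignment has already been removed.

The gradient with respect to the control-point coefficients is obtained
voxel-centrically via the chain rule: each voxel contributes

    dLSD/dT = 2 * gradF(x) * d / (1 + d^2),        d = F_warped - R

and the region-wise gather accumulates ``dLSD/dT * basis_product`` into
the 4^D control points supporting each region, normalized once by the
voxel count.  ``gradF`` is the precomputed spatial gradient of the
*initial* moving image (a deliberate approximation that makes it a
reusable lookup table); its consequences for finite-difference
agreement are documented in the methods note.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .bspline import (
    ControlPointMesh,
    LUTSet,
    cubic_bspline_weights,
    interpolate_displacement,
    interpolate_displacement_naive,
    local_coordinates,
    warp_image,
)
from .errors import ConfigurationError, DomainError

__all__ = [
    "CostGradient",
    "lsd_cost",
    "total_cost",
    "voxel_gradient",
    "gather_control_point_gradient",
    "gather_control_point_gradient_naive",
    "evaluate_cost_and_field",
]


@dataclass
class CostGradient:
    """Scalar cost with its control-point gradient (mesh-shaped)."""

    cost: float
    gradient: np.ndarray


def lsd_cost(reference: np.ndarray, warped: np.ndarray) -> float:
    """Mean of ``ln(d^2 + 1)`` over voxels, ``d`` the intensity difference.

    Non-negative; zero iff the images are identical; symmetric in its
    arguments; bounded above by the mean squared difference.
    """
    reference = np.asarray(reference, dtype=np.float64)
    warped = np.asarray(warped, dtype=np.float64)
    if reference.shape != warped.shape:
        raise DomainError(
            f"image shapes differ: {reference.shape} vs {warped.shape}"
        )
    d = warped - reference
    return float(np.mean(np.log1p(d * d)))


def total_cost(lsd: float, smooth_penalty: float | None, lam: float) -> float:
    """Penalized cost ``C = (1 - lambda) * LSD - lambda * C_smooth``.

    Only ``lam == 0`` is executable: no smoothness penalty is
    implemented, so a positive weight raises rather than silently
    dropping the term.
    """
    if not (0.0 <= lam < 1.0):
        raise DomainError(f"penalty weight must satisfy 0 <= lambda < 1, got {lam}")
    if lam == 0.0:
        return float(lsd)
    if smooth_penalty is None:
        raise NotImplementedError(
            "smoothness penalty is not implemented; only lambda = 0 is supported"
        )
    return float((1.0 - lam) * lsd - lam * smooth_penalty)


def voxel_gradient(
    reference: np.ndarray, warped: np.ndarray, luts: LUTSet
) -> np.ndarray:
    """Per-voxel derivative of the metric w.r.t. the displacement vector.

    ``2 * gradF * d / (1 + d^2)`` with ``gradF`` taken from the LUT of
    the initial moving image.  Shape ``image_shape + (D,)``.  The
    1/n_voxels normalization is applied later, in the gather step, so
    that it appears exactly once in the chain rule.
    """
    reference = np.asarray(reference, dtype=np.float64)
    warped = np.asarray(warped, dtype=np.float64)
    if reference.shape != warped.shape:
        raise DomainError(
            f"image shapes differ: {reference.shape} vs {warped.shape}"
        )
    if luts.moving_gradient.shape != reference.shape + (reference.ndim,):
        raise DomainError("LUT moving-image gradient does not match image shape")
    d = warped - reference
    scale = 2.0 * d / (1.0 + d * d)
    return luts.moving_gradient * scale[..., None]


def gather_control_point_gradient(
    voxel_grads: np.ndarray, luts: LUTSet, geometry=None
) -> np.ndarray:
    """Accumulate per-voxel gradients into the control-point lattice.

    For each control point the entry is ``(1/n_voxels) * sum`` over its
    supported voxels of ``voxel_gradient * basis_product`` — the basis
    product being the constant derivative of the displacement with
    respect to that coefficient.  Processed region-wise through the LUT
    index tables, each region scattering into its 4^D surrounding
    control points.
    """
    g = luts.geometry if geometry is None else geometry
    if voxel_grads.shape != g.image_shape + (g.ndim,):
        raise ConfigurationError(
            f"voxel gradient shape {voxel_grads.shape} does not match geometry "
            f"{g.image_shape}"
        )
    off_row, reg_row = luts.voxel_rows()
    vg_flat = voxel_grads.reshape(-1, g.ndim)
    bp = luts.basis_products[off_row]  # (Nvox, 4^D)
    cpi = luts.cp_indices[reg_row]  # (Nvox, 4^D)
    out = np.zeros((g.n_control_points, g.ndim))
    for t in range(bp.shape[1]):
        contrib = bp[:, t, None] * vg_flat
        np.add.at(out, cpi[:, t], contrib)
    out /= g.n_voxels
    return out.reshape(g.cp_counts + (g.ndim,))


def gather_control_point_gradient_naive(
    voxel_grads: np.ndarray, geometry
) -> np.ndarray:
    """Reference gather: explicit loop per control point over its support.

    Oracle for :func:`gather_control_point_gradient`; O(CPs x support).
    For each control point the 4^D supporting regions are visited in tap
    order and each region's voxels in lexicographic order, with basis
    weights evaluated directly from the spline polynomials per voxel.
    """
    g = geometry
    out = np.zeros(g.cp_counts + (g.ndim,))
    taps = list(itertools.product(range(4), repeat=g.ndim))
    # per-voxel basis weights along each axis, computed from the polynomials
    axis_weights = [
        [cubic_bspline_weights((x % s) / s) for x in range(n)]
        for n, s in zip(g.image_shape, g.spacing)
    ]
    for cp in itertools.product(*(range(c) for c in g.cp_counts)):
        acc = np.zeros(g.ndim)
        for tap in taps:
            region = tuple(cp[a] - tap[a] for a in range(g.ndim))
            if any(not (0 <= region[a] < g.regions[a]) for a in range(g.ndim)):
                continue
            ranges = [
                range(region[a] * g.spacing[a],
                      min((region[a] + 1) * g.spacing[a], g.image_shape[a]))
                for a in range(g.ndim)
            ]
            for vox in itertools.product(*ranges):
                w = 1.0
                for a in range(g.ndim):
                    w *= axis_weights[a][vox[a]][tap[a]]
                acc += w * voxel_grads[vox]
        out[cp] = acc / g.n_voxels
    return out


def evaluate_cost_and_field(
    mesh: ControlPointMesh,
    reference: np.ndarray,
    moving: np.ndarray,
    luts: LUTSet,
    lam: float = 0.0,
    backend: str = "lut",
):
    """One full evaluation: displacement, warp, cost and mesh gradient.

    Composes displacement interpolation, image warping, the metric and
    the voxel-to-control-point gradient gather.  ``backend`` selects the
    vectorized LUT path (``"lut"``) or the literal per-voxel /
    per-control-point loops (``"naive"``, the testing oracle).

    Returns ``(CostGradient, displacement_field, warped_image)``.
    """
    if backend not in ("lut", "naive"):
        raise ConfigurationError(f"unknown backend {backend!r}")
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if reference.shape != moving.shape:
        raise DomainError(
            f"reference/moving shapes differ: {reference.shape} vs {moving.shape}"
        )
    if mesh.geometry.image_shape != reference.shape:
        raise ConfigurationError("mesh geometry does not match image shape")
    if backend == "lut":
        disp = interpolate_displacement(mesh, luts)
    else:
        disp = interpolate_displacement_naive(mesh)
    warped = warp_image(moving, disp)
    lsd = lsd_cost(reference, warped)
    cost = total_cost(lsd, None, lam)
    vg = voxel_gradient(reference, warped, luts)
    if backend == "lut":
        grad = gather_control_point_gradient(vg, luts)
    else:
        grad = gather_control_point_gradient_naive(vg, mesh.geometry)
    if lam != 0.0:  # pragma: no cover - total_cost already raised
        raise NotImplementedError
    return CostGradient(cost=cost, gradient=grad), disp, warped
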