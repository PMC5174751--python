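"""Cubic B-spline free-form deformation: lattice geometry, basis
evaluation, lookup tables, displacement interpolation and image warping.

The transformation model is the classic FFD: a coarse regular lattice of
control-point displacement coefficients phi, blended by the uniform cubic
B-spline basis, produces a dense per-voxel displacement field

    T(x) = sum over the 4^D neighbouring control points of
           B_i(u_x) * B_j(u_y) [* B_k(u_z)] * phi[region + (i,j[,k])]

where ``region = floor(x / spacing)`` and ``u = x/spacing - region`` is
the normalized local coordinate in [0, 1).  Every voxel of a region
shares the same 4^D supporting control points, which is what makes the
region the natural tile for the accelerated (LUT) evaluation path.

Conventions used throughout the package:

* images and fields are ``float64`` numpy arrays; axis order is
  (x, y[, z]) with axis 0 = x;
* displacement fields have one trailing component axis of length D and
  are expressed in voxels;
* the control lattice has ``regions + 3`` points per axis so that every
  voxel, including those of a ragged last region, has a full 4^D
  support;
* coordinates are 0-based.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DomainError

__all__ = [
    "ImageVolume",
    "LatticeGeometry",
    "ControlPointMesh",
    "LUTSet",
    "cubic_bspline_weights",
    "bspline_weight_table",
    "make_geometry",
    "local_coordinates",
    "build_luts",
    "interpolate_displacement",
    "interpolate_displacement_naive",
    "warp_image",
    "validate_image",
]

#: images and displacement fields are plain ndarrays; these aliases name
#: the roles they play in signatures.
ImageVolume = np.ndarray
DisplacementField = np.ndarray


def validate_image(image: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Check an intensity volume and promote it to float64.

    Requires 2-D or 3-D data, all intensities finite and every axis at
    least 4 voxels long (the minimum for one full cubic-support region).
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim not in (2, 3):
        raise DomainError(f"{name} must be 2-D or 3-D, got {arr.ndim}-D")
    if any(n < 4 for n in arr.shape):
        raise DomainError(f"every axis of {name} must have >= 4 voxels, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite intensities")
    return arr


def cubic_bspline_weights(t: float) -> np.ndarray:
    """The four uniform cubic B-spline basis weights at fraction ``t``.

    Returns ``(B0(t), B1(t), B2(t), B3(t))`` with

        B0 = (1-t)^3 / 6
        B1 = (3t^3 - 6t^2 + 4) / 6
        B2 = (-3t^3 + 3t^2 + 3t + 1) / 6
        B3 = t^3 / 6

    The weights are non-negative and sum to one (partition of unity).

    Raises
    ------
    DomainError
        If ``t`` is outside ``[0, 1)``.
    """
    if not (0.0 <= t < 1.0):
        raise DomainError(f"B-spline fraction must lie in [0, 1), got {t!r}")
    return _weights_vec(np.asarray([t], dtype=np.float64))[0]


def _weights_vec(t: np.ndarray) -> np.ndarray:
    """Vectorized basis weights; t shape (n,) -> (n, 4)."""
    t = np.asarray(t, dtype=np.float64)
    t2 = t * t
    t3 = t2 * t
    out = np.empty(t.shape + (4,), dtype=np.float64)
    out[..., 0] = (1.0 - t) ** 3 / 6.0
    out[..., 1] = (3.0 * t3 - 6.0 * t2 + 4.0) / 6.0
    out[..., 2] = (-3.0 * t3 + 3.0 * t2 + 3.0 * t + 1.0) / 6.0
    out[..., 3] = t3 / 6.0
    return out


def bspline_weight_table(spacing: int) -> np.ndarray:
    """Per-axis weight table: row o holds the 4 weights at t = o/spacing."""
    t = np.arange(spacing, dtype=np.float64) / spacing
    return _weights_vec(t)


@dataclass(frozen=True)
class LatticeGeometry:
    """Regular control-point lattice covering an image.

    ``regions[a] = ceil(image_shape[a] / spacing[a])`` and
    ``cp_counts[a] = regions[a] + 3``: the lattice is padded so every
    voxel has a complete 4^D cubic support.  A 512-voxel axis with
    spacing 16 therefore has 32 regions and 35 control points.
    """

    image_shape: tuple[int, ...]
    spacing: tuple[int, ...]
    regions: tuple[int, ...]
    cp_counts: tuple[int, ...]

    @property
    def ndim(self) -> int:
        return len(self.image_shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.image_shape))

    @property
    def n_regions(self) -> int:
        return int(np.prod(self.regions))

    @property
    def n_control_points(self) -> int:
        return int(np.prod(self.cp_counts))


def make_geometry(image_shape, spacing) -> LatticeGeometry:
    """Build the lattice geometry for an image shape and spacing.

    ``spacing`` may be a scalar (isotropic) or a per-axis sequence of
    integer voxel counts, each at least 2 and at most the axis length.
    """
    shape = tuple(int(n) for n in image_shape)
    if np.isscalar(spacing):
        spc = (int(spacing),) * len(shape)
    else:
        spc = tuple(int(s) for s in spacing)
    if len(spc) != len(shape):
        raise ConfigurationError(
            f"spacing has {len(spc)} entries for a {len(shape)}-D image"
        )
    for n, s in zip(shape, spc):
        if s < 2:
            raise ConfigurationError(f"control-point spacing must be >= 2, got {s}")
        if s > n:
            raise ConfigurationError(
                f"control-point spacing {s} exceeds axis length {n}"
            )
    regions = tuple(math.ceil(n / s) for n, s in zip(shape, spc))
    cp_counts = tuple(r + 3 for r in regions)
    return LatticeGeometry(shape, spc, regions, cp_counts)


def local_coordinates(voxel, geometry: LatticeGeometry):
    """Region index and normalized fraction of a voxel, per axis.

    ``region = floor(x / spacing)`` and ``u = x/spacing - region``; for
    integer voxel coordinates ``u = (x mod spacing) / spacing``, always
    in [0, 1).
    """
    vox = tuple(int(v) for v in voxel)
    if len(vox) != geometry.ndim:
        raise DomainError(f"voxel {vox} has wrong dimensionality")
    for v, n in zip(vox, geometry.image_shape):
        if not (0 <= v < n):
            raise DomainError(f"voxel {vox} outside image of shape {geometry.image_shape}")
    region = tuple(v // s for v, s in zip(vox, geometry.spacing))
    frac = tuple((v % s) / s for v, s in zip(vox, geometry.spacing))
    return region, frac


@dataclass
class ControlPointMesh:
    """Displacement coefficients on the control lattice.

    ``coefficients`` has shape ``cp_counts + (D,)``, in voxel units.
    The canonical flattening (used by the optimizer) is the C-order
    ravel of this array: axis-major, component-last.
    """

    geometry: LatticeGeometry
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        expected = self.geometry.cp_counts + (self.geometry.ndim,)
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != expected:
            raise ConfigurationError(
                f"coefficient array has shape {self.coefficients.shape}, "
                f"expected {expected}"
            )
        if not np.all(np.isfinite(self.coefficients)):
            raise DomainError("control-point coefficients must be finite")

    @classmethod
    def zeros(cls, geometry: LatticeGeometry) -> "ControlPointMesh":
        shape = geometry.cp_counts + (geometry.ndim,)
        return cls(geometry, np.zeros(shape))


@dataclass
class LUTSet:
    """Precomputed tables shared by the accelerated evaluation path.

    * ``basis_products``: for each of the ``prod(spacing)`` within-region
      integer offsets (C order), the 4^D ordered tensor products
      ``B_i(u) B_j(v) [B_k(w)]``.  Each row sums to 1.
    * ``cp_indices``: for each region (C order), the flat indices of its
      4^D supporting control points in the raveled lattice.
    * ``moving_gradient``: central-difference spatial gradient of the
      initial moving image, shape ``image_shape + (D,)``.  The analytic
      similarity gradient keeps using this initial gradient for the
      whole registration.
    """

    geometry: LatticeGeometry
    basis_products: np.ndarray
    cp_indices: np.ndarray
    moving_gradient: np.ndarray
    # derived per-voxel index maps, built lazily: row of basis_products
    # and row of cp_indices for every voxel (flat, C order).
    _voxel_offset_row: np.ndarray | None = field(default=None, repr=False)
    _voxel_region_row: np.ndarray | None = field(default=None, repr=False)

    def voxel_rows(self) -> tuple[np.ndarray, np.ndarray]:
        if self._voxel_offset_row is None:
            g = self.geometry
            axes = [np.arange(n) for n in g.image_shape]
            grids = np.meshgrid(*axes, indexing="ij")
            offs = [grid % s for grid, s in zip(grids, g.spacing)]
            regs = [grid // s for grid, s in zip(grids, g.spacing)]
            self._voxel_offset_row = np.ravel_multi_index(
                [o.ravel() for o in offs], g.spacing
            )
            self._voxel_region_row = np.ravel_multi_index(
                [r.ravel() for r in regs], g.regions
            )
        return self._voxel_offset_row, self._voxel_region_row


def _basis_product_table(geometry: LatticeGeometry) -> np.ndarray:
    per_axis = [bspline_weight_table(s) for s in geometry.spacing]
    if geometry.ndim == 2:
        out = np.einsum("ai,bj->abij", per_axis[0], per_axis[1])
        return out.reshape(-1, 16)
    out = np.einsum("ai,bj,ck->abcijk", per_axis[0], per_axis[1], per_axis[2])
    return out.reshape(-1, 64)


def _cp_index_table(geometry: LatticeGeometry) -> np.ndarray:
    g = geometry
    taps = list(itertools.product(range(4), repeat=g.ndim))
    regions = np.stack(
        np.unravel_index(np.arange(g.n_regions), g.regions), axis=-1
    )  # (n_regions, D)
    table = np.empty((g.n_regions, len(taps)), dtype=np.intp)
    for t, tap in enumerate(taps):
        idx = regions + np.asarray(tap)
        table[:, t] = np.ravel_multi_index(tuple(idx.T), g.cp_counts)
    return table


def build_luts(geometry: LatticeGeometry, moving: ImageVolume) -> LUTSet:
    """Construct the three lookup tables for a geometry / moving image.

    Raises
    ------
    ConfigurationError
        If the moving image shape disagrees with the geometry.
    """
    moving = validate_image(moving, name="moving image")
    if moving.shape != geometry.image_shape:
        raise ConfigurationError(
            f"moving image shape {moving.shape} does not match geometry "
            f"{geometry.image_shape}"
        )
    gradient = np.stack(np.gradient(moving), axis=-1)
    return LUTSet(
        geometry=geometry,
        basis_products=_basis_product_table(geometry),
        cp_indices=_cp_index_table(geometry),
        moving_gradient=gradient,
    )


def interpolate_displacement(mesh: ControlPointMesh, luts: LUTSet) -> DisplacementField:
    """Dense displacement field from a control mesh via the LUT tables.

    Vectorized over voxels: for each of the 4^D taps, gathers the basis
    product from ``basis_products`` and the coefficient through
    ``cp_indices``.  Agrees with the literal per-voxel tensor-product
    loop (:func:`interpolate_displacement_naive`) to float accumulation
    order.
    """
    g = mesh.geometry
    if luts.geometry != g:
        raise ConfigurationError("mesh and LUT set have different geometry")
    off_row, reg_row = luts.voxel_rows()
    phi_flat = mesh.coefficients.reshape(-1, g.ndim)
    bp = luts.basis_products[off_row]  # (Nvox, 4^D)
    cpi = luts.cp_indices[reg_row]  # (Nvox, 4^D)
    field_flat = np.zeros((g.n_voxels, g.ndim))
    for t in range(bp.shape[1]):
        field_flat += bp[:, t, None] * phi_flat[cpi[:, t]]
    return field_flat.reshape(g.image_shape + (g.ndim,))


def interpolate_displacement_naive(mesh: ControlPointMesh) -> DisplacementField:
    """Reference evaluation: explicit per-voxel loop over the 4^D support.

    Slow by design; this is the oracle the LUT path is verified against.
    """
    g = mesh.geometry
    out = np.zeros(g.image_shape + (g.ndim,))
    taps = list(itertools.product(range(4), repeat=g.ndim))
    for vox in itertools.product(*(range(n) for n in g.image_shape)):
        region, frac = local_coordinates(vox, g)
        w_axis = [cubic_bspline_weights(f) for f in frac]
        acc = np.zeros(g.ndim)
        for tap in taps:
            w = 1.0
            for a in range(g.ndim):
                w *= w_axis[a][tap[a]]
            cp = tuple(region[a] + tap[a] for a in range(g.ndim))
            acc += w * mesh.coefficients[cp]
        out[vox] = acc
    return out


def warp_image(moving: np.ndarray, disp: DisplacementField) -> np.ndarray:
    """Resample ``moving`` at ``x + T(x)`` with multilinear interpolation.

    Sample positions outside the image are clamped to the nearest edge
    voxel, so a uniform shift slides intensities in and repeats the
    border value.

    Raises
    ------
    DomainError
        On shape mismatch or non-finite displacement components.
    """
    moving = np.asarray(moving, dtype=np.float64)
    disp = np.asarray(disp, dtype=np.float64)
    if disp.shape != moving.shape + (moving.ndim,):
        raise DomainError(
            f"field shape {disp.shape} does not match image shape {moving.shape}"
        )
    if not np.all(np.isfinite(disp)):
        raise DomainError("displacement field contains non-finite components")
    axes = [np.arange(n, dtype=np.float64) for n in moving.shape]
    grids = np.meshgrid(*axes, indexing="ij")
    coords = [grid + disp[..., a] for a, grid in enumerate(grids)]
    return ndimage.map_coordinates(moving, coords, order=1, mode="nearest")
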