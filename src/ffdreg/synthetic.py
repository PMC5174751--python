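"""Synthetic phantoms, ground-truth deformations, and recovery scoring.

The evaluation protocol: take a reference image, draw a smooth random
deformation field with a prescribed mean displacement magnitude (the
ground truth), warp the reference with it to obtain the moving image,
run the registration, and score the estimated field against the truth.

The ground-truth field is itself a cubic B-spline field, drawn on a
lattice *coarser* than the registration lattice, so it is smooth and
plausibly representable without being trivially inside the search
space, then rescaled exactly to the requested mean magnitude.

Scoring metrics: the per-case field MSE (mean squared Euclidean vector
error per voxel), its mean/standard deviation over repeated cases, and
the normalized RMSE between two fields,

    nRMSE(a, b) = sqrt( sum ||a - b||^2 / sum ||a||^2 )

with the first argument acting as the reference field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bspline import (
    ControlPointMesh,
    build_luts,
    interpolate_displacement,
    make_geometry,
    warp_image,
)
from .errors import ConfigurationError, DomainError
from .optimize import RegistrationConfig, RegistrationResult, run_ncg

__all__ = [
    "SyntheticCase",
    "generate_phantom",
    "generate_ground_truth_field",
    "make_case",
    "recover_field",
    "field_mse",
    "mse_statistics",
    "normalized_rmse",
]

PHANTOM_KINDS = ("blobs", "checkerboard", "gradient")


@dataclass
class SyntheticCase:
    """A reference image, a known deformation, and the warped moving image.

    ``moving`` is exactly ``warp_image(reference, true_field)``: the
    moving image samples the reference at ``x + T_true(x)``.  The field
    that deforms the *reference* onto the moving image is therefore the
    ground truth itself, which is what :func:`recover_field` estimates.
    """

    reference: np.ndarray
    true_field: np.ndarray
    moving: np.ndarray
    seed: int
    mean_magnitude: float


def generate_phantom(shape, kind: str = "blobs", seed: int = 0, *, period: int = 8) -> np.ndarray:
    """Deterministic test image with intensities in [0, 255].

    ``blobs``
        A sum of random Gaussian bumps (centres kept away from the
        border, widths a few percent of the image size), min-max
        rescaled to [0, 255].  Smooth with rich gradients — the default
        for registration experiments.
    ``checkerboard``
        Alternating 0/255 tiles of the given ``period``.
    ``gradient``
        A linear ramp along the sum of normalized coordinates.
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 4 for n in shape):
        raise DomainError(f"phantom axes must be >= 4 voxels, got {shape}")
    if kind not in PHANTOM_KINDS:
        raise ConfigurationError(
            f"unknown phantom kind {kind!r}; expected one of {PHANTOM_KINDS}"
        )
    rng = np.random.default_rng(seed)
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    if kind == "checkerboard":
        tile = sum(g.astype(np.intp) // period for g in grids) % 2
        return tile.astype(np.float64) * 255.0
    if kind == "gradient":
        ramp = sum(g / max(n - 1, 1) for g, n in zip(grids, shape))
        return ramp / len(shape) * 255.0
    # blobs
    n_blobs = int(np.clip(np.prod(shape) / 500.0, 10, 60))
    size = min(shape)
    img = np.zeros(shape)
    for _ in range(n_blobs):
        centre = [rng.uniform(0.15 * n, 0.85 * n) for n in shape]
        sigma = rng.uniform(0.04 * size, 0.10 * size)
        amp = rng.uniform(0.3, 1.0)
        r2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
        img += amp * np.exp(-r2 / (2.0 * sigma**2))
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) * 255.0


def _boundary_taper(shape) -> np.ndarray:
    """Separable raised-cosine window: 0 at the border, 1 in the interior.

    The ramp spans ~10% of each axis (at least 4 voxels) so synthetic
    deformations vanish smoothly at the image edge.
    """
    windows = []
    for n in shape:
        margin = max(4, round(0.1 * n))
        w = np.ones(n)
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(margin) / margin)
        w[:margin] = ramp
        w[n - margin:] = ramp[::-1]
        windows.append(w)
    out = windows[0]
    for w in windows[1:]:
        out = out[..., None] * w
    return out


def generate_ground_truth_field(
    shape, mean_magnitude: float, seed: int = 0, *, control_spacing: int | None = None
) -> np.ndarray:
    """Smooth random displacement field with an exact mean magnitude.

    A coarse control lattice (default spacing a quarter of the longest
    axis, at least 8 voxels) is filled with unit-normal coefficients,
    interpolated to a dense cubic B-spline field, smoothly tapered to
    zero at the image border (deformations never reference content from
    outside the frame), and rescaled so the mean per-voxel Euclidean
    displacement equals ``mean_magnitude``.  Deterministic for a given
    seed.
    """
    shape = tuple(int(n) for n in shape)
    if mean_magnitude < 0:
        raise DomainError(f"mean displacement magnitude must be >= 0, got {mean_magnitude}")
    ndim = len(shape)
    if mean_magnitude == 0.0:
        return np.zeros(shape + (ndim,))
    if control_spacing is None:
        control_spacing = max(max(shape) // 4, 8)
    control_spacing = min(control_spacing, min(shape))
    geometry = make_geometry(shape, control_spacing)
    rng = np.random.default_rng(seed)
    coeffs = rng.standard_normal(geometry.cp_counts + (ndim,))
    mesh = ControlPointMesh(geometry, coeffs)
    luts = build_luts(geometry, np.zeros(shape))
    disp = interpolate_displacement(mesh, luts)
    disp *= _boundary_taper(shape)[..., None]
    mean_norm = float(np.mean(np.linalg.norm(disp, axis=-1)))
    if mean_norm == 0.0:  # vanishing draw: retry deterministically
        return generate_ground_truth_field(
            shape, mean_magnitude, seed + 1, control_spacing=control_spacing
        )
    return disp * (mean_magnitude / mean_norm)


def make_case(
    shape,
    mean_magnitude: float,
    seed: int = 0,
    kind: str = "blobs",
) -> SyntheticCase:
    """Phantom + ground-truth field + warped moving image, from one seed."""
    ss = np.random.SeedSequence(seed)
    img_seed, field_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    reference = generate_phantom(shape, kind=kind, seed=img_seed)
    true_field = generate_ground_truth_field(shape, mean_magnitude, seed=field_seed)
    moving = warp_image(reference, true_field)
    return SyntheticCase(
        reference=reference,
        true_field=true_field,
        moving=moving,
        seed=seed,
        mean_magnitude=mean_magnitude,
    )


def recover_field(
    case: SyntheticCase, config: RegistrationConfig | None = None
) -> RegistrationResult:
    """Estimate the ground-truth field of a synthetic case.

    Because ``moving(x) = reference(x + T_true(x))``, the field that
    deforms the original reference onto the moving image is ``T_true``
    itself.  The registration is therefore run with the moving image as
    the (fixed) target and the reference as the image being deformed,
    so the returned field estimates ``T_true`` directly and
    :func:`field_mse` against ``case.true_field`` is a like-for-like
    comparison.
    """
    return run_ncg(case.moving, case.reference, config)


def field_mse(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Mean over voxels of the squared Euclidean vector error."""
    estimated = np.asarray(estimated, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if estimated.shape != truth.shape:
        raise DomainError(
            f"field shapes differ: {estimated.shape} vs {truth.shape}"
        )
    diff = estimated - truth
    return float(np.mean(np.sum(diff * diff, axis=-1)))


def mse_statistics(cases) -> tuple[float, float]:
    """Sample mean and standard deviation (n-1) of per-case field MSEs.

    ``cases`` is a sequence of ``(estimated, truth)`` field pairs; at
    least two are required for the sample standard deviation.
    """
    cases = list(cases)
    if len(cases) < 2:
        raise DomainError("need at least 2 cases for mean/std statistics")
    mses = np.array([field_mse(est, tru) for est, tru in cases])
    return float(np.mean(mses)), float(np.std(mses, ddof=1))


def normalized_rmse(v_reference: np.ndarray, v_other: np.ndarray) -> float:
    """Normalized RMSE of two displacement fields.

    ``sqrt(sum ||v_ref - v_other||^2 / sum ||v_ref||^2)``; the first
    argument is the field the comparison is normalized by and must not
    be identically zero.
    """
    v_reference = np.asarray(v_reference, dtype=np.float64)
    v_other = np.asarray(v_other, dtype=np.float64)
    if v_reference.shape != v_other.shape:
        raise DomainError(
            f"field shapes differ: {v_reference.shape} vs {v_other.shape}"
        )
    denom = float(np.sum(v_reference * v_reference))
    if denom == 0.0:
        raise DomainError("normalized RMSE undefined for a zero reference field")
    num = float(np.sum((v_reference - v_other) ** 2))
    return float(np.sqrt(num / denom))
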