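"""Nonlinear conjugate-gradient minimization with a hybrid beta.

The search direction is

    d_1 = -g_1,        d_i = -g_i + beta_i * d_{i-1}   (i >= 2)

with the hybrid mixing parameter

    beta = max(0, min(beta_HS, beta_DY))
    beta_HS = g_i . (g_i - g_{i-1}) / d_{i-1} . (g_i - g_{i-1})
    beta_DY = g_i . g_i             / d_{i-1} . (g_i - g_{i-1})

The clamp at zero and a descent guard (reset to -g whenever d . g >= 0)
make every accepted step a descent step, so the accepted cost sequence
is non-increasing.  The step length comes from an inexact backtracking
line search with the Armijo sufficient-decrease condition; the initial
trial step is scaled so the first trial moves no coefficient by more
than ``step_scale`` voxels and subsequently warm-started from the
previous accepted step.

:func:`ncg_minimize` is the generic vector-space driver (pluggable line
search, used directly by the tests with an exact quadratic line
search); :func:`run_ncg` is the registration front end that wires it to
the free-form-deformation cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .bspline import (
    ControlPointMesh,
    build_luts,
    interpolate_displacement,
    interpolate_displacement_naive,
    make_geometry,
    validate_image,
    warp_image,
)
from .errors import ConfigurationError, DomainError
from .similarity import evaluate_cost_and_field, lsd_cost, total_cost

__all__ = [
    "RegistrationConfig",
    "BetaResult",
    "LineSearchResult",
    "IterationRecord",
    "NCGResult",
    "compute_beta",
    "search_direction",
    "line_search",
    "ncg_minimize",
    "run_ncg",
]


@dataclass(frozen=True)
class RegistrationConfig:
    """Settings for a registration run.

    ``spacing`` is the control-point spacing in voxels (scalar or
    per-axis).  ``lam`` is the smoothness-penalty weight; only 0 is
    executable.  ``step_scale`` caps, in voxels, the largest coefficient
    change tried first by the line search.
    """

    spacing: int | Sequence[int] = 10
    lam: float = 0.0
    max_iterations: int = 100
    tolerance: float = 1e-6
    rho: float = 0.5
    c1: float = 1e-4
    max_backtracks: int = 20
    step_scale: float = 1.0
    backend: str = "lut"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam < 1.0):
            raise ConfigurationError(
                f"penalty weight must satisfy 0 <= lambda < 1, got {self.lam}"
            )
        if self.lam != 0.0:
            raise NotImplementedError(
                "smoothness penalty is not implemented; set lam = 0"
            )
        if self.backend not in ("lut", "naive"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass(frozen=True)
class BetaResult:
    beta: float
    beta_hs: float
    beta_dy: float
    restarted: bool


@dataclass(frozen=True)
class LineSearchResult:
    alpha: float
    cost: float
    n_evals: int
    success: bool


@dataclass
class IterationRecord:
    iteration: int
    cost: float
    grad_norm: float
    alpha: float
    beta: float
    restarts: int


@dataclass
class NCGResult:
    x: np.ndarray
    cost: float
    history: list[IterationRecord]
    converged: bool


def compute_beta(g: np.ndarray, g_prev: np.ndarray, d_prev: np.ndarray) -> BetaResult:
    """Hybrid conjugacy parameter ``max(0, min(beta_HS, beta_DY))``.

    A vanishing or non-finite denominator ``d_prev . (g - g_prev)``
    degenerates to ``beta = 0`` (steepest-descent restart).
    """
    g = np.asarray(g, dtype=np.float64).ravel()
    g_prev = np.asarray(g_prev, dtype=np.float64).ravel()
    d_prev = np.asarray(d_prev, dtype=np.float64).ravel()
    y = g - g_prev
    denom = float(d_prev @ y)
    if denom == 0.0 or not np.isfinite(denom):
        return BetaResult(0.0, 0.0, 0.0, True)
    beta_hs = float(g @ y) / denom
    beta_dy = float(g @ g) / denom
    beta = max(0.0, min(beta_hs, beta_dy))
    return BetaResult(beta, beta_hs, beta_dy, beta == 0.0)


def search_direction(
    g: np.ndarray,
    g_prev: np.ndarray | None,
    d_prev: np.ndarray | None,
    iteration: int,
) -> np.ndarray:
    """Conjugate search direction for the given iteration (1-based).

    First iteration: steepest descent.  Later iterations mix in the
    previous direction with the hybrid beta, and fall back to steepest
    descent whenever the result would not be a descent direction.
    """
    g = np.asarray(g, dtype=np.float64).ravel()
    if iteration < 1:
        raise DomainError("iteration index is 1-based")
    if iteration == 1 or g_prev is None or d_prev is None:
        return -g
    beta = compute_beta(g, g_prev, d_prev).beta
    d = -g + beta * np.asarray(d_prev, dtype=np.float64).ravel()
    if float(d @ g) >= 0.0:
        return -g
    return d


def line_search(
    cost_fn: Callable[[np.ndarray], float],
    x: np.ndarray,
    d: np.ndarray,
    g: np.ndarray,
    *,
    alpha0: float = 1.0,
    rho: float = 0.5,
    c1: float = 1e-4,
    max_backtracks: int = 20,
    cost0: float | None = None,
) -> LineSearchResult:
    """Backtracking Armijo line search along a descent direction.

    Tries ``alpha = alpha0 * rho^k`` for k = 0, 1, ... until the
    sufficient-decrease condition
    ``C(x + alpha d) <= C(x) + c1 * alpha * g.d`` holds.  If no trial
    satisfies it within ``max_backtracks`` halvings the last alpha is
    returned flagged unsuccessful.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    d = np.asarray(d, dtype=np.float64).ravel()
    g = np.asarray(g, dtype=np.float64).ravel()
    slope = float(g @ d)
    if slope >= 0.0:
        raise DomainError("line search requires a descent direction (g . d < 0)")
    c0 = cost_fn(x) if cost0 is None else float(cost0)
    alpha = float(alpha0)
    n_evals = 0
    cost = np.inf
    for _ in range(max_backtracks + 1):
        cost = float(cost_fn(x + alpha * d))
        n_evals += 1
        if cost <= c0 + c1 * alpha * slope:
            return LineSearchResult(alpha, cost, n_evals, True)
        alpha *= rho
    warnings.warn(
        "line search found no sufficient decrease within "
        f"{max_backtracks} backtracks", RuntimeWarning, stacklevel=2,
    )
    # report the last alpha actually evaluated
    return LineSearchResult(alpha / rho, cost, n_evals, False)


def ncg_minimize(
    cost_fn: Callable[[np.ndarray], float],
    grad_fn: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    *,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
    rho: float = 0.5,
    c1: float = 1e-4,
    max_backtracks: int = 20,
    step_scale: float | None = None,
    line_search_fn: Callable[..., LineSearchResult] | None = None,
) -> NCGResult:
    """Minimize a smooth function with hybrid-beta nonlinear CG.

    ``step_scale``, when given, sets the first trial step to
    ``step_scale / max|d|`` (i.e. the first trial changes no coordinate
    by more than ``step_scale``); later iterations warm-start from twice
    the previously accepted step.  With ``step_scale=None`` every line
    search starts at ``alpha0 = 1``.  ``line_search_fn`` may replace the
    Armijo search (e.g. an exact quadratic line search in tests); it
    must accept ``(cost_fn, x, d, g, alpha0=..., cost0=...)`` keywords it
    understands and return a :class:`LineSearchResult`.

    The lowest-cost iterate visited is returned; the accepted cost
    sequence is non-increasing by construction.
    """
    ls = line_search_fn or line_search
    x = np.asarray(x0, dtype=np.float64).ravel().copy()
    cost = float(cost_fn(x))
    if not np.isfinite(cost):
        raise DomainError("initial cost is not finite")
    g = np.asarray(grad_fn(x), dtype=np.float64).ravel()
    history: list[IterationRecord] = [
        IterationRecord(0, cost, float(np.max(np.abs(g))) if g.size else 0.0, 0.0, 0.0, 0)
    ]
    best_x, best_cost = x.copy(), cost
    if float(np.max(np.abs(g))) < tolerance:
        return NCGResult(best_x, best_cost, history, True)
    d = -g
    restarts = 0
    alpha_prev: float | None = None
    converged = False
    for i in range(1, max_iterations + 1):
        if step_scale is None:
            alpha0 = 1.0
        elif alpha_prev is None:
            dmax = float(np.max(np.abs(d)))
            alpha0 = step_scale / dmax if dmax > 0 else 1.0
        else:
            alpha0 = 2.0 * alpha_prev
        result = ls(
            cost_fn, x, d, g,
            alpha0=alpha0, rho=rho, c1=c1, max_backtracks=max_backtracks,
            cost0=cost,
        )
        if not result.success or not np.isfinite(result.cost):
            break  # no sufficient decrease: treat as converged at x
        x = x + result.alpha * d
        cost = result.cost
        alpha_prev = result.alpha
        g_new = np.asarray(grad_fn(x), dtype=np.float64).ravel()
        if not np.all(np.isfinite(g_new)):
            raise DomainError(f"non-finite gradient at iteration {i}")
        beta_res = compute_beta(g_new, g, d)
        beta = beta_res.beta
        d_new = -g_new + beta * d
        restarted = beta_res.restarted
        if float(d_new @ g_new) >= 0.0:
            d_new = -g_new
            restarted = True
        if restarted:
            restarts += 1
        grad_norm = float(np.max(np.abs(g_new)))
        history.append(IterationRecord(i, cost, grad_norm, result.alpha, beta, restarts))
        if cost < best_cost:
            best_cost, best_x = cost, x.copy()
        g, d = g_new, d_new
        if grad_norm < tolerance:
            converged = True
            break
    return NCGResult(best_x, best_cost, history, converged)


@dataclass
class RegistrationResult:
    """Outcome of :func:`run_ncg`."""

    mesh: ControlPointMesh
    field: np.ndarray
    warped: np.ndarray
    cost: float
    history: list[IterationRecord]
    converged: bool


def run_ncg(
    reference: np.ndarray,
    moving: np.ndarray,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Register ``moving`` onto ``reference``.

    Minimizes the log-squared-difference cost over the control-point
    coefficients, starting from the zero mesh.  Returns the lowest-cost
    mesh visited, its dense displacement field and warped image, and the
    per-iteration history (iteration, cost, gradient infinity-norm,
    step, beta, cumulative restarts).

    Identical images terminate immediately: the initial cost and
    gradient are both zero.
    """
    config = config or RegistrationConfig()
    reference = validate_image(reference, name="reference image")
    moving = validate_image(moving, name="moving image")
    if reference.shape != moving.shape:
        raise DomainError(
            f"reference/moving shapes differ: {reference.shape} vs {moving.shape}"
        )
    geometry = make_geometry(reference.shape, config.spacing)
    luts = build_luts(geometry, moving)
    mesh_shape = geometry.cp_counts + (geometry.ndim,)

    def to_mesh(x: np.ndarray) -> ControlPointMesh:
        return ControlPointMesh(geometry, x.reshape(mesh_shape))

    def cost_fn(x: np.ndarray) -> float:
        # cost-only path for the line search: no gradient gather
        mesh = to_mesh(x)
        if config.backend == "lut":
            disp = interpolate_displacement(mesh, luts)
        else:
            disp = interpolate_displacement_naive(mesh)
        warped = warp_image(moving, disp)
        return total_cost(lsd_cost(reference, warped), None, config.lam)

    def grad_fn(x: np.ndarray) -> np.ndarray:
        cg, _, _ = evaluate_cost_and_field(
            to_mesh(x), reference, moving, luts,
            lam=config.lam, backend=config.backend,
        )
        return cg.gradient.ravel()

    x0 = np.zeros(int(np.prod(mesh_shape)))
    res = ncg_minimize(
        cost_fn, grad_fn, x0,
        max_iterations=config.max_iterations,
        tolerance=config.tolerance,
        rho=config.rho, c1=config.c1,
        max_backtracks=config.max_backtracks,
        step_scale=config.step_scale,
    )
    mesh = to_mesh(res.x)
    cg, disp, warped = evaluate_cost_and_field(
        mesh, reference, moving, luts, lam=config.lam, backend=config.backend
    )
    return RegistrationResult(
        mesh=mesh, field=disp, warped=warped, cost=cg.cost,
        history=res.history, converged=res.converged,
    )
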