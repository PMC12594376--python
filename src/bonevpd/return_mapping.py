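"""Strain-driven return-mapping integration of one time step.

The step is an elastic-predictor / plastic-corrector scheme: the elastic
trial stress is computed first; if it lies inside the (generalized) yield
surface the step is elastic and the trial is accepted.  Otherwise the
three-block nonlinear system

    Ybar(sigma, gamma, kappa)  = 0        (generalized yield)
    R(sigma, gamma, kappa)     = 0        (strain-dimensioned stress residual)
    h(sigma, gamma, kappa)     = 0        (accumulated plastic strain update)

is solved for x = [sigma(6), gamma, kappa] by a Newton-Raphson iteration
started from the trial state.  Convergence requires both the full residual
measure res = Ybar^2 + |R|^2 + h^2 < tol1 and |Ybar| < tol2 (defaults
1e-6 and 1e-8).

The stress residual reads

    R = E sigma_t / (1 - D(kappa_n)) - E sigma / (1 - D(kappa)) - dt gamma dY/dsigma

with E the undamaged compliance, so that R is a strain quantity: the first
term is the total-minus-plastic strain at the step start, the second the
elastic strain of the candidate state, and the third the plastic strain
increment of the flow rule.  The trial state zeroes R and h exactly, and a
converged state satisfies the damaged-elastic law and the flow rule
simultaneously.  Damage is evaluated at the unknown kappa inside the loop
(not frozen at the step start), keeping stress and damage consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constitutive as con
from .parameters import MaterialParameters, MaterialState, ParameterError

__all__ = [
    "SolverSettings",
    "StepResult",
    "StepContext",
    "ConvergenceError",
    "elastic_trial",
    "residual_vector",
    "jacobian",
    "integrate_step",
]


@dataclass(frozen=True)
class SolverSettings:
    """Newton solver tolerances and options.

    ``tol1`` bounds the full residual measure (sum of squares of the
    8-component residual); ``tol2`` bounds |Ybar| alone and must be the
    tighter of the two.  ``jacobian_mode`` selects the analytic Jacobian
    (default) or central finite differences with relative perturbation 1e-7.
    """

    tol1: float = 1e-6
    tol2: float = 1e-8
    max_iter: int = 50
    jacobian_mode: str = "analytic"

    def __post_init__(self) -> None:
        if not self.tol2 < self.tol1:
            raise ParameterError("tol2 must be smaller than tol1")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.jacobian_mode not in ("analytic", "finite_difference"):
            raise ParameterError(f"unknown jacobian_mode {self.jacobian_mode!r}")


@dataclass
class StepResult:
    """Outcome of one integrated step.

    ``residual_norm`` is the converged value of the full residual measure
    (Ybar^2 + |R|^2 + h^2); for elastic steps it is 0 by construction and
    ``gamma`` = 0 with ``iterations`` = 0.
    """

    state: MaterialState
    regime: str
    iterations: int
    residual_norm: float
    gamma: float
    ybar: float = 0.0


@dataclass
class StepContext:
    """Frozen inputs of one step: start state, target strain, dt, material."""

    state_n: MaterialState
    eps_new: np.ndarray
    dt: float
    params: MaterialParameters
    mode: str | None = None


class ConvergenceError(RuntimeError):
    """Newton failure; carries the last residual measure and iteration count."""

    def __init__(self, message: str, residual: float = np.nan, iterations: int = 0):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


def elastic_trial(
    state_n: MaterialState, eps_new: np.ndarray, params: MaterialParameters
) -> np.ndarray:
    """Trial stress sigma_t = (1 - D(kappa_n)) S (eps_new - eps_p_n)."""
    eps_new = np.asarray(eps_new, dtype=float).reshape(6)
    return (1.0 - state_n.D) * (params.stiffness @ (eps_new - state_n.eps_p))


def _unpack(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    x = np.asarray(x, dtype=float).reshape(8)
    return x[:6], float(x[6]), float(x[7])


def residual_vector(x: np.ndarray, ctx: StepContext) -> np.ndarray:
    """8-vector b = [Ybar; R(6); h] at x = [sigma, gamma, kappa]."""
    sigma, gamma, kappa = _unpack(x)
    p = ctx.params
    D = con._damage(kappa, p.damage)
    if D >= 1.0 - 1e-12:
        raise ConvergenceError("material point fully damaged (D >= 1)")
    r = con._hardening(kappa, p.hardening, ctx.mode)
    yt = p.yield_tensors
    q = sigma - r * yt.A
    w = yt.Afour @ q
    n2 = float(q @ w)
    if n2 <= 0.0:
        raise ConvergenceError("iterate reached the yield-surface centre")
    n = np.sqrt(n2)
    grad = w / n
    ybar = (n - r) - con._phi(gamma, p.viscosity)

    eps_eff_trial = ctx.eps_new - ctx.state_n.eps_p
    R = eps_eff_trial - (p.compliance @ sigma) / (1.0 - D) - ctx.dt * gamma * grad
    h = ctx.state_n.kappa - kappa + ctx.dt * gamma * con.flow_norm(grad)

    b = np.empty(8)
    b[0] = ybar
    b[1:7] = R
    b[7] = h
    return b


def _fd_jacobian(x: np.ndarray, ctx: StepContext) -> np.ndarray:
    x = np.asarray(x, dtype=float).reshape(8)
    B = np.empty((8, 8))
    for i in range(8):
        h = 1e-7 * max(abs(x[i]), 1.0)
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        B[:, i] = (residual_vector(xp, ctx) - residual_vector(xm, ctx)) / (2.0 * h)
    return B


def _analytic_jacobian(x: np.ndarray, ctx: StepContext) -> np.ndarray:
    sigma, gamma, kappa = _unpack(x)
    p = ctx.params
    yt = p.yield_tensors
    dt = ctx.dt

    D = con._damage(kappa, p.damage)
    Dp = con._damage_prime(kappa, p.damage)
    r = con._hardening(kappa, p.hardening, ctx.mode)
    rp = con._hardening_prime(kappa, p.hardening, ctx.mode)

    q = sigma - r * yt.A
    w = yt.Afour @ q
    n2 = float(q @ w)
    if n2 <= 0.0:
        raise ConvergenceError("iterate reached the yield-surface centre")
    n = np.sqrt(n2)
    grad = w / n

    # d(grad)/d(q): (Afour - grad grad^T Afour-projected) / n
    dgrad_dq = (yt.Afour - np.outer(grad, grad)) / n
    dq_dkappa = -rp * yt.A
    dgrad_dsigma = dgrad_dq
    dgrad_dkappa = dgrad_dq @ dq_dkappa

    W = con.FLOW_NORM_WEIGHTS
    nw = con.flow_norm(grad)
    dnw_dgrad = (W * grad) / nw

    B = np.zeros((8, 8))
    # Ybar row: Y = n - r, phi(gamma)
    B[0, :6] = grad
    B[0, 6] = -con._phi_prime(gamma, p.viscosity)
    B[0, 7] = rp * float(grad @ (-yt.A)) - rp
    # R rows
    B[1:7, :6] = -p.compliance / (1.0 - D) - dt * gamma * dgrad_dsigma
    B[1:7, 6] = -dt * grad
    B[1:7, 7] = -(p.compliance @ sigma) * Dp / (1.0 - D) ** 2 - dt * gamma * dgrad_dkappa
    # h row
    B[7, :6] = dt * gamma * (dnw_dgrad @ dgrad_dsigma)
    B[7, 6] = dt * nw
    B[7, 7] = -1.0 + dt * gamma * float(dnw_dgrad @ dgrad_dkappa)
    return B


def jacobian(x: np.ndarray, ctx: StepContext, settings: SolverSettings | None = None) -> np.ndarray:
    """8x8 Jacobian of the residual; analytic or central finite differences."""
    settings = settings or SolverSettings()
    if settings.jacobian_mode == "analytic":
        return _analytic_jacobian(x, ctx)
    return _fd_jacobian(x, ctx)


def integrate_step(
    state_n: MaterialState,
    eps_new: np.ndarray,
    dt: float,
    params: MaterialParameters,
    settings: SolverSettings | None = None,
    mode: str | None = None,
) -> StepResult:
    """Integrate one strain-driven step from ``state_n`` to strain ``eps_new``.

    Returns an elastic acceptance of the trial when the trial overstress is
    non-positive, otherwise the Newton-corrected viscoplastic state.  Raises
    :class:`ConvergenceError` when Newton stalls (callers may sub-step).
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    settings = settings or SolverSettings()
    eps_new = np.asarray(eps_new, dtype=float).reshape(6)

    sigma_t = elastic_trial(state_n, eps_new, params)
    y_trial = con.yield_value(sigma_t, state_n.kappa, params.yield_tensors, params.hardening, mode)
    if y_trial <= 0.0:
        new_state = MaterialState(sigma_t, state_n.eps_p.copy(), state_n.kappa, state_n.D)
        return StepResult(new_state, "elastic", 0, 0.0, 0.0, ybar=y_trial)

    ctx = StepContext(state_n, eps_new, dt, params, mode)
    x = np.empty(8)
    x[:6] = sigma_t
    x[6] = 0.0
    x[7] = state_n.kappa

    res = np.inf
    b = None
    for it in range(settings.max_iter + 1):
        b = residual_vector(x, ctx)
        if not np.all(np.isfinite(b)):
            raise ConvergenceError("non-finite residual", residual=res, iterations=it)
        res = float(b @ b)
        if res < settings.tol1 and abs(b[0]) < settings.tol2:
            break
        if it == settings.max_iter:
            raise ConvergenceError(
                f"Newton did not converge in {settings.max_iter} iterations "
                f"(res={res:.3e}, |Ybar|={abs(b[0]):.3e})",
                residual=res,
                iterations=it,
            )
        B = jacobian(x, ctx, settings)
        try:
            dx = np.linalg.solve(B, b)
        except np.linalg.LinAlgError:
            cond = np.linalg.cond(B)
            raise ConvergenceError(
                f"singular Jacobian (condition number {cond:.3e})",
                residual=res,
                iterations=it,
            ) from None
        x = x - dx
    iterations = it

    sigma, gamma, kappa = _unpack(x)
    if gamma < 0.0:
        if gamma < -1e-10:
            raise ConvergenceError(
                f"converged to negative gamma {gamma:.3e}", residual=res, iterations=iterations
            )
        gamma = 0.0
    if kappa < state_n.kappa:
        if kappa < state_n.kappa - 1e-10:
            raise ConvergenceError(
                f"kappa decreased from {state_n.kappa:.6e} to {kappa:.6e}",
                residual=res,
                iterations=iterations,
            )
        kappa = state_n.kappa

    grad = con.yield_gradient(sigma, kappa, params.yield_tensors, params.hardening, mode)
    eps_p = state_n.eps_p + dt * gamma * grad
    D = con.damage_value(kappa, params.damage)
    new_state = MaterialState(sigma, eps_p, kappa, D)
    return StepResult(new_state, "plastic", iterations, res, gamma, ybar=float(b[0]))
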