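"""Taylor linearization at a fixed point and its linear-algebra services.

Around a steady state ``(x_ss, u_bf)`` the first-order model is

    d(x - x_ss)/dt = A (x - x_ss) + B (u - u_bf),
    A = df/dx|_(x_ss, u_bf),   B = df/du,

with all second- and higher-order state terms discarded.  Because the
mass-action grammar keeps B constant and A independent of u, the expansion
is exact in the input directions.  For a step input with final value
``u_final`` the linear model's new steady state follows from one linear
solve,

    x_dev_ss = -A^{-1} B (u_final - u_bf),

and the inverse ("required input deviation") problem solves
``B du = -A dx_target`` in the least-squares sense.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.linalg import expm, lstsq

from .errors import (
    ConfigurationError,
    DimensionError,
    NonConvergenceError,
    SingularityError,
)
from .reaction_model import ReactionNetwork, input_jacobian, state_jacobian
from .simulation import SteadyState

__all__ = [
    "LinearModel",
    "HyperbolicityReport",
    "InputDeviation",
    "linearize",
    "linear_steady_state",
    "clip_nonnegative",
    "check_hyperbolic",
    "iterative_relinearization",
    "required_input_deviation",
]

#: condition-number ceiling beyond which A is treated as singular
COND_LIMIT = 1e12


@dataclass(frozen=True)
class LinearModel:
    """State-space pair (A, B) anchored at a fixed point."""

    A: np.ndarray
    B: np.ndarray
    x_ss: np.ndarray
    u_bf: np.ndarray

    @cached_property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]

    def f_linear(self, x, u) -> np.ndarray:
        """First-order RHS at an arbitrary state/input."""
        return self.A @ (np.asarray(x) - self.x_ss) + self.B @ (np.asarray(u) - self.u_bf)

    @property
    def stable(self) -> bool:
        return check_hyperbolic(self).stable

    @property
    def hyperbolic(self) -> bool:
        return check_hyperbolic(self).hyperbolic


@dataclass(frozen=True)
class HyperbolicityReport:
    hyperbolic: bool
    stable: bool
    eigenvalues: np.ndarray
    tol_re: float


@dataclass(frozen=True)
class InputDeviation:
    """Solution of the inverse problem B du = -A dx_target."""

    delta_u: np.ndarray
    residual: float   # ||B du + A dx_target||_2; > 0 flags an unreachable target


def linearize(network: ReactionNetwork, ss: SteadyState, residual_tol: float = 1e-6) -> LinearModel:
    """Build the Taylor linearization anchored at a steady state."""
    scale = 1.0 + np.linalg.norm(ss.x_ss, np.inf)
    if ss.residual_norm > residual_tol * scale:
        raise ConfigurationError(
            f"anchor is not a steady state: residual {ss.residual_norm:.3g} "
            f"exceeds {residual_tol:g}*(1+||x||)"
        )
    A = state_jacobian(network, ss.x_ss)
    B = input_jacobian(network)
    return LinearModel(A=A, B=B, x_ss=ss.x_ss.copy(), u_bf=ss.u_bf.copy())


def _checked_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise SingularityError(
            f"state matrix is singular or ill-conditioned (cond={cond:.3g}); "
            "the anchor is not hyperbolic"
        )
    return np.linalg.solve(A, b)


def linear_steady_state(lin: LinearModel, u_final) -> np.ndarray:
    """Predict the linear model's new steady state for a step input.

    One dense linear solve of ``A x_dev = -B (u_final - u_bf)``; no
    integration.  The prediction is *not* clipped — pass it through
    :func:`clip_nonnegative` before comparing with nonlinear states.
    """
    u_final = np.asarray(u_final, dtype=float)
    if u_final.shape != (lin.m,):
        raise DimensionError(
            f"u_final has shape {u_final.shape}, expected ({lin.m},)"
        )
    x_dev = _checked_solve(lin.A, -lin.B @ (u_final - lin.u_bf))
    return lin.x_ss + x_dev


def clip_nonnegative(x_pred) -> np.ndarray:
    """Componentwise max(x, 0); negative concentrations are unphysical."""
    return np.maximum(np.asarray(x_pred, dtype=float), 0.0)


def check_hyperbolic(lin: LinearModel, tol_re: float | None = None) -> HyperbolicityReport:
    """Classify the anchor: hyperbolic iff no eigenvalue real part is ~0.

    ``tol_re`` defaults to ``1e-8 * spectral radius`` (with a tiny floor),
    scaling the zero test to the system's timescales.
    """
    eig = lin.eigenvalues
    if tol_re is None:
        rho = float(np.max(np.abs(eig), initial=0.0))
        tol_re = 1e-8 * rho if rho > 0 else 1e-12
    re = eig.real
    return HyperbolicityReport(
        hyperbolic=bool(np.min(np.abs(re)) > tol_re),
        stable=bool(np.max(re) < -tol_re),
        eigenvalues=eig,
        tol_re=tol_re,
    )


def iterative_relinearization(
    network: ReactionNetwork,
    u_final,
    ss0: SteadyState,
    dt_schedule=None,
    tol: float = 1e-10,
    max_steps: int = 20000,
    t_final: float | None = None,
    require_stable: bool = True,
    return_path: bool = False,
):
    """Piecewise-linear path to the perturbed steady state.

    At each step the model is re-expanded at the current state ``x_k``:
    ``f(x) ~ f(x_k, u) + J(x_k)(x - x_k)``, and the frozen-Jacobian system
    is advanced *exactly* over ``dt`` (matrix exponential),

        x_{k+1} = x_k + (e^{J dt} - I) J^{-1} f(x_k, u).

    With ``dt_schedule=None`` each step jumps straight to the frozen
    model's own fixed point (the dt -> infinity limit, a Newton step); for
    a constant Jacobian this returns the one-solve step prediction after a
    single step.  Iteration stops when ``||x_{k+1}-x_k||_inf`` drops below
    ``tol*(1+||x||_inf)``, or at ``t_final`` if a fixed horizon is given.

    With ``return_path=True`` the visited times and anchors are returned
    as ``(x, t_path, x_path)`` so the piecewise-linear trajectory can be
    compared against the nonlinear one (the per-step truncation error
    shrinks as the increments shrink).
    """
    u_final = np.asarray(u_final, dtype=float)
    x = ss0.x_ss.astype(float).copy()
    if np.isscalar(dt_schedule) or dt_schedule is None:
        schedule = None if dt_schedule is None else [float(dt_schedule)]
    else:
        schedule = [float(d) for d in dt_schedule]
        if not schedule:
            raise ConfigurationError("dt_schedule must not be empty")
    t = 0.0
    eye = np.eye(network.n_species)
    t_path = [0.0]
    x_path = [x.copy()]

    def _done(x_final):
        if return_path:
            return x_final, np.asarray(t_path), np.asarray(x_path)
        return x_final

    for step in range(max_steps):
        A = network.jac(x)
        fx = network.rhs(x, u_final)
        if require_stable:
            if np.max(np.linalg.eigvals(A).real) >= 0:
                raise NonConvergenceError(
                    f"anchor at step {step} is not stable; relinearization path left "
                    "the stable region"
                )
        if schedule is None:
            dx = -_checked_solve(A, fx)
        else:
            dt = schedule[min(step, len(schedule) - 1)]
            dx = (expm(A * dt) - eye) @ _checked_solve(A, fx)
            t += dt
        x = x + dx
        t_path.append(t)
        x_path.append(x.copy())
        if t_final is not None:
            if t >= t_final - 1e-12:
                return _done(x)
            continue
        if np.linalg.norm(dx, np.inf) < tol * (1.0 + np.linalg.norm(x, np.inf)):
            return _done(x)
    raise NonConvergenceError(
        f"relinearization did not converge within {max_steps} steps"
    )


def required_input_deviation(lin: LinearModel, delta_x_target) -> InputDeviation:
    """Minimum-norm input deviation producing a desired steady-state shift.

    Solves ``B du = -A dx_target`` by least squares; a nonzero residual
    means the target state deviation is not reachable through the inputs.
    """
    dx = np.asarray(delta_x_target, dtype=float)
    if dx.shape != (lin.n,):
        raise DimensionError(
            f"delta_x_target has shape {dx.shape}, expected ({lin.n},)"
        )
    if not np.any(lin.B):
        raise ConfigurationError("input matrix B is zero: no actuation available")
    rhs = -lin.A @ dx
    du, _, _, _ = lstsq(lin.B, rhs)
    residual = float(np.linalg.norm(lin.B @ du - rhs))
    return InputDeviation(delta_u=du, residual=residual)
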