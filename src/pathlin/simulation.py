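"""Stiff forward simulation, steady-state detection and the agreement system.

Steady states solve ``0 = f(x_ss, u_bf)`` for a frozen ("step-like")
input.  They are located by implicit integration (variable-order BDF with
the analytic Jacobian) until the residual test

    ||f(x)||_inf < tol_ss * (1 + ||x||_inf)

passes, then polished with a damped Newton iteration on ``f``.

The *agreement system* stacks the linearized deviation dynamics on top of
the nonlinear dynamics,

    d/dt [x_dev; x_nonlin] = [A x_dev + B (u - u_bf);  f(x_nonlin, u)],

started from ``[0; x_ss]`` so both halves sit at the linearization point
at t = 0.  Its trajectory directly exposes the linearization error
``e(t) = x_nonlin(t) - x_dev(t) - x_ss``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import block_diag

from .errors import (
    DimensionError,
    InstabilityError,
    IntegrationError,
    NonConvergenceError,
)
from .reaction_model import ReactionNetwork

__all__ = [
    "SteadyState",
    "AgreementSystem",
    "AgreementResult",
    "simulate_to_steady_state",
    "simulate_trajectory",
    "build_agreement_system",
    "simulate_agreement",
]

#: componentwise divergence guard, relative to the initial scale
DIVERGENCE_FACTOR = 1e9


@dataclass(frozen=True)
class SteadyState:
    """Fixed point of the nonlinear model for a frozen input."""

    x_ss: np.ndarray
    u_bf: np.ndarray
    residual_norm: float
    t_converged: float
    method: str = "integrate+newton"

    @property
    def n(self) -> int:
        return self.x_ss.shape[0]


@dataclass(frozen=True)
class AgreementResult:
    """Joint trajectory of the agreement system and its steady state."""

    t: np.ndarray            # time grid, shape (nt,)
    x_dev: np.ndarray        # (nt, n) linear deviation states
    x_nonlin: np.ndarray     # (nt, n) nonlinear states
    x_ss: np.ndarray         # linearization anchor
    x_dev_ss: np.ndarray     # steady-state deviation of the linear model
    x_nonlin_ss: np.ndarray  # steady-state of the nonlinear model

    @property
    def e(self) -> np.ndarray:
        """Linearization error e(t) = x_nonlin - x_dev - x_ss."""
        return self.x_nonlin - self.x_dev - self.x_ss[None, :]

    @property
    def e_ss(self) -> np.ndarray:
        return self.x_nonlin_ss - self.x_dev_ss - self.x_ss


def _newton_refine(rhs, jac, x, max_iter=50, tol=1e-13):
    """Damped Newton polish of a root of ``rhs``; returns (x, ||rhs||_inf)."""
    fx = rhs(x)
    norm = np.linalg.norm(fx, np.inf)
    for _ in range(max_iter):
        scale = tol * (1.0 + np.linalg.norm(x, np.inf))
        if norm < scale:
            break
        try:
            step = np.linalg.solve(jac(x), -fx)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        for _ in range(30):
            x_new = x + lam * step
            f_new = rhs(x_new)
            n_new = np.linalg.norm(f_new, np.inf)
            if n_new < norm:
                x, fx, norm = x_new, f_new, n_new
                break
            lam *= 0.5
        else:
            break
    return x, norm


def _integrate_until_steady(rhs, jac, x0, tol_ss, t_max, scale0):
    """Chunked BDF integration until the residual criterion passes."""
    x = np.asarray(x0, dtype=float).copy()
    t = 0.0
    t_next = 1.0
    while True:
        res = np.linalg.norm(rhs(x), np.inf)
        if res < tol_ss * (1.0 + np.linalg.norm(x, np.inf)):
            return x, t
        if t >= t_max:
            raise NonConvergenceError(
                f"no steady state within t_max={t_max:g} "
                f"(residual {res:.3g}); the model may be unstable or oscillatory"
            )
        t_next = min(max(t_next, 10.0 * max(t, 0.1)), t_max)
        sol = solve_ivp(
            lambda _t, y: rhs(y),
            (t, t_next),
            x,
            method="BDF",
            jac=lambda _t, y: jac(y),
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise IntegrationError(f"BDF failed on [{t:g}, {t_next:g}]: {sol.message}")
        x = sol.y[:, -1]
        t = sol.t[-1]
        if np.linalg.norm(x, np.inf) > DIVERGENCE_FACTOR * scale0:
            raise InstabilityError(
                f"trajectory norm exceeded {DIVERGENCE_FACTOR:g} x initial scale at t={t:g}"
            )


def simulate_to_steady_state(
    network: ReactionNetwork,
    u,
    x0=None,
    tol_ss: float = 1e-9,
    t_max: float = 1e7,
) -> SteadyState:
    """Integrate the nonlinear model under a frozen input to its fixed point.

    BDF integration with the analytic Jacobian runs in geometrically
    growing time chunks until ``||f||_inf < tol_ss*(1 + ||x||_inf)``; the
    root is then polished by damped Newton and tiny negative components
    (integrator noise) are clipped to zero.
    """
    u = np.asarray(u, dtype=float)
    if x0 is None:
        x0 = np.zeros(network.n_species)
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise DimensionError("initial state must be componentwise nonnegative")
    rhs = lambda y: network.rhs(y, u)
    jac = network.jac
    scale0 = max(1.0, np.linalg.norm(x0, np.inf), float(np.max(u, initial=0.0)))
    x, t = _integrate_until_steady(rhs, jac, x0, tol_ss, t_max, scale0)
    x, res = _newton_refine(rhs, jac, x)
    neg = x < 0
    if np.any(x[neg] < -1e-6 * max(1.0, np.linalg.norm(x, np.inf))):
        raise NonConvergenceError(
            "steady-state refinement produced significantly negative components"
        )
    x[neg] = 0.0
    res = float(np.linalg.norm(rhs(x), np.inf))
    return SteadyState(
        x_ss=x, u_bf=u.copy(), residual_norm=res, t_converged=t,
        method="integrate+newton",
    )


def simulate_trajectory(network: ReactionNetwork, u, x0, t_grid) -> np.ndarray:
    """Dense nonlinear trajectory at the requested times (shape nt x n)."""
    u = np.asarray(u, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        lambda _t, y: network.rhs(y, u),
        (float(t_grid[0]), float(t_grid[-1])),
        x0,
        method="BDF",
        jac=lambda _t, y: network.jac(y),
        t_eval=t_grid,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise IntegrationError(f"trajectory integration failed: {sol.message}")
    return sol.y.T


class AgreementSystem:
    """Augmented 2n-state model co-evolving linear and nonlinear halves."""

    def __init__(self, network: ReactionNetwork, linmodel):
        n = network.n_species
        if linmodel.A.shape != (n, n) or linmodel.B.shape != (n, network.n_inputs):
            raise DimensionError(
                "linear model dimensions do not match the network"
            )
        self.network = network
        self.lin = linmodel
        self.n = n

    def rhs(self, z, u):
        xd, xn = z[: self.n], z[self.n :]
        lin = self.lin
        return np.concatenate(
            (lin.A @ xd + lin.B @ (u - lin.u_bf), self.network.rhs(xn, u))
        )

    def jac(self, z):
        xn = z[self.n :]
        return block_diag(self.lin.A, self.network.jac(xn))

    def initial_state(self):
        """[0; x_ss]: both halves start at the linearization point."""
        return np.concatenate((np.zeros(self.n), self.lin.x_ss.copy()))


def build_agreement_system(network: ReactionNetwork, linmodel) -> AgreementSystem:
    return AgreementSystem(network, linmodel)


def simulate_agreement(
    augmented: AgreementSystem,
    u,
    t_max: float = 1e7,
    tol_ss: float = 1e-9,
    n_save: int = 201,
) -> AgreementResult:
    """Integrate the agreement system to its joint steady state.

    The trajectory is integrated with BDF (block-diagonal Jacobian) until
    both halves satisfy the residual test, then each half's fixed point is
    refined exactly: the linear deviation via one linear solve, the
    nonlinear state via damped Newton.
    """
    u = np.asarray(u, dtype=float)
    n = augmented.n
    z0 = augmented.initial_state()
    rhs = lambda z: augmented.rhs(z, u)
    jac = augmented.jac
    scale0 = max(
        1.0,
        np.linalg.norm(z0, np.inf),
        float(np.max(u, initial=0.0)),
    )
    # integrate in chunks, saving a coarse trajectory for inspection
    z = z0.copy()
    t = 0.0
    t_next = 1.0
    ts = [0.0]
    zs = [z0.copy()]
    while True:
        res = np.linalg.norm(rhs(z), np.inf)
        if res < tol_ss * (1.0 + np.linalg.norm(z, np.inf)):
            break
        if t >= t_max:
            raise NonConvergenceError(
                f"agreement system did not reach steady state within t_max={t_max:g}"
            )
        t_next = min(max(t_next, 10.0 * max(t, 0.1)), t_max)
        sol = solve_ivp(
            lambda _t, y: rhs(y),
            (t, t_next),
            z,
            method="BDF",
            jac=lambda _t, y: jac(y),
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise IntegrationError(f"agreement integration failed: {sol.message}")
        ts.extend(sol.t[1:].tolist())
        zs.extend(sol.y[:, 1:].T)
        z = sol.y[:, -1]
        t = sol.t[-1]
        if np.linalg.norm(z, np.inf) > DIVERGENCE_FACTOR * scale0:
            raise InstabilityError(
                "agreement trajectory diverged — perturbation may have driven "
                "the system into an unstable region"
            )

    lin = augmented.lin
    # exact steady states of each half
    try:
        x_dev_ss = np.linalg.solve(lin.A, -lin.B @ (u - lin.u_bf))
    except np.linalg.LinAlgError:
        x_dev_ss = z[:n].copy()
    x_nonlin_ss, _ = _newton_refine(
        lambda y: augmented.network.rhs(y, u), augmented.network.jac, z[n:].copy()
    )
    x_nonlin_ss = np.where(
        (x_nonlin_ss < 0) & (x_nonlin_ss > -1e-8), 0.0, x_nonlin_ss
    )

    t_arr = np.asarray(ts)
    z_arr = np.asarray(zs)
    if len(t_arr) > n_save:
        idx = np.unique(
            np.linspace(0, len(t_arr) - 1, n_save).round().astype(int)
        )
        t_arr, z_arr = t_arr[idx], z_arr[idx]
    return AgreementResult(
        t=t_arr,
        x_dev=z_arr[:, :n],
        x_nonlin=z_arr[:, n:],
        x_ss=lin.x_ss.copy(),
        x_dev_ss=x_dev_ss,
        x_nonlin_ss=x_nonlin_ss,
    )
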