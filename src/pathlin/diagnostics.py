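"""Validity diagnostics: Lyapunov exponents, contraction, Hessian effects.

These checks probe whether a linearization anchored at a fixed point can
be trusted: Lyapunov exponents measure the per-unit-time log growth of
infinitesimal trajectory separations (negative = local convergence); the
discrete-time flow map ``Phi`` over a sampling period ``T_s`` is a strict
contraction when the spectral norm of its Jacobian stays below 1, which
guarantees a unique fixed point; and the magnitude of the discarded
second-order Taylor term — exact for (at most bimolecular) mass-action
kinetics, whose third state derivatives vanish — indicates how fast the
linearization error grows with the deviation.

All functions accept any object exposing ``rhs(x, u)`` and ``jac(x)``
(:class:`~pathlin.reaction_model.ReactionNetwork` does); :class:`LTISystem`
wraps a constant (A, B) pair for reference cases such as pure rotations.
Euclidean norms are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import (
    ConfigurationError,
    DimensionError,
    InstabilityError,
    IntegrationError,
    SingularityError,
)

__all__ = [
    "LTISystem",
    "LyapunovDiagnostics",
    "ContractionReport",
    "HessianIndicator",
    "SensitivityComparison",
    "flow_with_variational",
    "local_lyapunov_exponent",
    "global_lyapunov_estimate",
    "contraction_check",
    "hessian_error_indicator",
    "input_sensitivity_compare",
]


class LTISystem:
    """Constant-coefficient system dx/dt = A x + B u."""

    def __init__(self, A, B=None):
        self.A = np.asarray(A, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise DimensionError("A must be square")
        self.B = (
            np.zeros((n, 1)) if B is None else np.asarray(B, dtype=float)
        )
        self.n_species = n
        self.n_inputs = self.B.shape[1]

    def rhs(self, x, u=None):
        x = np.asarray(x, dtype=float)
        out = self.A @ x
        if u is not None:
            out = out + self.B @ np.asarray(u, dtype=float)
        return out

    def jac(self, x):
        return self.A.copy()

    def input_matrix(self):
        return self.B.copy()


@dataclass(frozen=True)
class LyapunovDiagnostics:
    """Local exponents along a trajectory plus their average."""

    T_s: float
    local_exponents: np.ndarray
    global_exponent: float
    y0: np.ndarray


@dataclass(frozen=True)
class ContractionReport:
    is_contraction: bool
    c_max: float
    per_sample: np.ndarray  # spectral norm of J(Phi, x) at each sample


@dataclass(frozen=True)
class HessianIndicator:
    """Exact directional second-order Taylor term |1/2 dx^T H dx| per row."""

    norm: float
    components: np.ndarray


@dataclass(frozen=True)
class SensitivityComparison:
    abs_diff: float   # spectral norm of S_new - S_anchor
    rel_diff: float
    S_anchor: np.ndarray
    S_new: np.ndarray


def _zero_u(system):
    m = getattr(system, "n_inputs", 0)
    return np.zeros(m)


def flow_with_variational(system, x0, u, T_s: float, rtol=1e-10, atol=1e-12):
    """Integrate state and variational matrix jointly over one period.

    Returns ``(x(T_s), Psi)`` where ``Psi = J(Phi, x0)`` solves the matrix
    ODE ``dPsi/dt = J(x(t)) Psi`` with ``Psi(0) = I``.
    """
    if T_s <= 0:
        raise ConfigurationError("T_s must be > 0")
    x0 = np.asarray(x0, dtype=float)
    n = x0.shape[0]

    def joint_rhs(_t, z):
        x = z[:n]
        psi = z[n:].reshape(n, n)
        J = system.jac(x)
        return np.concatenate((system.rhs(x, u), (J @ psi).ravel()))

    z0 = np.concatenate((x0, np.eye(n).ravel()))
    sol = solve_ivp(joint_rhs, (0.0, T_s), z0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"variational integration failed: {sol.message}")
    zT = sol.y[:, -1]
    return zT[:n], zT[n:].reshape(n, n)


def local_lyapunov_exponent(
    system, x, y, T_s: float, u=None, frozen: bool = False
) -> float:
    """ln(||J(Phi, x) y||) / T_s for a unit direction ``y``.

    ``frozen=True`` replaces the variational flow by the matrix
    exponential of the Jacobian frozen at ``x`` (exact for constant
    Jacobians).  Negative values mean nearby trajectories converge.
    """
    y = np.asarray(y, dtype=float)
    if not np.isclose(np.linalg.norm(y), 1.0, rtol=1e-8):
        raise ConfigurationError("direction y must be a unit vector")
    if T_s <= 0:
        raise ConfigurationError("T_s must be > 0")
    if u is None:
        u = _zero_u(system)
    if frozen:
        psi = expm(system.jac(np.asarray(x, dtype=float)) * T_s)
    else:
        _, psi = flow_with_variational(system, x, u, T_s)
    return float(np.log(np.linalg.norm(psi @ y)) / T_s)


def global_lyapunov_estimate(
    system, x0, u, y0, T_s: float, n_steps: int,
    divergence_bound: float = 1e9,
) -> LyapunovDiagnostics:
    """Average of local exponents along the trajectory from ``x0``.

    The direction is propagated through the variational Jacobian at every
    step; for a trajectory settling onto a stable fixed point the tail
    exponents approach an eigendirection decay rate.  ``n_steps=1``
    reduces to the local exponent at ``x0``.
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    x = np.asarray(x0, dtype=float)
    y = np.asarray(y0, dtype=float)
    y = y / np.linalg.norm(y)
    scale0 = max(1.0, np.linalg.norm(x, np.inf))
    exps = np.empty(n_steps)
    for k in range(n_steps):
        x_next, psi = flow_with_variational(system, x, u, T_s)
        y_next = psi @ y
        growth = np.linalg.norm(y_next)
        exps[k] = np.log(growth) / T_s
        y = y_next / growth
        x = x_next
        if np.linalg.norm(x, np.inf) > divergence_bound * scale0:
            raise InstabilityError(
                f"trajectory diverged after {k + 1} Lyapunov steps"
            )
    return LyapunovDiagnostics(
        T_s=T_s,
        local_exponents=exps,
        global_exponent=float(exps.mean()),
        y0=np.asarray(y0, dtype=float),
    )


def contraction_check(system, region_samples, T_s: float, u=None) -> ContractionReport:
    """Spectral-norm test of the flow map over ``T_s`` at sample points.

    ``c_max = max_x ||J(Phi, x)||_2``; the map is certified a strict
    contraction on the sampled region when ``c_max < 1`` (a sufficient
    condition — the margin ``1 - c_max`` is reported through ``c_max``).
    """
    if u is None:
        u = _zero_u(system)
    norms = []
    for x in region_samples:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ConfigurationError("region samples must be nonnegative")
        _, psi = flow_with_variational(system, x, u, T_s)
        norms.append(np.linalg.norm(psi, 2))
    norms = np.asarray(norms)
    c_max = float(norms.max())
    return ContractionReport(
        is_contraction=bool(c_max < 1.0), c_max=c_max, per_sample=norms
    )


def hessian_error_indicator(system, x_anchor, dx, u=None) -> HessianIndicator:
    """Magnitude of the discarded second-order Taylor term along ``dx``.

    Evaluated as the exact second central difference
    ``[f(x+dx) + f(x-dx) - 2 f(x)] / 2`` per component — for mass-action
    kinetics of order <= 2 the cubic remainder vanishes identically, so
    this equals ``1/2 dx^T H dx`` exactly.
    """
    x = np.asarray(x_anchor, dtype=float)
    dx = np.asarray(dx, dtype=float)
    if u is None:
        u = _zero_u(system)
    second = 0.5 * (
        system.rhs(x + dx, u) + system.rhs(x - dx, u) - 2.0 * system.rhs(x, u)
    )
    comp = np.abs(second)
    return HessianIndicator(norm=float(np.linalg.norm(second)), components=comp)


def input_sensitivity_compare(system, x_anchor, x_new, B=None) -> SensitivityComparison:
    """Compare steady-state input sensitivities S = -J(x)^{-1} B.

    A large spectral-norm difference between the sensitivity matrices at
    the anchor and at the post-perturbation fixed point flags operating
    points where the linearization's input response no longer matches the
    nonlinear model's.
    """
    if B is None:
        B = system.input_matrix()
    B = np.asarray(B, dtype=float)

    def sens(x):
        J = system.jac(np.asarray(x, dtype=float))
        cond = np.linalg.cond(J)
        if not np.isfinite(cond) or cond > 1e12:
            raise SingularityError(
                f"state Jacobian is singular or ill-conditioned (cond={cond:.3g})"
            )
        return -np.linalg.solve(J, B)

    S0 = sens(x_anchor)
    S1 = sens(x_new)
    diff = float(np.linalg.norm(S1 - S0, 2))
    base = float(np.linalg.norm(S0, 2))
    return SensitivityComparison(
        abs_diff=diff,
        rel_diff=diff / base if base > 0 else np.inf,
        S_anchor=S0,
        S_new=S1,
    )
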