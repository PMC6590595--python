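"""Monte Carlo quantification of linearization error.

The workflow mirrors the accuracy study: for each base input sample the
nonlinear model is driven to its steady state ``x_ss0`` and linearized
there; the input is then perturbed multiplicatively,

    u_i = (1 + r_noise - 2 r_noise d_i) o u_bf,i,       d_i ~ U[0,1]^m,

(``o`` the Hadamard product, so each component is scaled by a factor in
``[1 - r_noise, 1 + r_noise]``), the agreement system is co-simulated
from ``[0; x_ss0]``, the linear prediction is clipped to ``[0, inf)`` and
error metrics are computed against the nonlinear steady state:

    MSE = mean((x_lin - x_nonlin)^2)
    MRE = mean(|x_lin - x_nonlin| / x_nonlin)          [percent]
    std_ratio = std(e) / std(x_nonlin - x_ss0)         [percent]

averaged arithmetically over input samples, on two scopes: all model
states and the readout subvector.  Components whose nonlinear steady
state is numerically zero are excluded from the MRE denominator (the
clipped-prediction analogue of the small-denominator blowup).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DimensionError,
    MetricUndefinedError,
    PathlinError,
)
from .linearization import clip_nonnegative, linearize
from .reaction_model import ReactionNetwork, evaluate_outputs
from .simulation import build_agreement_system, simulate_agreement, simulate_to_steady_state
from .synthetic import sample_parameters

__all__ = [
    "PerturbationSet",
    "ErrorMetrics",
    "MCReport",
    "TrendFit",
    "perturb_inputs",
    "compute_metrics",
    "run_workflow",
    "run_study",
    "fit_error_trend",
    "relative_dataset_ratios",
]

logger = logging.getLogger(__name__)

SCOPES = ("all_states", "readouts")


@dataclass(frozen=True)
class PerturbationSet:
    """Shared perturbation directions for one workflow run.

    The same direction matrix is reused across every ``r_noise`` level of
    the run, so noise levels differ only in magnitude, not direction.
    """

    directions: np.ndarray  # (n_samples, m) entries in [0, 1]
    seed: int

    @classmethod
    def draw(cls, n_samples: int, n_inputs: int, seed) -> "PerturbationSet":
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.0, 1.0, size=(n_samples, n_inputs))
        return cls(directions=d, seed=int(seed) if np.isscalar(seed) else -1)


@dataclass(frozen=True)
class ErrorMetrics:
    mse: float
    mre_pct: float
    std_ratio_pct: float
    scope: str
    n_excluded: int = 0


@dataclass
class MCReport:
    """Aggregated metrics for one workflow (one parameter vector)."""

    table: pd.DataFrame          # r_noise, scope, std_ratio_pct, mre_pct, mse
    per_sample: pd.DataFrame     # adds a 'sample' column, pre-aggregation
    n_samples: int
    n_excluded_samples: int
    seed: int
    model_id: str
    workflow_id: int = 1

    def metric(self, r_noise: float, scope: str, column: str) -> float:
        rows = self.table[
            (np.isclose(self.table.r_noise, r_noise)) & (self.table.scope == scope)
        ]
        if rows.empty:
            raise KeyError(f"no row for r_noise={r_noise}, scope={scope}")
        return float(rows.iloc[0][column])


@dataclass(frozen=True)
class TrendFit:
    slope: float
    monotone: bool
    exact_linear: bool = False


def perturb_inputs(u_bf, r_noise: float, d) -> np.ndarray:
    """u_i = (1 + r_noise - 2 r_noise d) o u_bf, with d in [0,1]^m."""
    u_bf = np.asarray(u_bf, dtype=float)
    d = np.asarray(d, dtype=float)
    if d.shape != u_bf.shape:
        raise DimensionError(
            f"direction shape {d.shape} does not match input shape {u_bf.shape}"
        )
    if np.any(d < 0.0) or np.any(d > 1.0):
        raise ConfigurationError("direction entries must lie in [0, 1]")
    if not 0.0 <= r_noise < 1.0:
        raise ConfigurationError("r_noise must lie in [0, 1)")
    return (1.0 + r_noise - 2.0 * r_noise * d) * u_bf


def compute_metrics(
    x_lin_ss,
    x_nonlin_ss,
    x_ss0,
    scope_indices=None,
    eps_den: float | None = None,
    scope: str = "all_states",
) -> ErrorMetrics:
    """Error metrics of a clipped linear prediction vs the nonlinear truth.

    ``scope_indices=None`` scores every state; otherwise the given subset
    (e.g. the readouts).  ``eps_den`` defaults to ``1e-9 * max(x_nonlin)``
    over the scope: components whose nonlinear value falls below it are
    excluded from the MRE mean (they would divide by numerical zero) but
    still count toward MSE and the std ratio.
    """
    x_lin = np.asarray(x_lin_ss, dtype=float)
    x_non = np.asarray(x_nonlin_ss, dtype=float)
    x0 = np.asarray(x_ss0, dtype=float)
    if not (x_lin.shape == x_non.shape == x0.shape):
        raise DimensionError("metric inputs must share one shape")
    if scope_indices is not None:
        idx = np.asarray(scope_indices, dtype=np.intp)
        x_lin, x_non, x0 = x_lin[idx], x_non[idx], x0[idx]
    e = x_lin - x_non
    mse = float(np.mean(e**2))
    if eps_den is None:
        eps_den = 1e-9 * float(np.max(x_non, initial=0.0))
    keep = x_non > max(eps_den, 0.0)
    n_excluded = int(np.size(e) - np.count_nonzero(keep))
    if not np.any(keep):
        raise MetricUndefinedError(
            "every component was excluded from the MRE denominator"
        )
    mre = float(np.mean(np.abs(e[keep]) / x_non[keep])) * 100.0
    x_diff = x_non - x0
    sd_diff = float(np.std(x_diff, ddof=1)) if x_diff.size > 1 else 0.0
    sd_e = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    std_ratio = 100.0 * sd_e / sd_diff if sd_diff > 0 else (0.0 if sd_e == 0 else np.nan)
    return ErrorMetrics(
        mse=mse, mre_pct=mre, std_ratio_pct=std_ratio,
        scope=scope, n_excluded=n_excluded,
    )


def run_workflow(
    network: ReactionNetwork,
    base_inputs,
    r_noise_list=(0.10, 0.25, 0.50),
    seed=0,
    tol_ss: float = 1e-9,
    t_max: float = 1e7,
    workflow_id: int = 1,
) -> MCReport:
    """One full Monte Carlo run for a fixed parameter vector.

    For every base input: simulate to ``x_ss0``, linearize there, and for
    every noise level perturb the input (directions drawn once per run),
    co-simulate the agreement system from ``[0; x_ss0]``, clip the linear
    steady-state prediction and score it on both scopes.  Samples whose
    simulation fails are excluded and counted.
    """
    base_inputs = np.atleast_2d(np.asarray(base_inputs, dtype=float))
    if base_inputs.shape[1] != network.n_inputs:
        raise DimensionError(
            f"base inputs have {base_inputs.shape[1]} components, "
            f"expected {network.n_inputs}"
        )
    if np.any(base_inputs <= 0):
        raise ConfigurationError("base inputs must be strictly positive")
    r_noise_list = [float(r) for r in r_noise_list]
    n_samples = base_inputs.shape[0]
    pset = PerturbationSet.draw(n_samples, network.n_inputs, seed)
    readout_idx = network.readout_indices if network.n_readouts else None

    records = []
    n_failed = 0
    for i, u_bf in enumerate(base_inputs):
        try:
            ss0 = simulate_to_steady_state(network, u_bf, tol_ss=tol_ss, t_max=t_max)
            lin = linearize(network, ss0)
            agr = build_agreement_system(network, lin)
            sample_rows = []
            for r in r_noise_list:
                u_i = perturb_inputs(u_bf, r, pset.directions[i])
                res = simulate_agreement(agr, u_i, t_max=t_max, tol_ss=tol_ss)
                x_lin = clip_nonnegative(ss0.x_ss + res.x_dev_ss)
                for scope in SCOPES:
                    if scope == "readouts" and readout_idx is None:
                        continue
                    m = compute_metrics(
                        x_lin,
                        res.x_nonlin_ss,
                        ss0.x_ss,
                        scope_indices=readout_idx if scope == "readouts" else None,
                        scope=scope,
                    )
                    sample_rows.append(
                        dict(
                            sample=i, r_noise=r, scope=scope, mse=m.mse,
                            mre_pct=m.mre_pct, std_ratio_pct=m.std_ratio_pct,
                            n_excluded=m.n_excluded,
                        )
                    )
        except PathlinError as exc:
            n_failed += 1
            logger.warning("sample %d excluded: %s", i, exc)
            continue
        records.extend(sample_rows)

    if not records:
        raise ConfigurationError("every Monte Carlo sample failed to simulate")
    per_sample = pd.DataFrame.from_records(records)
    table = (
        per_sample.groupby(["r_noise", "scope"], as_index=False)
        .agg(
            std_ratio_pct=("std_ratio_pct", "mean"),
            mre_pct=("mre_pct", "mean"),
            mse=("mse", "mean"),
            n_excluded=("n_excluded", "sum"),
        )
        .sort_values(["r_noise", "scope"], ignore_index=True)
    )
    return MCReport(
        table=table,
        per_sample=per_sample,
        n_samples=n_samples,
        n_excluded_samples=n_failed,
        seed=int(seed) if np.isscalar(seed) else -1,
        model_id=network.name,
        workflow_id=workflow_id,
    )


def run_study(
    network: ReactionNetwork,
    base_inputs,
    n_workflows: int = 4,
    r_noise_list=(0.10, 0.25, 0.50),
    seed=0,
    **workflow_kwargs,
) -> list[MCReport]:
    """Repeat the workflow for several random parameter vectors.

    The same base-input set is shared across workflows; each workflow
    draws its own parameter vector (log-uniform over the network's rate
    constants) and its own perturbation directions.
    """
    root = np.random.SeedSequence(seed)
    reports = []
    for w, child in enumerate(root.spawn(n_workflows), start=1):
        s_param, s_dirs = child.spawn(2)
        p = sample_parameters(len(network.parameters), seed=s_param)
        net_w = network.with_parameters(p)
        rep = run_workflow(
            net_w, base_inputs, r_noise_list,
            seed=s_dirs, workflow_id=w, **workflow_kwargs,
        )
        rep.seed = seed
        reports.append(rep)
    return reports


def fit_error_trend(report: MCReport, scope: str = "all_states") -> TrendFit:
    """Log-log slope of mean MRE against r_noise plus a monotonicity flag."""
    rows = report.table[report.table.scope == scope].sort_values("r_noise")
    if len(rows) < 3:
        raise ConfigurationError("need at least 3 r_noise levels to fit a trend")
    r = rows.r_noise.to_numpy()
    mre = rows.mre_pct.to_numpy()
    if np.all(mre == 0.0):
        return TrendFit(slope=np.nan, monotone=True, exact_linear=True)
    monotone = bool(np.all(np.diff(mre) >= 0))
    keep = mre > 0
    slope = float(np.polyfit(np.log(r[keep]), np.log(mre[keep]), 1)[0])
    return TrendFit(slope=slope, monotone=monotone)


def relative_dataset_ratios(
    network: ReactionNetwork,
    u_base,
    u_variants,
    use_linear: bool = False,
    tol_ss: float = 1e-9,
) -> list[np.ndarray]:
    """Per-readout output ratios y(u_variant)/y(u_base) at steady state.

    The linear path performs exactly one linear solve per variant after a
    single base simulation + linearization; the nonlinear path forward
    simulates each variant starting from the base steady state.
    """
    u_base = np.asarray(u_base, dtype=float)
    ss = simulate_to_steady_state(network, u_base, tol_ss=tol_ss)
    y_base = evaluate_outputs(network, ss.x_ss)
    y_floor = 1e-12 * max(1.0, float(np.max(y_base, initial=0.0)))
    if np.any(y_base <= y_floor):
        bad = [network.readouts[i] for i in np.flatnonzero(y_base <= y_floor)]
        raise ConfigurationError(
            f"base steady-state outputs are (numerically) zero for readouts {bad}: "
            "ratios undefined"
        )
    ratios = []
    lin = linearize(network, ss) if use_linear else None
    for uv in u_variants:
        uv = np.asarray(uv, dtype=float)
        if use_linear:
            from .linearization import linear_steady_state

            x = clip_nonnegative(linear_steady_state(lin, uv))
        else:
            x = simulate_to_steady_state(network, uv, x0=ss.x_ss, tol_ss=tol_ss).x_ss
        ratios.append(evaluate_outputs(network, x) / y_base)
    return ratios
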