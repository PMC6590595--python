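"""Mass-action reaction networks and their analytic Jacobians.

A :class:`ReactionNetwork` describes a biochemical system

    dx/dt = f(x, p, u),        y = g(x, p, u),

where ``x`` is the vector of species concentrations, ``p`` the vector of
positive rate constants, ``u`` a vector of exogenous zero-order inflows
(conc/time) and ``y`` a readout subvector of ``x``.  Kinetics are
mass-action with at most bimolecular reactions, so the right-hand side is
bilinear in the state: every row can be written as

    dx_k/dt = -x_k * h1_k(x_i, p) + h2_k(x_i, p) + u_k,

with ``h1_k > c_k > 0`` (first-order losses, guaranteed when the species
carries a first-order self-loss reaction) and ``h2_k >= 0`` (production
driven by the other species).  This structure makes each state a stable
first-order filter for frozen inputs, keeps trajectories nonnegative, and
makes the input Jacobian a constant 0/1 incidence matrix, so a Taylor
linearization is exact in the input directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DimensionError,
    ModelValidationError,
    StructuralFormError,
)

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "StructuralDecomposition",
    "LinearityFlags",
    "evaluate_rhs",
    "state_jacobian",
    "input_jacobian",
    "decompose_structural_form",
    "check_linearity_conditions",
    "evaluate_outputs",
]


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``reactants`` / ``products`` map species name -> stoichiometric
    coefficient; ``rate_param`` names the rate constant in the network's
    parameter table.  The reactant side is restricted to total order <= 2
    with per-species stoichiometry <= 1 (at most bimolecular, consumption
    first order in each consumed species).
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_param: str

    def as_dict(self) -> dict:
        return {
            "reactants": dict(self.reactants),
            "products": dict(self.products),
            "rate_param": self.rate_param,
        }


@dataclass(frozen=True)
class StructuralDecomposition:
    """Row ``k`` of the RHS collected as ``-x_k*h1 + h2 + u_k``.

    ``h1`` aggregates first-order loss coefficients (1/time), ``h2`` the
    production rate from the other species (conc/time) and ``input_rate``
    the exogenous inflow into species ``k`` (conc/time).
    """

    k: int
    h1: float
    h2: float
    input_rate: float

    def rhs_value(self, x_k: float) -> float:
        return -x_k * self.h1 + self.h2 + self.input_rate


@dataclass(frozen=True)
class LinearityFlags:
    """Outcome of numeric probing of the two input-linearity conditions."""

    input_jacobian_constant: bool
    state_jacobian_u_free: bool

    def __iter__(self):
        yield self.input_jacobian_constant
        yield self.state_jacobian_u_free


class ReactionNetwork:
    """Immutable mass-action network compiled to fast vectorized kernels.

    Parameters
    ----------
    species:
        Ordered species identifiers.
    reactions:
        Sequence of :class:`Reaction` (or dicts with the same keys).
    parameters:
        Mapping rate-constant name -> strictly positive value.
    inputs:
        Ordered mapping input name -> species receiving that zero-order
        inflow.  The mapping order defines the layout of ``u``.
    readouts:
        Ordered subset of species names defining the output vector ``y``.
    rhs_extension:
        Optional callable ``(x, u) -> array`` added to the mass-action RHS.
        Meant as a hook for probing non-input-linear kinetics; analytic
        Jacobians are unavailable while an extension is attached.
    """

    def __init__(
        self,
        species: Sequence[str],
        reactions: Sequence[Reaction | Mapping],
        parameters: Mapping[str, float],
        inputs: Mapping[str, str],
        readouts: Sequence[str] = (),
        rhs_extension: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
        name: str = "network",
    ):
        self.species = list(species)
        if len(set(self.species)) != len(self.species):
            raise ModelValidationError("species: duplicate identifiers")
        self._index = {s: i for i, s in enumerate(self.species)}
        self.reactions = [
            r if isinstance(r, Reaction) else Reaction(
                dict(r["reactants"]), dict(r["products"]), r["rate_param"]
            )
            for r in reactions
        ]
        self.parameters = dict(parameters)
        self.inputs = dict(inputs)
        self.readouts = list(readouts)
        self.rhs_extension = rhs_extension
        self.name = name
        self._validate()
        self._compile()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        for pname, val in self.parameters.items():
            if not np.isfinite(val) or val <= 0:
                raise ModelValidationError(
                    f"parameters: '{pname}' must be strictly positive, got {val!r}"
                )
        for j, rxn in enumerate(self.reactions):
            if rxn.rate_param not in self.parameters:
                raise ModelValidationError(
                    f"reactions[{j}]: unknown rate_param '{rxn.rate_param}'"
                )
            order = 0
            for side, stoich in (("reactants", rxn.reactants), ("products", rxn.products)):
                for sp, nu in stoich.items():
                    if sp not in self._index:
                        raise ModelValidationError(
                            f"reactions[{j}].{side}: unknown species '{sp}'"
                        )
                    if int(nu) != nu or nu < 1:
                        raise ModelValidationError(
                            f"reactions[{j}].{side}: stoichiometry of '{sp}' must be a positive integer"
                        )
            for sp, nu in rxn.reactants.items():
                if nu > 1:
                    raise ModelValidationError(
                        f"reactions[{j}]: reactant stoichiometry of '{sp}' exceeds 1"
                    )
                order += nu
            if order > 2:
                raise ModelValidationError(
                    f"reactions[{j}]: total reactant order {order} exceeds 2 (at most bimolecular)"
                )
        for uname, sp in self.inputs.items():
            if sp not in self._index:
                raise ModelValidationError(f"inputs: '{uname}' feeds unknown species '{sp}'")
        seen = set()
        for sp in self.readouts:
            if sp not in self._index:
                raise ModelValidationError(f"readouts: unknown species '{sp}'")
            if sp in seen:
                raise ModelValidationError(f"readouts: duplicate species '{sp}'")
            seen.add(sp)

    # -- compilation to array kernels -----------------------------------

    def _compile(self) -> None:
        n, nr = self.n_species, len(self.reactions)
        r1 = np.full(nr, -1, dtype=np.intp)   # first reactant (-1: zero order)
        r2 = np.full(nr, -1, dtype=np.intp)   # second reactant (-1: none)
        k = np.empty(nr)
        coo_rxn, coo_sp, coo_coef = [], [], []
        for j, rxn in enumerate(self.reactions):
            k[j] = self.parameters[rxn.rate_param]
            reac = sorted(rxn.reactants.items(), key=lambda t: self._index[t[0]])
            if len(reac) >= 1:
                r1[j] = self._index[reac[0][0]]
            if len(reac) == 2:
                r2[j] = self._index[reac[1][0]]
            net: dict[int, float] = {}
            for sp, nu in rxn.reactants.items():
                net[self._index[sp]] = net.get(self._index[sp], 0.0) - nu
            for sp, nu in rxn.products.items():
                net[self._index[sp]] = net.get(self._index[sp], 0.0) + nu
            for i, c in net.items():
                if c != 0.0:
                    coo_rxn.append(j)
                    coo_sp.append(i)
                    coo_coef.append(c)
        self._r1, self._r2, self._k = r1, r2, k
        self._coo_rxn = np.asarray(coo_rxn, dtype=np.intp)
        self._coo_sp = np.asarray(coo_sp, dtype=np.intp)
        self._coo_coef = np.asarray(coo_coef)
        # input incidence matrix B (n x m), one column per input
        B = np.zeros((n, self.n_inputs))
        for col, sp in enumerate(self.inputs.values()):
            B[self._index[sp], col] = 1.0
        self._B = B
        self._readout_idx = np.asarray(
            [self._index[s] for s in self.readouts], dtype=np.intp
        )

    # -- basic properties ------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_readouts(self) -> int:
        return len(self.readouts)

    @property
    def readout_indices(self) -> np.ndarray:
        return self._readout_idx.copy()

    def species_index(self, name: str) -> int:
        return self._index[name]

    # -- derived copies --------------------------------------------------

    def with_parameters(self, parameters) -> "ReactionNetwork":
        """Same topology with a new rate-constant vector or mapping."""
        if isinstance(parameters, Mapping):
            new = dict(parameters)
        else:
            vals = np.asarray(parameters, dtype=float)
            names = list(self.parameters)
            if vals.shape != (len(names),):
                raise DimensionError(
                    f"expected {len(names)} parameter values, got {vals.shape}"
                )
            new = dict(zip(names, vals.tolist()))
        return ReactionNetwork(
            self.species, self.reactions, new, self.inputs, self.readouts,
            rhs_extension=self.rhs_extension, name=self.name,
        )

    def with_readouts(self, readouts: Sequence[str]) -> "ReactionNetwork":
        return ReactionNetwork(
            self.species, self.reactions, self.parameters, self.inputs,
            readouts, rhs_extension=self.rhs_extension, name=self.name,
        )

    def with_extension(self, rhs_extension) -> "ReactionNetwork":
        return ReactionNetwork(
            self.species, self.reactions, self.parameters, self.inputs,
            self.readouts, rhs_extension=rhs_extension, name=self.name,
        )

    # -- kernels ---------------------------------------------------------

    def _rates(self, x: np.ndarray) -> np.ndarray:
        r = self._k.copy()
        has1 = self._r1 >= 0
        r[has1] *= x[self._r1[has1]]
        has2 = self._r2 >= 0
        r[has2] *= x[self._r2[has2]]
        return r

    def rhs(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        """f(x, p, u): mass-action production/consumption plus inflows."""
        x = self._check_state(x)
        u = self._check_input(u)
        rates = self._rates(x)
        f = self._B @ u
        np.add.at(f, self._coo_sp, self._coo_coef * rates[self._coo_rxn])
        if self.rhs_extension is not None:
            f = f + np.asarray(self.rhs_extension(x, u), dtype=float)
        return f

    def jac(self, x: np.ndarray) -> np.ndarray:
        """Analytic state Jacobian df/dx (independent of ``u``)."""
        if self.rhs_extension is not None:
            raise ModelValidationError(
                "analytic Jacobians are unavailable while rhs_extension is attached"
            )
        x = self._check_state(x)
        n = self.n_species
        J = np.zeros(n * n)
        # d(rate_j)/d(x_r1) = k * x_r2 (or k), d/d(x_r2) = k * x_r1
        has1 = self._r1[self._coo_rxn] >= 0
        sel = self._coo_rxn[has1]
        d1 = self._k[sel].copy()
        with_second = self._r2[sel] >= 0
        d1[with_second] *= x[self._r2[sel[with_second]]]
        np.add.at(
            J,
            self._coo_sp[has1] * n + self._r1[sel],
            self._coo_coef[has1] * d1,
        )
        has2 = self._r2[self._coo_rxn] >= 0
        sel2 = self._coo_rxn[has2]
        d2 = self._k[sel2] * x[self._r1[sel2]]
        np.add.at(
            J,
            self._coo_sp[has2] * n + self._r2[sel2],
            self._coo_coef[has2] * d2,
        )
        return J.reshape(n, n)

    def input_matrix(self) -> np.ndarray:
        """Constant 0/1 incidence matrix B = df/du."""
        if self.rhs_extension is not None:
            raise ModelValidationError(
                "analytic Jacobians are unavailable while rhs_extension is attached"
            )
        return self._B.copy()

    def outputs(self, x: np.ndarray) -> np.ndarray:
        if self.n_readouts == 0:
            raise ConfigurationError("network defines no readouts")
        x = self._check_state(x)
        return x[self._readout_idx]

    # -- checks ----------------------------------------------------------

    def _check_state(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_species,):
            raise DimensionError(
                f"state vector has shape {x.shape}, expected ({self.n_species},)"
            )
        return x

    def _check_input(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if u.shape != (self.n_inputs,):
            raise DimensionError(
                f"input vector has shape {u.shape}, expected ({self.n_inputs},)"
            )
        return u

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "species": list(self.species),
            "reactions": [r.as_dict() for r in self.reactions],
            "parameters": dict(self.parameters),
            "inputs": dict(self.inputs),
            "readouts": list(self.readouts),
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ReactionNetwork(name={self.name!r}, n_species={self.n_species}, "
            f"n_reactions={len(self.reactions)}, n_inputs={self.n_inputs}, "
            f"n_readouts={self.n_readouts})"
        )


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def evaluate_rhs(network: ReactionNetwork, x, u) -> np.ndarray:
    """Evaluate dx/dt = f(x, p, u) for the given state and inputs."""
    return network.rhs(x, u)


def state_jacobian(network: ReactionNetwork, x) -> np.ndarray:
    """Analytic Jacobian A(x) = df/dx; never depends on ``u``."""
    return network.jac(x)


def input_jacobian(network: ReactionNetwork) -> np.ndarray:
    """Constant input Jacobian B = df/du (0/1 inflow incidence)."""
    return network.input_matrix()


def evaluate_outputs(network: ReactionNetwork, x) -> np.ndarray:
    """Readout map y = g(x): the subvector of x at the readout indices."""
    return network.outputs(x)


def decompose_structural_form(
    network: ReactionNetwork, k: int, x, u
) -> StructuralDecomposition:
    """Collect row ``k`` of the RHS as ``-x_k*h1 + h2 + u_k``.

    Raises
    ------
    StructuralFormError
        If species ``k`` has no first-order self-loss reaction, so the
        constant lower bound ``h1 >= c_k > 0`` cannot be certified.
    """
    x = network._check_state(x)
    u = network._check_input(u)
    if not 0 <= k < network.n_species:
        raise DimensionError(f"state index {k} out of range")
    sp_k = network.species[k]
    h1 = 0.0
    h2 = 0.0
    c_k = 0.0
    for rxn in network.reactions:
        rate_k = network.parameters[rxn.rate_param]
        if sp_k in rxn.reactants:
            net_cons = rxn.reactants[sp_k] - rxn.products.get(sp_k, 0)
            others = [s for s in rxn.reactants if s != sp_k]
            factor = rate_k
            for s in others:
                factor *= x[network.species_index(s)]
            h1 += net_cons * factor
            if not others and net_cons >= 1:
                c_k += net_cons * rate_k
        elif sp_k in rxn.products:
            rate = rate_k
            for s, nu in rxn.reactants.items():
                rate *= x[network.species_index(s)]
            h2 += rxn.products[sp_k] * rate
    if c_k <= 0.0:
        raise StructuralFormError(
            f"species '{sp_k}' has no first-order self-loss reaction: "
            "the lower bound h1 > c_k > 0 cannot be guaranteed"
        )
    u_k = float(network._B[k] @ u)
    return StructuralDecomposition(k=k, h1=float(h1), h2=float(h2), input_rate=u_k)


def check_linearity_conditions(
    network: ReactionNetwork,
    n_probes: int = 3,
    seed: int = 0,
    rtol: float = 1e-5,
    atol: float = 1e-7,
) -> LinearityFlags:
    """Probe the two conditions that make linearization input-exact.

    (i) the input Jacobian is constant in ``(x, u)`` and (ii) the state
    Jacobian does not depend on ``u``.  Both are verified numerically at
    ``n_probes`` random operating points so that networks carrying a
    ``rhs_extension`` with u-dependent kinetics are detected.
    """
    if n_probes < 1:
        raise ConfigurationError("n_probes must be >= 1")
    rng = np.random.default_rng(seed)
    n, m = network.n_species, network.n_inputs

    def fd_input_jac(x, u, h=1e-5):
        B = np.empty((n, m))
        for j in range(m):
            e = np.zeros(m)
            e[j] = h
            B[:, j] = (network.rhs(x, u + e) - network.rhs(x, u - e)) / (2 * h)
        return B

    def fd_state_jac(x, u, h=1e-6):
        J = np.empty((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = h
            J[:, j] = (network.rhs(x + e, u) - network.rhs(x - e, u)) / (2 * h)
        return J

    input_const = True
    state_u_free = True
    B_ref = None
    for _ in range(n_probes):
        x = rng.uniform(0.1, 2.0, n)
        u1 = rng.uniform(0.1, 2.0, m)
        u2 = rng.uniform(0.1, 2.0, m)
        B_here = fd_input_jac(x, u1)
        if B_ref is None:
            B_ref = B_here
        if not np.allclose(B_here, B_ref, rtol=rtol, atol=atol):
            input_const = False
        if not np.allclose(fd_input_jac(x, u2), B_ref, rtol=rtol, atol=atol):
            input_const = False
        if not np.allclose(
            fd_state_jac(x, u1), fd_state_jac(x, u2), rtol=rtol, atol=atol
        ):
            state_u_free = False
    return LinearityFlags(input_const, state_u_free)
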