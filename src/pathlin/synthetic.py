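"""Synthetic WNT-like cascade networks and analytic toy fixtures.

The generator emulates the class of receptor-ligand signaling models used
for the accuracy study: a layered mass-action cascade in which exogenous
inflows feed ligands, receptors, coreceptors and downstream cofactor
proteins; ligand-receptor binding produces membrane complexes which are
elaborated layer by layer; terminal "positive"/"negative" readout pairs
share a precursor complex (mirroring transcription-factor readouts that
either include or exclude the signaling effector).  Every species carries
a first-order degradation reaction, which certifies the structural-form
lower bound ``h1_k >= c_k > 0`` for every state and makes each state a
stable first-order filter.

Rate constants are drawn log-uniformly from ``[10^-1, 10^1]`` and base
inputs from a log-normal distribution, matching the sampling scheme of the
accuracy study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .reaction_model import ReactionNetwork

__all__ = [
    "GeneratorConfig",
    "generate_wnt_like_network",
    "sample_parameters",
    "sample_base_inputs",
    "make_toy_model",
    "toy_config",
    "desk_config",
    "full_scale_config",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the cascade generator.

    ``density`` is the probability that an allowed cross-layer binding
    reaction is instantiated; ``n_cofactors_per_layer`` downstream free
    proteins per cascade layer are input-fed, in addition to ligands,
    receptors and coreceptors.  All randomness flows from ``seed``.
    """

    n_ligands: int = 3
    n_receptors: int = 3
    n_coreceptors: int = 1
    n_readouts: int = 8
    depth: int = 2
    density: float = 0.8
    seed: int = 0
    n_cofactors_per_layer: int = 1
    param_log10_range: tuple[float, float] = (-1.0, 1.0)
    input_lognormal: tuple[float, float] = (0.0, 0.5)

    def __post_init__(self):
        for name in ("n_ligands", "n_receptors", "n_coreceptors", "n_readouts"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.depth < 0:
            raise ConfigurationError("depth must be >= 0")
        if not 0.0 < self.density <= 1.0:
            raise ConfigurationError("density must lie in (0, 1]")
        if self.n_readouts % 2:
            raise ConfigurationError(
                "n_readouts must be even (positive/negative readout pairs)"
            )
        if self.input_lognormal[1] <= 0:
            raise ConfigurationError("input_lognormal sigma must be > 0")


def toy_config(seed: int = 0) -> GeneratorConfig:
    """Minimal generated cascade (a handful of states)."""
    return GeneratorConfig(
        n_ligands=1, n_receptors=1, n_coreceptors=1, n_readouts=2,
        depth=1, density=1.0, seed=seed,
    )


def desk_config(seed: int = 0) -> GeneratorConfig:
    """Workstation-scale cascade: ~40 states, 8 inputs, 8 readouts."""
    return GeneratorConfig(
        n_ligands=3, n_receptors=2, n_coreceptors=1, n_readouts=8,
        depth=0, density=1.0, seed=seed, n_cofactors_per_layer=0,
    )


def full_scale_config(seed: int = 0) -> GeneratorConfig:
    """Full-scale preset: ~421 states, 60 inputs, 40 readouts."""
    return GeneratorConfig(
        n_ligands=7, n_receptors=7, n_coreceptors=2, n_readouts=40,
        depth=6, density=0.955, seed=seed, n_cofactors_per_layer=7,
    )


def sample_parameters(n: int, seed=0, log10_range: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """Rate constants ``10**v`` with ``v ~ Uniform(log10_range)``."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = log10_range
    return 10.0 ** rng.uniform(lo, hi, n)


def sample_base_inputs(
    n_samples: int, n_inputs: int, mu: float = 0.0, sigma: float = 0.5, seed=0
) -> np.ndarray:
    """I.i.d. log-normal base-input vectors, shape (n_samples, n_inputs)."""
    if sigma <= 0:
        raise ConfigurationError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    return rng.lognormal(mu, sigma, size=(n_samples, n_inputs))


def generate_wnt_like_network(config: GeneratorConfig) -> ReactionNetwork:
    """Build a layered ligand/receptor cascade network.

    Layer 0 holds input-fed ligands, receptors and coreceptors.  Binding
    produces ligand-receptor complexes, then signalosomes (complex +
    coreceptor).  Each of the ``depth`` downstream layers introduces
    input-fed cofactor proteins that bind the previous layer's complexes.
    Finally ``n_readouts/2`` precursor complexes each bind a shared
    activator (positive readout) and a shared repressor (negative
    readout).  Every species degrades first order.  Deterministic for a
    fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)

    species: list[str] = []
    inputs: dict[str, str] = {}
    reactions: list[dict] = []
    param_names: list[str] = []

    def add_species(name: str, fed: bool = False) -> str:
        species.append(name)
        if fed:
            inputs[f"u_{name}"] = name
        return name

    def add_reaction(reactants: dict, products: dict, tag: str) -> None:
        pname = f"k_{tag}"
        param_names.append(pname)
        reactions.append({"reactants": reactants, "products": products, "rate_param": pname})

    ligands = [add_species(f"LIG{i+1}", fed=True) for i in range(config.n_ligands)]
    receptors = [add_species(f"REC{i+1}", fed=True) for i in range(config.n_receptors)]
    coreceptors = [add_species(f"COR{i+1}", fed=True) for i in range(config.n_coreceptors)]

    # ligand-receptor complexes
    lr: list[str] = []
    for li in ligands:
        for re in receptors:
            if rng.random() <= config.density:
                c = add_species(f"{li}:{re}")
                add_reaction({li: 1, re: 1}, {c: 1}, f"bind_{c}")
                lr.append(c)
    if not lr:  # density guarantees >0 probability; force at least one pair
        c = add_species(f"{ligands[0]}:{receptors[0]}")
        add_reaction({ligands[0]: 1, receptors[0]: 1}, {c: 1}, f"bind_{c}")
        lr.append(c)

    # signalosomes: ligand-receptor complex + coreceptor
    prev_layer: list[str] = []
    for idx, c in enumerate(lr):
        if rng.random() <= config.density:
            co = coreceptors[idx % config.n_coreceptors]
            s = add_species(f"{c}:{co}")
            add_reaction({c: 1, co: 1}, {s: 1}, f"bind_{s}")
            prev_layer.append(s)
    if not prev_layer:
        co = coreceptors[0]
        s = add_species(f"{lr[0]}:{co}")
        add_reaction({lr[0]: 1, co: 1}, {s: 1}, f"bind_{s}")
        prev_layer.append(s)

    # downstream cascade layers
    for layer in range(1, config.depth + 1):
        cofactors = [
            add_species(f"CF{layer}_{i+1}", fed=True)
            for i in range(config.n_cofactors_per_layer)
        ]
        new_layer: list[str] = []
        for idx, c in enumerate(prev_layer):
            if rng.random() <= config.density:
                partner = (
                    cofactors[int(rng.integers(len(cofactors)))]
                    if cofactors
                    else None
                )
                if partner is None:
                    continue
                s = add_species(f"L{layer}C{idx+1}")
                add_reaction({c: 1, partner: 1}, {s: 1}, f"bind_{s}")
                new_layer.append(s)
        if new_layer:
            prev_layer = new_layer

    # terminal readout pairs sharing precursors
    activator = add_species("ACT", fed=True)
    repressor = add_species("REP", fed=True)
    readouts: list[str] = []
    n_pairs = config.n_readouts // 2
    for i in range(n_pairs):
        precursor = prev_layer[i % len(prev_layer)]
        pos = add_species(f"POS{i+1}")
        neg = add_species(f"NEG{i+1}")
        add_reaction({precursor: 1, activator: 1}, {pos: 1}, f"bind_{pos}")
        add_reaction({precursor: 1, repressor: 1}, {neg: 1}, f"bind_{neg}")
        readouts.extend([pos, neg])

    # first-order degradation for every species
    for sp in species:
        pname = f"k_deg_{sp}"
        param_names.append(pname)
        reactions.append({"reactants": {sp: 1}, "products": {}, "rate_param": pname})

    if not reactions:
        raise ConfigurationError("configuration produced no reactions")

    lo, hi = config.param_log10_range
    values = 10.0 ** rng.uniform(lo, hi, len(param_names))
    parameters = dict(zip(param_names, values.tolist()))

    return ReactionNetwork(
        species, reactions, parameters, inputs, readouts,
        name=f"wnt_like(seed={config.seed})",
    )


# ---------------------------------------------------------------------------
# analytic toy fixtures
# ---------------------------------------------------------------------------

def _decay1() -> ReactionNetwork:
    # dx/dt = u - 2x; steady state x = u/2
    return ReactionNetwork(
        species=["X"],
        reactions=[{"reactants": {"X": 1}, "products": {}, "rate_param": "k_deg"}],
        parameters={"k_deg": 2.0},
        inputs={"u": "X"},
        readouts=["X"],
        name="decay1",
    )


def _bind2() -> ReactionNetwork:
    # A + B -> C (k=1); A, B, C degrade at rate 1; inflows uA, uB.
    # At u = (2, 2): steady state (1, 1, 1) from s^2 + s - 2 = 0.
    return ReactionNetwork(
        species=["A", "B", "C"],
        reactions=[
            {"reactants": {"A": 1, "B": 1}, "products": {"C": 1}, "rate_param": "k_bind"},
            {"reactants": {"A": 1}, "products": {}, "rate_param": "k_deg_A"},
            {"reactants": {"B": 1}, "products": {}, "rate_param": "k_deg_B"},
            {"reactants": {"C": 1}, "products": {}, "rate_param": "k_deg_C"},
        ],
        parameters={"k_bind": 1.0, "k_deg_A": 1.0, "k_deg_B": 1.0, "k_deg_C": 1.0},
        inputs={"uA": "A", "uB": "B"},
        readouts=["C"],
        name="bind2",
    )


def _chain3() -> ReactionNetwork:
    # u -> A -> B -> C with unit conversion and degradation rates;
    # steady state (u/2, u/4, u/4).
    return ReactionNetwork(
        species=["A", "B", "C"],
        reactions=[
            {"reactants": {"A": 1}, "products": {"B": 1}, "rate_param": "k_ab"},
            {"reactants": {"B": 1}, "products": {"C": 1}, "rate_param": "k_bc"},
            {"reactants": {"A": 1}, "products": {}, "rate_param": "k_deg_A"},
            {"reactants": {"B": 1}, "products": {}, "rate_param": "k_deg_B"},
            {"reactants": {"C": 1}, "products": {}, "rate_param": "k_deg_C"},
        ],
        parameters={
            "k_ab": 1.0, "k_bc": 1.0,
            "k_deg_A": 1.0, "k_deg_B": 1.0, "k_deg_C": 1.0,
        },
        inputs={"u": "A"},
        readouts=["C"],
        name="chain3",
    )


def _affine_n(n: int = 8) -> ReactionNetwork:
    """Purely linear conversion chain: no bimolecular reactions.

    x1 -> x2 -> ... -> xn with distinct first-order conversion and
    degradation rates; inflow u1 feeds x1 and u2 feeds the middle of the
    chain.  The state Jacobian is constant, so the Taylor linearization is
    exact everywhere — the package's zero-error oracle.
    """
    if n < 2:
        raise ConfigurationError("affine_n requires n >= 2")
    species = [f"x{i+1}" for i in range(n)]
    reactions, parameters = [], {}
    for i in range(n - 1):
        pname = f"k_conv_{i+1}"
        parameters[pname] = 1.0 + 0.1 * i
        reactions.append(
            {"reactants": {species[i]: 1}, "products": {species[i + 1]: 1}, "rate_param": pname}
        )
    for i in range(n):
        pname = f"k_deg_{i+1}"
        parameters[pname] = 0.5 + 0.05 * i
        reactions.append({"reactants": {species[i]: 1}, "products": {}, "rate_param": pname})
    inputs = {"u1": species[0], "u2": species[n // 2]}
    readouts = species[-2:]
    return ReactionNetwork(
        species, reactions, parameters, inputs, readouts, name=f"affine_{n}"
    )


_TOYS = {
    "decay1": _decay1,
    "bind2": _bind2,
    "chain3": _chain3,
    "affine_n": _affine_n,
}


def make_toy_model(name: str, **kwargs) -> ReactionNetwork:
    """Return a named analytic fixture.

    ``name`` is one of ``decay1``, ``bind2``, ``chain3``, ``affine_n``
    (the last accepts ``n=<size>``).
    """
    try:
        factory = _TOYS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown toy model '{name}'; choose from {sorted(_TOYS)}"
        ) from None
    return factory(**kwargs)
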