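# pathlin

**Linearization-accuracy analysis for mass-action signaling ODE networks.**

Large intracellular signaling models — receptor–ligand cascades such as the
canonical WNT/β-catenin pathway, with hundreds of species and rate
constants — are stiff nonlinear ODE systems

```
dx/dt = f(x, p, u),        y = g(x, p, u),
```

where `x` are species concentrations, `p` positive rate constants, `u`
exogenous inflows and `y` a readout subvector of `x`. Computing a drug- or
condition-response means forward simulating to a steady state for every
input vector, which is expensive when thousands of input conditions must be
screened. A Taylor linearization around a base steady state `(x_ss, u_bf)`,

```
d(x − x_ss)/dt = A (x − x_ss) + B (u − u_bf),
A = ∂f/∂x |_(x_ss, u_bf),    B = ∂f/∂u,
```

replaces each simulation by **one linear solve**,
`x_dev,ss = −A⁻¹ B (u_final − u_bf)` — but is only trustworthy for inputs
close to the base. `pathlin` is a toolkit for quantifying exactly *how*
close: it builds and linearizes mass-action reaction networks, co-simulates
the linear and nonlinear models through an augmented *agreement system*
whose trajectory exposes the linearization error
`e(t) = x_nonlin − x_dev − x_ss`, runs a Monte Carlo workflow over
multiplicative input perturbations

```
u_i = (1 + r_noise − 2 r_noise d_i) ∘ u_bf,     d_i ~ U[0,1]^m,
```

and scores the clipped linear predictions with mean relative error (MRE),
mean squared error (MSE) and the error/response standard-deviation ratio.
Validity diagnostics (hyperbolicity of the anchor, local/global Lyapunov
exponents, contraction certificates of the flow map, exact second-order
Taylor-term indicators) flag operating points where a linearization should
not be trusted. It is aimed at computational systems biologists who want to
know when a cheap linear surrogate of their pathway model is safe to use.

Because published cascade models of this class are rarely deposited with
their input data, the package ships a seeded synthetic generator producing
WNT-like layered networks (input-fed ligands/receptors/coreceptors, binding
cascades, paired positive/negative readouts, first-order degradation on
every species) at anything from toy to full scale (~421 states, 60 inputs,
40 readouts), plus analytic toy fixtures with closed-form steady states.

## Worked example

```python
import numpy as np
from pathlin import (
    make_toy_model, simulate_to_steady_state, linearize,
    linear_steady_state, build_agreement_system, simulate_agreement,
)

net = make_toy_model("bind2")          # A + B -> C, all species degrade
ss = simulate_to_steady_state(net, np.array([2.0, 2.0]))
print(ss.x_ss)                          # [1. 1. 1.]

lin = linearize(net, ss)
pred = linear_steady_state(lin, np.array([2.2, 2.2]))
print(pred[2])                          # 1.1333333333333335

res = simulate_agreement(build_agreement_system(net, lin), np.array([2.2, 2.2]))
print(res.x_nonlin_ss[2])               # 1.1347524157501472
print(res.e_ss[2])                      # 0.001419082416813655
```

A +10% step on both inflows moves the complex C to 1.13475 in the nonlinear
model; the one-solve linear prediction says 1.13333, so the linearization
error on this readout is ~0.0014 concentration units (0.13%) — the
second-order term the Taylor expansion discarded. Running the Monte Carlo
workflow on a synthetic cascade:

```python
from pathlin import generate_wnt_like_network, desk_config, sample_base_inputs, run_workflow

net = generate_wnt_like_network(desk_config(3))
base = sample_base_inputs(10, net.n_inputs, seed=5)
print(run_workflow(net, base, seed=11).table)
#    r_noise       scope  std_ratio_pct    mre_pct           mse  n_excluded
# 0     0.10  all_states       2.349467   0.434775  4.715808e-06           0
# 1     0.10    readouts      11.690460   0.660388  3.620916e-07           0
# 2     0.25  all_states       5.730427   2.768356  1.809460e-04           0
# 3     0.25    readouts      29.321659   4.144887  1.371942e-05           0
# 4     0.50  all_states      10.578042  12.465869  2.158048e-03           0
# 5     0.50    readouts      57.477903  18.297502  2.112211e-04           0
```

MRE grows roughly quadratically with the perturbation range (log–log slope
≈ 2.1 here): ±10% input noise leaves the linear surrogate within half a
percent of the nonlinear steady states, ±50% pushes it past 12%.

The same pipeline is available from the shell:

```bash
pathlin generate --preset desk --seed 3 -o model.json
pathlin mc-run model.json --samples 50 --workflows 4 --seed 7 \
        -o report.json --csv report.csv
pathlin report report.json --plot trend.png
```

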