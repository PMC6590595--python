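# Methods

## Model class

`pathlin` works with mass-action reaction networks restricted to at most
bimolecular reactions with reactant-side stoichiometry ≤ 1 per species.
This grammar makes the right-hand side *bilinear* in the state: every row
can be collected into the structural form

    dx_k/dt = −x_k · h1_k(x_i, p) + h2_k(x_i, p) + u_k,

where `h1_k` aggregates first-order loss coefficients (1/time), `h2_k` the
production driven by the other species (conc/time), and `u_k` is a
zero-order exogenous inflow. The package *requires* every species to carry
a first-order self-loss reaction (degradation or conversion), which
certifies a constant lower bound `h1_k ≥ c_k > 0`. Three consequences are
load-bearing and are exploited throughout:

1. **Positivity.** At a zero crossing of `x_k` the row reduces to
   `h2_k + u_k ≥ 0`, so trajectories started nonnegative stay nonnegative.
   Negative values in the *linear* model are therefore unphysical artifacts
   and are clipped to `[0, ∞)` before scoring.
2. **Input exactness.** Inflows enter additively, so the input Jacobian
   `B` is a constant 0/1 incidence matrix and the state Jacobian never
   depends on `u`: the Taylor expansion discards no input terms, and all
   linearization error comes from the state nonlinearity.
3. **Exact second differences.** A bilinear RHS has identically zero third
   derivatives, so the discarded second-order Taylor term is computed
   *exactly* by one symmetric second difference
   `[f(x+dx) + f(x−dx) − 2f(x)]/2` (a finite-difference fallback would be
   needed only for future non-polynomial kinetics).

Rate laws outside this grammar (Hill, Michaelis–Menten), delays and
stochastic dynamics are out of scope. A `rhs_extension` hook exists solely
so the input-linearity probe can be shown to *detect* u-dependent kinetics;
analytic Jacobians refuse to operate while an extension is attached.

## Steady states and the agreement system

Steady states are found by chunked implicit integration (SciPy BDF,
variable order/step, analytic Jacobian supplied) with geometrically growing
time chunks, declaring convergence when

    ||f(x)||_∞ < tol_ss · (1 + ||x||_∞),       tol_ss = 1e-9 default,

followed by a damped-Newton polish of the root (tolerance 1e-13 relative)
and clipping of sub-roundoff negative components. Integrator tolerances
default to rtol 1e-8 / atol 1e-10. A divergence guard aborts when the
trajectory norm exceeds 1e9 × the initial scale, signalling an unstable
model or a perturbation that left the stable region. Step inputs are
applied as a Heaviside switch at t = 0; only the final value matters for
the steady states compared here.

The agreement system stacks the linear deviation dynamics over the
nonlinear model (2n states, block-diagonal Jacobian) and starts at
`[0; x_ss]`, so `e(0) = 0` and `e(t) = x_nonlin − x_dev − x_ss` is the
linearization error directly. After the joint residual test passes, each
half's fixed point is sharpened exactly — the linear one by a single solve
of `A x_dev = −B Δu`, the nonlinear one by Newton — so steady-state error
metrics are limited by conditioning, not by integration tolerance.

## Linearization services

* `linear_steady_state` refuses matrices with condition number above 1e12
  (a non-hyperbolic anchor), raising a singularity error rather than
  returning garbage.
* Hyperbolicity uses the tolerance `tol_re = 1e-8 × spectral radius`
  (floor 1e-12 for nilpotent corner cases): an eigenvalue real part is
  "zero" only relative to the system's own timescales.
* `required_input_deviation` solves `B Δu = −A Δx_target` by minimum-norm
  least squares and reports the residual, so unreachable targets are
  detectable instead of silently projected.
* Iterative relinearization advances the locally frozen linear model
  exactly over each increment via the matrix exponential,
  `x_{k+1} = x_k + (e^{J(x_k) dt} − I) J(x_k)^{-1} f(x_k, u)`.
  Because each step is exact for the frozen model, the iteration's fixed
  point satisfies `f(x) = 0` for *any* dt: the converged result is the
  nonlinear steady state, while the visited path tracks the nonlinear
  trajectory with O(dt²) truncation error (the package verifies both
  properties). With `dt_schedule=None` each step jumps to the frozen
  model's own fixed point — a Newton step — which for a constant Jacobian
  reproduces the one-solve step prediction after a single iteration.

## Monte Carlo accuracy workflow

For each base input sample: simulate to `x_ss0`, linearize there, then for
each noise range `r_noise ∈ {10%, 25%, 50%}` perturb the input
multiplicatively with direction vectors `d_i ~ U[0,1]^m` **drawn once per
workflow run and reused across noise levels** (so levels differ in
magnitude, not direction), co-simulate the agreement system, clip the
linear prediction, and score:

* `MSE = mean((x_lin − x_nonlin)²)`,
* `MRE = mean(|x_lin − x_nonlin| / x_nonlin)` in percent — the absolute
  value makes it a proper nonnegative error,
* `std_ratio = std(x_lin − x_nonlin) / std(x_nonlin − x_ss0)` in percent,

each on two scopes (all states; readouts only), averaged arithmetically
over samples. Two pooling conventions were genuinely open and are fixed as
follows: standard deviations are taken *across scope components of a
single steady-state vector* and then averaged across samples; MRE is
averaged over components first, then samples. Components whose nonlinear
steady state falls below `eps_den = 1e-9 × max component` are excluded
from the MRE denominator (with the exclusion count reported): clipping
fixes the numerator of the small-denominator problem, the guard fixes the
denominator. Failed samples (non-convergent or unstable simulations) are
excluded and counted rather than aborting the run.

`fit_error_trend` summarizes a report by the least-squares slope of
log MRE vs log r_noise. For the bilinear model class the leading error
term is quadratic in the deviation, so slopes near 2 are expected and
observed (≈ 2.1 on both the closed-form fixture and generated cascades).

## Diagnostics

The discrete-time map Φ is the flow over a sampling period `T_s`,
realized by integrating the ODE; its Jacobian `J(Φ, x)` comes from the
variational matrix ODE `dΨ/dt = J(x(t)) Ψ` integrated jointly with the
state (finite differences of stiff flows are ill-conditioned; a
frozen-Jacobian `e^{J T_s}` shortcut is available and exact for constant
Jacobians). Local Lyapunov exponents are `ln ||Ψ y|| / T_s` for unit
directions `y`; the global estimate propagates the direction along the
trajectory and averages per-step exponents. Euclidean norms are used
throughout.

Contraction is certified by the *sufficient* spectral-norm condition
`c_max = max_x ||J(Φ, x)||₂ < 1` over sampled points, not by the
line-segment construction (which is a proof device; a test verifies the
segment inequality numerically on collinear samples). `T_s` matters for
non-normal Jacobians: over a fraction of the fastest timescale transient
growth can push the spectral norm above 1 even for asymptotically stable
cascades, so contraction should be probed at about one *slowest* time
constant, `T_s ≈ 1/|max Re λ|`; as `T_s → 0`, `log(c_max)/T_s` recovers
the spectral abscissa for normal Jacobians.

## Synthetic generator

The generator emulates the class of receptor–ligand cascade models used in
the accuracy study, whose concrete equations and input data are not
published: input-fed ligands, receptors and coreceptors; ligand–receptor
binding; signalosome formation with coreceptors; `depth` downstream layers
of input-fed cofactors binding the previous layer's complexes; and paired
positive/negative terminal readouts sharing precursors. Every species
degrades first order, so generated networks satisfy the structural form by
construction; the default topology is acyclic (binding only), which
empirically yields stable hyperbolic fixed points, matching the intended
operating regime of the linearization.

Defaults and their rationale:

* rate constants log-uniform on `[10⁻¹, 10¹]` — the sampling scheme of the
  accuracy study;
* base inputs i.i.d. log-normal with `(μ, σ) = (0, 0.5)`: the real input
  samples behind the study's fitted log-normal are unavailable, so σ was
  fixed once at a value giving ~±2.5× input spread, a realistic
  concentration range without driving toy networks unstable;
* `desk` preset ≈ 28 states / 8 inputs / 8 readouts for interactive work;
  `full` preset (7 ligands, 7 receptors, 2 coreceptors, depth 6, density
  0.955) reproduces the full-scale dimensions ~421 states / 60 inputs /
  40 readouts within ±5% across seeds.

What passing tests on generated networks do **not** show: real pathways
contain feedback loops (here off by default), conservation cycles,
Michaelis–Menten-reduced steps and correlated inputs; synthetic results
demonstrate the *methodology* (error growth laws, diagnostics behavior),
not biological parameter realism.

## Problem sizes used by tests and the acceptance script

Monte Carlo runs use 50 input samples on generated cascades of ~15–30
states at noise ranges {10%, 25%, 50%} (plus a wider {5…40%} sweep on the
closed-form fixture), 4 parameter vectors per study; the CLI defaults
mirror these. These sizes give stable qualitative conclusions (strict MRE
growth, slope ≈ 2, ratio MRE(50%)/MRE(10%) ≫ 3) while keeping a full run
in tens of seconds; the full-scale preset is available but not exercised
by the default suite.

## Known limitations

* Only mass-action (≤ bimolecular) kinetics; no conservation-law handling
  beyond what degradation provides.
* Contraction and Lyapunov estimates sample finitely many points and
  directions; they certify nothing outside the sampled region.
* The agreement system shares one integrator tolerance between both
  halves; error trajectories below ~1e-8 are integrator noise.
* SBML import/export is not provided; the native model format is the
  JSON/YAML reaction-list schema.
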