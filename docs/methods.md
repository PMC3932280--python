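# Methods

## Model

The package implements the reaction–diffusion predator–prey system

```
N_t = D1 ΔN + ε (1 − N/K) N − a φ(N) P
P_t = D2 ΔP − M(P) P + b φ(N) P
```

on an interval `(0, ℓ)` with homogeneous Neumann (no-flux) boundary
conditions and nonnegative initial fields, together with its reduced
(diffusion-free) ODE. The predator mortality
`M(P) = (γ + δP)/(1 + P)` interpolates between a low-density mortality
`γ` and a crowding mortality `δ > γ`; it is bounded and increasing, so
`γ ≤ M(P) < δ` always. The functional response `φ` is an arbitrary
consumption-rate curve subject to five structural hypotheses (C¹ with
`φ(0)=0`; `φ(N)/N` decreasing and ≤ `M̃`; `0 ≤ φ ≤ L`; `|φ′| ≤ H`;
increasing on `[0, l]` with `K < l`, required **strictly**). Both
classical Holling forms satisfy them with analytic constants:

| response | φ(N) | M̃ | L | H | l |
|---|---|---|---|---|---|
| Holling II | N/(β+N) | 1/β | 1 | 1/β | ∞ |
| Holling IV | N/(β+N²) | 1/β | 1/(2√β) | 1/β | √β |

For user-supplied responses the constants are grid suprema over
`[0, N_max]` (default 10⁵ points) inflated by 1 %: grid maxima are lower
bounds of the true suprema, and the inflation makes them usable as
certified upper bounds at the cost of 1 % conservatism. Smoothness is
certified by comparing the supplied derivative against central
differences at relative tolerance 10⁻⁴ (with an `O(h)` absolute floor
so smooth extrema are not flagged); mismatches are recorded as kink
locations and fail hypothesis (i). `l = ∞` is the sentinel for globally
increasing responses, making the monotone-range hypothesis pass for
every `K`. Expression-defined responses are parsed symbolically under a
character whitelist and a function whitelist, differentiated exactly,
and routed through the same grid certification.

## Equilibria and classification

The reduced ODE is rewritten as
`N′ = a φ(N) (f(N) − P)`, `P′ = P(−M(P) + b φ(N))` with the prey
nullcline `f(N) = ε(1−N/K)N/(a φ(N))` (value `ε/(a φ′(0))` at the
removable singularity `N = 0`). Interior equilibria are roots of
`g(N) = b φ(N) − M(f(N))` on `(0, K)`, located by a uniform 10⁴-point
sign scan on `(10⁻⁹K, K − 10⁻⁹K)` refined by Brent's method to machine
precision; hump-shaped responses can yield several roots and all are
returned. The Jacobian at an interior point uses the analytic
quotient-rule derivative

```
f′(N) = [ε(1 − 2N/K) φ(N) − ε(1 − N/K) N φ′(N)] / (a φ(N)²)
```

(cross-checked against finite differences in the tests) and
`M′(P) = (δ−γ)/(1+P)²`; boundary equilibria get their closed-form
triangular matrices. Classification follows the trace–determinant
plane with a nonhyperbolicity tolerance of 10⁻¹² on `|det|` and
`|trace|`; below it no stability claim is made. When a coexistence
state has `N0 ∈ [K/2, K]`, `f′(N0) ≤ 0` follows from the hypotheses and
stability is guaranteed; the code records this certificate and raises
if the numerical classification ever contradicted it.

## Discretisation and time integration

Space: node-centred uniform grid (endpoints included), second-order
central Laplacian with mirrored ghost nodes, so constant fields map to
zero exactly and zero flux is enforced to second order. The state
interleaves `(N_i, P_i)` per node, giving a banded Jacobian (bandwidth
2) that the stiff LSODA integrator exploits; a 201-node, t=500 run
takes well under a second. Defaults: `ℓ = π`, `n = 201` (so the first
positive Neumann eigenvalue is exactly 1 in the continuum, convenient
for threshold checks), `t_end = 500`, PDE tolerances
`rtol = 10⁻⁸ / atol = 10⁻¹¹`, ODE tolerances `10⁻⁹ / 10⁻¹²` (the
energy diagnostics need a smoothly decreasing signal).

Nonnegativity policy: saved values in `[−10⁻¹⁰, 0)` — solver noise — are
clamped to zero; anything below `−10⁻¹⁰` aborts the run with a hint to
tighten tolerances, rather than silently masking an instability.

Tail diagnostics (surrogates for `limsup`/`liminf` statements) use the
last 20 % of saved times after a burn-in of `max(10, 0.1 t_end)` time
units. The predator counts as extinct when its tail maximum is below
10⁻⁶.

## Long-time verdicts

- **Dissipativity**: the absorbing box is `[0, K] × [0, M0]` with
  `M0 = ε(K+1)/(a φ(K+1))`; the checker verifies tail maxima against
  `K + tol` and `M0 + tol` (default `tol = 10⁻³`).
- **Regime**: permanence iff the invasion margin `b φ(K) − γ` is
  positive; the boundary case `b φ(K) = γ` is assigned to the
  extinction branch, whose theory covers the non-strict inequality.
  The verdict is diffusion-independent by construction and the
  persistence margins `(q, Q, w, W)` are measured empirically from the
  trajectory tail (`q, Q` bounding prey, `w, W` bounding predator).

## Spatial stability and patterns

Mode matrices `B_j = A − λ_j diag(D1, D2)` over the Neumann spectrum
`λ_j = (jπ/ℓ)²`. Only finitely many modes can be unstable: the scan
cutoff is the larger of `trace(A)/(D1+D2)` (beyond which the trace is
negative) and the largest real root of the upward parabola
`det B(λ) = D1D2 λ² − (A11 D2 + A22 D1) λ + det A`, plus a 10 % margin;
degenerate diffusion (`D1 D2 = 0`) falls back to a fixed scan up to
`λ = 10⁴/ℓ²`. A Turing instability is a window of `λ` with
`det B(λ) < 0`; the scanner locates it on a 10⁴-point logarithmic grid
and refines the edges by root bracketing. Under the certified sign
pattern (`A11, A22, A12 < 0`, `A21 > 0`) no window can exist.

The no-pattern certificate applies when `γ < b φ(K) < δ`: positive
steady states then obey `max N ≤ K`, `max P ≤ K0 = (bφ(K)−γ)/(δ−bφ(K))`,
and the thresholds

```
μ1 D1 > ε + aL/2 + (a + b/2) K0 H
μ1 D2 > −γ + bL + aL/2 + (b/2) K0 H
```

exclude nonconstant steady states. `μ1 = (π/ℓ)²` is taken from the
continuum interval formula, not the discrete grid operator, because
the statement concerns the continuum Laplacian; the interval geometry
is the package's test-domain convention.

## Lyapunov diagnostics

The energy `E = ∫ [N − N0 − N0 ln(N/N0) + P − P0 − P0 ln(P/P0)] dx` is
evaluated by trapezoidal quadrature (second-order on generic smooth
fields; superconvergent on Neumann-compatible ones). A slope is counted
nonincreasing when `dE/dt ≤ 10⁻⁸ · max E`, absorbing quadrature noise.
The symbolic sufficient condition for global stability exists in two
defensible readings of the same collapsed source expression; the
default parse "A" is

```
cond1 = (q+N0) ε/(K Q) − ε q − a M̃/2 − b P0 H/(2w) > 0
cond2 = γ/W − b L w − b P0 H/(2w) − a M̃/2 > 0
```

with parse "B" (leading term `(q+N0) ε Q/K`) selectable. The verdict
always records the parse used and pairs it with the empirical test
(monotone fraction ≥ 0.99, terminal spatial variance < 10⁻⁸, terminal
state within 10⁻² of the equilibrium), which is authoritative: the
symbolic condition is sufficient-only and conservative — on the clean
preset it evaluates negative while the energy visibly descends. The
bounds `(q, Q, w, W)` default to measured persistence margins deflated/
inflated by 10 %; whether sharper bounds could be optimized instead is
left open, as the empirical branch already decides the cases of
interest. The symbolic branch refuses configurations with multiple
interior equilibria (its theory presumes uniqueness).

## Synthetic initial data

`random_init` builds `base · (1 + amplitude · s(x))` with `s` a seeded
combination of cosine modes 1–5, rescaled so `|s| < 1` strictly; cosine
modes have zero slope at both ends, so the no-flux condition holds
exactly at t = 0. Amplitude 0.5 (the preset default) is a strong, 50 %
heterogeneous perturbation — deliberately far from the linear regime —
while amplitudes ≤ 0.01 probe the linearised certificates. What these
synthetic fields do **not** emulate: rough or discontinuous initial
data, localized invasions fronts, or stochastic demographic noise;
passing tests certify the deterministic smooth-data theory only.

## Preset study conditions

All presets use `ε = 1, K = 2, a = b = 1, ℓ = π, n = 201, t_end = 500`
and amplitude-0.5 initial data unless noted: `clean_stable`
(`γ = 0.4, δ = 0.6, D = 0.1`; coexistence at exactly `(1,1)`),
`extinction` (`γ = 0.9, δ = 1.2`), `permanent_h2` (`γ = 0.5, δ = 0.7`),
`permanent_h4` (Holling IV with `β = 9`, `γ = 0.1, δ = 0.2`; `K = 2 <
l = 3`), `nonexistence_cert` (`γ = 0.4, δ = 0.8, D1 = 5, D2 = 3`, which
clears the thresholds 4.5 and 2.1), and `hypothesis_fail_h4`
(Holling IV with `β = 4`, `K = 3 > l = 2`, a deliberate violation).

## Numerical choices and limitations

- Equilibrium residual tolerance 10⁻¹⁰ (max norm of the reaction terms);
  Brent refinement reaches machine precision, so this is slack.
- The 10⁴-point equilibrium scan can in principle miss root pairs closer
  than `≈ 2·10⁻⁴ K`; the test-suite's 10⁶-point oracle guards the
  regimes actually exercised.
- Interval domains only; no 2-D habitats, advection, cross-diffusion or
  time-periodic forcing. No bifurcation continuation or limit-cycle
  tracking; nonhyperbolic states are reported as such, not unfolded.
- Grid-refinement convergence is verified on short transients: long
  runs in the stable regimes converge to constants on every grid, which
  would make order measurement ill-conditioned.
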