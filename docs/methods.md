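# Methods

## The model

A neural circuit stores a learned input-output mapping in a weight vector
`w` of N adaptive elements. Any state has a scalar task error `F[w]` ≥ 0 (the
loss landscape), twice differentiable in `w`. Per small time interval the
weight change decomposes as

    dw = dc + de

where `de` (synaptic fluctuations) is task-independent — its direction is
uncorrelated, in expectation, with the gradient and with `H dc` — and `dc`
(compensatory plasticity) moves downhill in expectation. Expanding `F` to
second order and taking expectations over the fluctuation distribution,

    E[dF] = dc·∇F + ½‖dc‖² Q_w[dc] + ½‖de‖² Q_w[de],

with `Q_w[v] = v̂ᵀ∇²F[w]v̂` the directional curvature (depends only on the
direction of `v`). Two consequences drive everything in the package:

* **Optimal step length.** Minimising over `‖dc‖` for a fixed downhill
  direction gives `‖dc‖* = (−d̂·∇F̂ / Q_w[dc]) ‖∇F‖`, valid for
  `Q_w[dc] > 0`; magnitudes are non-negative, so uphill directions are
  clamped to zero rather than given a negative length.
* **Steady-state ratio.** Imposing `E[dF] = 0` (maintenance, not learning)
  at the optimal magnitude yields `‖dc‖*² / ‖de‖² = Q_w[de] / Q_w[dc]`.
  During learning (`E[dF] < 0`) the optimal magnitude is at least the
  steady-state value; this direction is exercised as a property test, not
  exposed as an operation, since it is an inequality.

An isotropically random direction has expected curvature `Tr(∇²F)/N`. The
gradient direction on a quadratic landscape with eigenvalues `λ_i` and
displacement projections `c_i` has curvature
`Q[∇F] = Σc_i²λ_i³ / Σc_i²λ_i²` ≥ the mean eigenvalue, with the gap growing
with eigenvalue spread: the gradient is biased toward high-curvature
directions. Hence for first-order compensation the optimal ratio is below
one; for zero-order (random-probe) rules `Q[dc] ≈ Q[de]` and the ratio is
about one; the Newton direction on a positive-definite quadratic backtracks
the displacement exactly, also giving one.

## Simulated system

The network tasks follow a fixed protocol: rate-based feedforward networks
without biases, `r = σ(Wu)` with the logistic `σ` applied at every layer
including the output (the defining equation covers every neuron, not only
hidden ones), or fully linear. The standard nonlinear architecture is
12-20-10 (N = 440), the linear one 12-10 (N = 120). Weights are
Xavier-initialised; "Xavier" is read as the uniform variant
U(±√(6/(fan_in+fan_out))) by default, with the normal variant available via
`distribution="normal"` since the convention is ambiguous. Task error is the
mean over a fixed suite of unit-Gaussian input vectors (1000 at full scale)
of the squared output mismatch against a frozen copy of the initial network
(student-teacher maintenance: the error at t = 0 is exactly zero). The input
suite is generated once per network and held fixed for the whole run.

Fluctuations are white noise rescaled to an exact per-step norm (norm 2 in
the staircase protocol; a swept variable elsewhere). Compensation is
`dc = −γ₁∇F̂ + γ₂ν̂` with fresh Gaussian `ν` each step (i.i.d. across steps;
the time-indexed noise is taken as uncorrelated since no correlation
structure is specified); `√(γ₁²+γ₂²)` sets the magnitude and `γ₂:γ₁` the
imprecision. By default the sum is *not* renormalised — the formula is
applied literally, and the realised norm differs from the target by an
O(1/√N) cross-term; `renormalize=True` is available where exact ratio
control matters. At the start of a maintenance run the gradient is exactly
zero (student = teacher); the simulator then applies only the noise
component of the rule for that step, since the descent direction is
undefined at a stationary point.

The zero-order rule is deliberately the minimal member of the exploratory
family: draw a random unit direction, probe the loss a distance
`probe_scale` (default 1e-3·(1+‖w‖∞)) along it, keep the direction if the
loss fell and oppose it otherwise, stepping the configured magnitude. Its
accepted directions carry average curvature, which is the property the
theory needs. The Newton rule is implemented only on positive-definite
quadratics and errors elsewhere; Hessian-accurate rules are treated as a
theoretical reference point, not a biologically plausible mechanism.

Randomness: every run derives independent fluctuation and compensation
streams from a single `SeedSequence`, and sweeps spawn per-repeat and
per-cell children, so identical seeds give bit-identical trajectories and no
two noise sources alias.

## Numerical choices

* Network gradients are analytic (hand-derived backpropagation, full batch
  over the input suite every step). Hessian-vector products use a central
  difference of two analytic gradients with step `h = 1e-5·(1+‖w‖∞)`;
  on quadratics they are exact. The networks are small, so a second
  reverse-mode pass would buy accuracy nobody needs at the tolerances used
  (hvp agreement with dense finite-difference Hessians is ~1e-3 relative).
* `hutchinson_trace` uses Rademacher probes (exact per probe for diagonal
  Hessians, unbiased in general).
* "Highly trained" (PSD) classification tolerates eigenvalues down to
  −1e-8·‖H‖₂ to absorb finite-difference noise.
* Out-of-regime curvature inputs (non-positive `Q`) raise errors rather
  than returning NaN: the steady-state formula's derivation restricts its
  validity and silent NaNs would propagate into sweep tables.
* The steady-state ratio formula needs `Q` values "at steady state". The
  steady-state weight distribution is symmetric about the optimum, so the
  time-averaged *weights* sit at the minimiser, where the gradient direction
  is undefined. The package's convention is therefore the time-average of
  `Q_w[∇F]` over tail-of-trajectory snapshots, which is well defined and
  stable; this is the operating-point value used in the theory-vs-simulation
  comparison.
* Sweep argmin ties break toward the smallest ratio, so a reported optimum
  is never inflated.
* Aborted cells (non-finite loss) are excluded from sweep statistics with a
  warning; the trajectory prefix is kept for diagnosis.

## The isotropic closed form

On `F = ½‖w−w*‖²` with exact-gradient compensation of norm `m` and
fluctuations of norm `e`, the distance to the minimiser obeys
`E[d'²] = (d−m)² + e²` per step, whose fixed point is `d = (m²+e²)/(2m)`
with `F = d²/2`; minimising over `m` gives `m = e` (ratio one, as the ratio
formula predicts for equal curvatures). The formula is valid on the branch
`d ≥ m`; with `e = 0` trajectories instead converge to the minimiser once
the distance falls below the step length. This recurrence was re-derived and
is verified against an independent scalar iteration and against stochastic
simulation in the test suite.

## Problem sizes

Full-scale protocol: 8000 steps per run, steady-state window of the last
500 timepoints, 8 repeats per sweep cell, 1000-input suites. The shipped
test suite and the acceptance script use a scaled-down preset — 4000 steps,
4 repeats, 200-input suites, the same 500-point window, and a 7-point
geometric ratio grid from 0.25 to 2.0 — chosen so a full replication run
completes on a laptop while leaving the argmin statistics stable across
seeds. The staircase schedule (not fully specified by the protocol) defaults
to 7 geometric stages from 0.25·e to 2·e, 1500–2000 steps per stage with the
first 1000–1500 discarded as transient. The quadratic test bed uses N = 30
with eigenvalues log-spaced over [0.1, 10] (condition number 100) unless a
test states otherwise.

## What the generator does and does not emulate

The synthetic system reproduces the statistical structure the theory rests
on: unit-Gaussian inputs, Xavier weights, fixed-norm white-noise
fluctuations, gradient-plus-noise compensation. It does not emulate spiking
dynamics, biases, recurrence, structured (e.g. homeostatic or correlated)
fluctuations beyond the optional subspace restriction, synapse
creation/elimination, or any dependence of noise on activity. Passing tests
therefore show that the curvature theory holds for the idealised dynamics it
was derived for — not that real circuits implement these rules.

## Known limitations

* Hessian-vector products on networks are finite-difference based;
  tolerances below ~1e-4 relative are not meaningful there.
* The steady-state ratio prediction is a self-consistency condition at an
  operating point that itself depends on the dynamics; near the optimum the
  steady-error curve is flat, so sweep argmins are only resolved to about
  one grid step.
* `classify_trained_state` forms a dense Hessian and is guarded at
  N ≤ 2000; larger problems must pass precomputed trace/eigenvalue
  estimates.
* The subspace-restricted fluctuation generator uses eigenvectors computed
  at the initial weights; on nonlinear tasks the "low-curvature subspace"
  drifts over a long run.
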