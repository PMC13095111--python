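# Methods

## Model

A steering circuit maps a heading `H` and a goal direction `G` (azimuths in
degrees) to a scalar turn command. Three populations are involved:

* **Compass neurons** with preferred firing directions (PFDs) `θ_j` receive
  drive `cos(H − θ_j)`.
* **Goal neurons** with associated directions `φ_j` receive `cos(G − φ_j)`.
* **Steering neurons**, split into two sub-populations, sum weighted
  compass and goal input: `I_S = W_C→S · r_C + W_G→S · r_G`.

All sigmoid-flavour neurons share the rate function
`r = 1 / (1 + e^{−a(I−b)})` with slope `a = 2` and bias `b = 0.6`
(dimensionless drive). The command is

```
command = k · ((1 − x) · Σ r_SL − x · Σ r_SR)        [deg/s]
```

with gain `k` and balance weight `x ∈ [0, 1]` (`x = 0.5` for symmetric
circuits). **Sign convention:** positive command turns the agent
counter-clockwise (heading increases), and the population in the `sl` slot
is the one whose excess activity drives positive turns. Published
descriptions of this circuit family are inconsistent about which steering
side is the positive one; we fix the convention once, package-wide, and
orient every builder's wiring so that the closed loop
`H ← H + command·dt` is negative feedback toward the goal. Concretely this
places the fly model's printed *right* PFL3 list, and the unintuitive
template's three-neuron steering population, in the positive-driving slot
(balance `1 − x₁₈` preserving the published output weighting).

The fly-flavour circuit is evaluated directly from `(H, G)`:
`S_j = f(cos(H − θ_j) + 0.3·cos(G − φ_j))` with
`f(u) = 29.23·ln(1 + e^{2.17(u−0.7)})` over the twelve printed PFL3
directions per side and twelve FC2 goal directions, and command
`l·(Σ S_ccw − Σ S_cw)` with `l = 0.00018`.

All connection weights are non-negative (the modelled connections are
excitatory); prohibited connections are explicit zeros in dense matrices.

## Positive bases and the rules

With firing rates constrained to be non-negative, a set of direction-tuned
neurons can represent every azimuth through a population-vector average
only if the PFD unit vectors form a *positive basis*: ≥ 3 distinct vectors
with the origin strictly inside their convex hull, equivalently every
adjacent inner angle strictly below 180° (angles summing to 360°). The
boundary case (a gap of exactly 180°) is classified as *not* a positive
basis; duplicate directions are collapsed before gap computation and
recorded as multiplicities.

The five construction rules are described in the README; rules 1, 4 and 5
are prescriptive (a builder can violate them), rules 2 and 3 are
descriptive annotations of what wiring implies.

## Goal-direction inference

A goal neuron's represented direction is a property of wiring, not a
label. Steering-neuron directions are normalised weighted complex sums of
the compass PFDs they sample; each goal neuron's two steering *sets*
combine the same way into unit vectors `g_L` (positive-driving side) and
`g_R`. Because the angle between them may exceed 180° (where a plain
vector sum points the wrong way, or vanishes at exactly 180°), the
procedure uses the signed angle `∠ = atan2(g_L⊥·g_R, g_L·g_R)` (with `g_L⊥`
the counter-clockwise orthogonal) and the two-branch midpoint rule

```
η = arg(g_L) + x·∠                  if ∠ > 0      (inner midpoint)
η = arg(g_L) − (180° − (1−x)·∠)     otherwise     (outer midpoint)
```

weighted by the output balance `x`. The boundary `∠ = 0` (exactly aligned
sets) falls in the second branch, giving the antipode — the balance point
on the far side of the circle. The inference is a *linear idealisation*:
it treats rates as proportional to the cosine drive. The sigmoid
introduces distortion, so on irregular circuits the true closed-loop
balance point can deviate from `η` by several degrees to a few tens of
degrees (see Limitations); on uniform circuits the procedure reduces
exactly to adjacent-PFD midpoints.

## Reference circuits

* **Uniform(N)** — PFDs `360·j/N`; `W_C→SL = 0.2·I_N`; the CW population
  samples the adjacent compass neuron one step counter-clockwise
  (`0.2·roll(I_N, 1)`); goal innervation is the identity on both sides.
  Goal directions are inferred (adjacent midpoints).
* **Fly** — the printed FC2 / PFL3 direction lists and softplus constants;
  structural one-hot matrices (each PFL3 neuron sampling the one compass
  column at its own direction, identity FC2 innervation over pairs) stand
  in for rule checking and inference.
* **Unintuitive** — four compass neurons at {350°, 10°, 90°, 200°}, three
  CCW- and two CW-driving steering neurons, three goal neurons; 18
  connection weights in [0, 2] on a fixed sparsity template plus the
  output balance in [0, 1], found by optimisation.
* **Rule breakers** — `rule1`: compass {0°, 60°, 120°} on minimal uniform
  wiring; `rule4`: minimal circuit with declared goal directions rotated
  180° from their wiring-implied values; `rule5`: minimal compass/steering
  wiring with goal neurons routed to steering pairs whose inferred
  directions {0°, 60°, 120°} sit inside one half-plane; `rule1and5`: both
  manipulations (inferred directions {30°, 60°, 90°}).

The rule-4 conformance check compares declared against inferred directions
with a default tolerance of 30°: discrete goal populations can
legitimately straddle the wiring-implied balance points (the fly's twelve
FC2 labels deviate by up to 15° from the eight distinct pair midpoints),
while the rule-4 breaker sits at 180°.

## Fitting the unintuitive circuit

The objective tabulates each candidate's steering command over a 24×24
linear (heading, goal) grid and takes the plain RMSE against the fly
circuit's surface on the same grid, both after their own output gains (the
fly's `l` already places it on the shared scale). Goal directions of every
candidate are re-inferred from its own wiring inside the objective.
Optimisation is differential evolution (scipy) with the library's default
strategy/mutation/recombination, population 15, up to 1200 generations,
and L-BFGS-B polish. Unconstrained searches land in comparably low minima
on either side of the rule-5 boundary depending on the seed, while the
construction goal is a *rule-conforming* mimic; the objective therefore
adds a soft penalty of 0.1 per normalised degree by which the candidate's
largest inferred-goal-direction gap exceeds 180° (zero for conforming
wiring, and comparable to the whole RMSE scale for strongly
non-conforming wiring). The fit runs two restarts (sub-seeds spawned
deterministically from the configured seed) and keeps the lowest-RMSE
conforming solution; if none conforms, the lowest-RMSE solution is
returned and the summary flags the failed rules. Reported RMSEs exclude
the penalty.

At these settings the residual RMSE plateaus around 0.003–0.005 against a
reference amplitude of ~0.012 — roughly the level of irregularity visible
when comparing the two models' surfaces — and appears structural: the
four-compass irregular template cannot reproduce the fly surface exactly.

## Simulation protocols

* **Integration** — explicit Euler, `dt = 0.01 s`. Commands are tuned to
  ≤ ~60°/s, so per-step heading changes stay ≤ 0.6°, far below any
  tuning-curve scale.
* **Gain tuning** — bisection on `k` until the peak turn rate during a 90°
  step response lies in [50, 60] °/s (the command is linear in `k`, so the
  initial bracket is found in one scaling step). All circuits are tuned
  this way before comparison, so tracking differences reflect wiring, not
  output scale.
* **Random walk** — goal accumulates von Mises increments (μ = 0,
  κ = 10.3; circular s.d. ≈ 18.3°), one per 1.0 s of simulated time, each
  held constant between increments. The period is chosen so the walk's
  drift rate (~18°/s) stays below the tuned turn-rate band; at a 0.1 s
  period the same increments would demand ~180°/s and no circuit —
  rule-following or not — could track.
* **Smooth turn** — linear ramp 0→360° over the first half of the run and
  back over the second (default 80 s, i.e. 9°/s), exposing headings where
  a circuit stalls.
* **Step change** — goal alternates between 0° and a step of 30/60/90°
  every 5 s.
* **Plateau detection** — heading dwell is histogrammed in 5° bins; bins
  above twice the uniform-dwell baseline (`2/n_bins`) merge into circular
  clusters, and a cluster is a plateau if its total dwell fraction reaches
  0.15. A tracker spreads dwell near the baseline and reports none; the
  rule-1 breaker under the smooth turn concentrates ~30 % of its time at
  each of two headings. Detection parameters are recorded in the report.
* **Durations** — 60 s random walks and 80 s smooth turns; these resolve
  the qualitative regimes at desk scale and are configuration, not claims.

## What the protocols do and do not emulate

The simulations probe circuit *wiring* under idealised conditions: a
perfect, drift-free compass; noiseless rates; an agent that is a pure
heading integrator. Passing them shows a wiring diagram implements the
balance-point steering principle, not that it would survive sensory noise,
compass drift, body dynamics, or neuromodulation; none of those are
modelled. Goal traces are exogenous — there is no vector memory or
path-integration state behind them.

## Numerical choices

* Canonical angle range [0, 360); wrapped differences [−180, 180); signed
  angles (−180, 180] with the exact −180 boundary mapped to +180.
* A population-vector average with resultant norm ≤ 10⁻¹² (relative) has
  no defined direction and raises, rather than guessing.
* Zero-norm direction sums in inference (a steering neuron with no compass
  input, or an empty goal set) raise structural errors.
* The circular RMSE wraps per-sample differences before squaring, so a
  constant half-turn offset scores exactly 180°.
* Closed-loop determinism: a single seeded generator drives the random
  walk; circuits themselves are deterministic.

## Known limitations

* Exact rotational invariance of the command in `H − G` holds only for
  shifts by the population spacing `360/N`; discreteness leaves a ripple
  (~0.4 % of amplitude for uniform N = 8, ~1 % for the fly, ~18 % for
  N = 3), consistent with treating even spacing as an enhancer of
  approximate invariance rather than a guarantee.
* The linear inference idealisation means wiring-implied directions of
  irregular (fitted) circuits deviate from the true closed-loop balance
  points — we measure deviations of ~10–30° on fitted unintuitive
  circuits, visible as their stepped tracking profile, whereas uniform and
  fly circuits settle within a few degrees.
* The fit is stochastic; reproducibility is per seed and scipy version.
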