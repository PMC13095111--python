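# cxsteer

Rule-based construction, validation, fitting and simulation of insect
central-complex steering circuits.

## The problem

Insects steer by comparing their current heading with a desired (goal)
heading. In the fly central complex this comparison is implemented by three
neural populations: compass neurons (EPG) whose sinusoidal activity bump
tracks heading, goal neurons (FC2) whose activity pattern encodes the
desired heading, and left/right steering neurons (PFL3) whose summed
activity difference is the turn command. Because firing rates are
non-negative, a population can encode *every* azimuth only if its preferred
firing directions (PFDs), viewed as unit vectors, form a **positive
basis** — at least three vectors with the origin strictly inside their
convex hull, equivalently all adjacent inner angles < 180°.

`cxsteer` implements a five-rule framework for building such circuits:

1. compass PFDs **C** must form a positive basis;
2. each steering neuron inherits the direction
   `s = normalise(Σ_k w_k c_k)` of the compass neurons it samples;
3. goal-neuron innervation organises steering neurons into left/right
   pairs (or weighted sets);
4. the direction a goal neuron actually represents is fixed by its wiring:
   with `g_L`, `g_R` the combined unit vectors of its two steering sets and
   `∠ = atan2(g_L⊥·g_R, g_L·g_R)` the signed angle between them,

   ```
   η = arg(g_L) + x·∠                    if ∠ > 0
   η = arg(g_L) − (180° − (1−x)·∠)       otherwise
   ```

   where `x` is the output balance weight (0.5 for symmetric circuits);
5. the inferred goal directions must themselves form a positive basis.

Rules 1, 4 and 5 are prescriptive (breakable by construction); the package
ships builders for uniform circuits (N compass/goal neurons, 2N steering
neurons on circulant wiring), the published fly model (softplus rates over
printed EPG/FC2/PFL3 direction lists), an irregular "unintuitive" template
whose 19 free weights are fitted to the fly's steering surface with
differential evolution, and four deliberate rule-breakers.

Neurons follow a sigmoid rate model `r = 1/(1+exp(−a(I−b)))` (`a = 2`,
`b = 0.6`) with cosine directional drive; the steering command is
`k·((1−x)·Σr_SL − x·Σr_SR)` with positive = counter-clockwise, and the
closed loop is the pure heading integrator `H ← H + command·dt`.

## Worked example

```python
import numpy as np
from cxsteer import (build_uniform, build_rule_breaker, rule_check,
                     tune_gain, run_closed_loop, random_walk_goal,
                     smooth_turn_goal, detect_stable_headings,
                     tracking_error)

spec = build_uniform(3)                     # minimal rule-following circuit
print(np.round(spec.goal_dirs))             # [ 60. 180. 300.]
print(rule_check(spec).passes)              # True

spec = spec.with_gain(tune_gain(spec))      # peak step rate in 50-60 deg/s
goal = random_walk_goal(duration=60.0, rng=123)
print(round(tracking_error(run_closed_loop(spec, goal)), 2))   # 13.01

breaker = build_rule_breaker("rule1")       # compass PFDs {0, 60, 120}
print(rule_check(breaker).failed_rules)     # [1]
breaker = breaker.with_gain(tune_gain(breaker))
report = detect_stable_headings(run_closed_loop(breaker, smooth_turn_goal()))
print(np.round(report.headings, 1))         # [ 60. 240.]
```

The minimal three-neuron circuit infers its goal directions at the
midpoints of adjacent compass PFDs, tracks a von Mises (κ = 10.3) random
walk to ~13° RMS error, while the rule-1 breaker — whose compass spans only
a third of the circle — stalls at the two headings (60°, 240°) aligned with
the centre of its PFD arc and its antipode.

A command-line interface mirrors the library:

```sh
steer build --type uniform --n 8 --out u8.json
steer check --circuit u8.json
steer simulate --circuit u8.json --protocol random-walk --seed 7 --out traj.csv
steer fit --seed 1 --out fitted.json
```

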