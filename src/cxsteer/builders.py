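"""Constructors for reference steering circuits and the rule checker.

Provides the uniform family (N compass, N goal, 2N steering neurons on
circulant wiring), the fly softplus circuit with its printed direction
lists, the irregular "unintuitive" template whose 19 free weights are found
by optimisation, and four deliberately rule-breaking circuits.

The five construction rules, with 1, 4 and 5 prescriptive (breakable):

1. compass PFDs must form a positive basis;
2. each steering neuron's direction is the (normalised) weighted sum of the
   compass PFDs it samples — descriptive;
3. goal-neuron innervation organises steering neurons into CCW/CW pairs or
   sets — descriptive;
4. the direction associated with a goal neuron is fixed by the wiring of
   its innervated steering sets (declared labels can contradict it);
5. the inferred goal directions must form a positive basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import (FLY_FLAVOR, ActivationParams, CircuitSpec,
                      FlyModelParams)
from .geometry import PositiveBasisReport, is_positive_basis, wrap_diff
from .inference import GoalInferenceResult, infer_goal_directions

__all__ = [
    "UNINTUITIVE_COMPASS_PFDS",
    "N_UNINTUITIVE_PARAMS",
    "RuleCheckReport",
    "build_uniform",
    "build_fly",
    "build_unintuitive",
    "build_rule_breaker",
    "rule_check",
]

#: Compass PFDs of the unintuitive template: unevenly spaced, but a
#: positive basis (largest adjacent gap is 150 deg).
UNINTUITIVE_COMPASS_PFDS = (350.0, 10.0, 90.0, 200.0)
N_UNINTUITIVE_PARAMS = 19


def _infer_and_set(spec: CircuitSpec) -> CircuitSpec:
    spec.goal_dirs = infer_goal_directions(spec).eta
    spec.provenance.setdefault("goal_dirs", "inferred")
    return spec


def build_uniform(n: int, d: float = 0.2, gain: float = 1.0,
                  activation: ActivationParams | None = None) -> CircuitSpec:
    """Uniform circuit: N compass, N goal, 2N steering neurons.

    Compass PFDs at ``360 j / N``; each CCW steering neuron samples one
    compass neuron (scale ``d``) and its CW partner samples the adjacent
    compass neuron one step counter-clockwise, so each goal neuron's
    inferred direction is the midpoint of two neighbouring PFDs.
    """
    if n < 3:
        raise ValueError("a positive basis needs at least 3 compass neurons")
    pfds = 360.0 * np.arange(n) / n
    eye = np.eye(n)
    spec = CircuitSpec(
        compass_pfds=pfds,
        w_c_sl=d * eye,
        w_c_sr=d * np.roll(eye, 1, axis=1),
        w_g_sl=eye.copy(),
        w_g_sr=eye.copy(),
        gain=gain,
        activation=activation or ActivationParams(),
        provenance={"builder": "uniform", "n": n, "d": d},
    )
    return _infer_and_set(spec)


def build_fly(gain: float = 1.0) -> CircuitSpec:
    """The fly (Drosophila) softplus circuit with the printed EPG/FC2/PFL3
    direction lists; goal directions are the declared FC2 tunings."""
    p = FlyModelParams()
    # Structural weight matrices serve rule checking / inference only; the
    # forward model evaluates the softplus lists directly.  The compass is
    # the set of distinct PFL3 directions (8 EPG-like columns at 45 deg
    # spacing); each PFL3 neuron samples the one compass column at its own
    # printed direction, and FC2 neuron j innervates PFL3 pair j on each
    # side.  The printed *right* list occupies the CCW-driving slot.
    ccw = np.mod(np.asarray(p.pfl3_r_dirs, dtype=float), 360.0)
    cw = np.mod(np.asarray(p.pfl3_l_dirs, dtype=float), 360.0)
    compass = np.unique(np.concatenate([ccw, cw]))

    def one_hot(dirs):
        w = np.zeros((dirs.size, compass.size))
        for i, d in enumerate(dirs):
            w[i, int(np.argmin(np.abs(compass - d)))] = 1.0
        return w

    return CircuitSpec(
        compass_pfds=compass,
        w_c_sl=one_hot(ccw),
        w_c_sr=one_hot(cw),
        w_g_sl=np.eye(12),
        w_g_sr=np.eye(12),
        goal_dirs=np.asarray(p.fc2_dirs, dtype=float),
        gain=gain,
        flavor=FLY_FLAVOR,
        fly=p,
        provenance={"builder": "fly", "goal_dirs": "declared"},
    )


def _unintuitive_matrices(x: np.ndarray):
    """Weight matrices of the unintuitive template from its parameter vector.

    The template has four compass neurons, a three-neuron and a two-neuron
    steering population, and three goal neurons.  The three-neuron
    population is mapped to the CCW-driving slot (its excess activity turns
    the agent counter-clockwise) and the two-neuron population to the
    CW-driving slot; ``balance = 1 - x[18]`` preserves the published output
    weighting under this orientation.
    """
    w_c_ccw = np.array([[x[4], x[5], 0, 0],
                        [0, 0, x[6], x[7]],
                        [x[8], 0, 0, x[9]]])
    w_c_cw = np.array([[x[0], 0, 0, x[1]],
                       [0, 0, x[2], x[3]]])
    w_g_ccw = np.array([[x[14], 0, 0],
                        [0, x[15], 0],
                        [0, x[16], x[17]]])
    w_g_cw = np.array([[x[10], x[11], 0],
                       [x[12], 0, x[13]]])
    return w_c_ccw, w_c_cw, w_g_ccw, w_g_cw


def build_unintuitive(x, gain: float = 1.0) -> CircuitSpec:
    """Unintuitive circuit from its 19-parameter vector.

    ``x[0:18]`` are connection weights in ``[0, 2]`` filling the template's
    sparsity pattern; ``x[18]`` in ``[0, 1]`` weights the two steering
    populations' contributions to the output.  Goal directions are inferred
    from the candidate wiring; degenerate wiring (a steering neuron or goal
    set with zero-norm direction sum) is rejected.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (N_UNINTUITIVE_PARAMS,):
        raise ValueError(f"expected {N_UNINTUITIVE_PARAMS} parameters")
    if np.any(x[:18] < 0) or np.any(x[:18] > 2) or not 0 <= x[18] <= 1:
        raise ValueError("parameters out of bounds: x[0:18] in [0,2], x[18] in [0,1]")
    w_c_ccw, w_c_cw, w_g_ccw, w_g_cw = _unintuitive_matrices(x)
    spec = CircuitSpec(
        compass_pfds=np.asarray(UNINTUITIVE_COMPASS_PFDS),
        w_c_sl=w_c_ccw, w_c_sr=w_c_cw,
        w_g_sl=w_g_ccw, w_g_sr=w_g_cw,
        gain=gain,
        balance=1.0 - x[18],
        provenance={"builder": "unintuitive", "x": [float(v) for v in x]},
    )
    return _infer_and_set(spec)


def build_rule_breaker(which: str, gain: float = 1.0) -> CircuitSpec:
    """Circuits that each break exactly the named prescriptive rule(s).

    * ``rule1`` — compass PFDs ``{0, 60, 120}`` (max gap 240 deg) on
      otherwise-minimal uniform wiring; goal directions still inferred.
    * ``rule4`` — minimal uniform circuit whose *declared* goal directions
      are displaced 180 deg from their wiring-implied values.
    * ``rule5`` — minimal compass and steering wiring, but goal neurons
      routed to steering pairs whose inferred directions ``{0, 60, 120}``
      all fall inside one half-plane.
    * ``rule1and5`` — both manipulations combined.
    """
    base = build_uniform(3, gain=gain)
    if which == "rule1":
        spec = CircuitSpec(
            compass_pfds=np.array([0.0, 60.0, 120.0]),
            w_c_sl=base.w_c_sl, w_c_sr=base.w_c_sr,
            w_g_sl=base.w_g_sl, w_g_sr=base.w_g_sr,
            gain=gain, provenance={"builder": "rule1"})
        return _infer_and_set(spec)
    if which == "rule4":
        spec = build_uniform(3, gain=gain)
        spec.goal_dirs = np.mod(spec.goal_dirs + 180.0, 360.0)
        spec.provenance = {"builder": "rule4", "goal_dirs": "declared",
                           "declared_offset_deg": 180.0}
        return spec
    if which == "rule5":
        spec = CircuitSpec(
            compass_pfds=base.compass_pfds,
            w_c_sl=base.w_c_sl, w_c_sr=base.w_c_sr,
            # goal 0 -> (L2, R0), goal 1 -> (L0, R0), goal 2 -> (L0, R1):
            # inferred directions {0, 60, 120}, all within one half-plane
            w_g_sl=np.array([[0., 1., 1.], [0., 0., 0.], [1., 0., 0.]]),
            w_g_sr=np.array([[1., 1., 0.], [0., 0., 1.], [0., 0., 0.]]),
            gain=gain, provenance={"builder": "rule5"})
        return _infer_and_set(spec)
    if which == "rule1and5":
        spec = CircuitSpec(
            compass_pfds=np.array([0.0, 60.0, 120.0]),
            w_c_sl=base.w_c_sl, w_c_sr=base.w_c_sr,
            # goal 0 -> (L0, R0), goal 1 -> (L0, R1), goal 2 -> (L1, R1):
            # inferred directions {30, 60, 90}
            w_g_sl=np.array([[1., 1., 0.], [0., 0., 1.], [0., 0., 0.]]),
            w_g_sr=np.array([[1., 0., 0.], [0., 1., 1.], [0., 0., 0.]]),
            gain=gain, provenance={"builder": "rule1and5"})
        return _infer_and_set(spec)
    raise ValueError(f"unknown rule breaker {which!r}; "
                     "choose rule1, rule4, rule5 or rule1and5")


@dataclass(frozen=True)
class RuleCheckReport:
    """Prescriptive-rule verdicts plus descriptive annotations.

    Rules 1 and 5 are positive-basis tests (pass/fail); rule 4 compares the
    spec's declared goal directions against the wiring-inferred ones within
    ``rule4_tol`` degrees.  Rules 2 and 3 are purely descriptive: inherited
    steering-neuron directions and the per-goal innervation sets.
    """

    rule1: PositiveBasisReport
    rule5: PositiveBasisReport
    rule2_directions: tuple
    rule3_pairs: list
    rule4_deviation: np.ndarray
    rule4_tol: float
    inference: GoalInferenceResult

    @property
    def rule4_pass(self) -> bool:
        return bool(np.max(np.abs(self.rule4_deviation)) <= self.rule4_tol)

    @property
    def failed_rules(self) -> list:
        failed = []
        if not self.rule1.is_positive_basis:
            failed.append(1)
        if not self.rule4_pass:
            failed.append(4)
        if not self.rule5.is_positive_basis:
            failed.append(5)
        return failed

    @property
    def passes(self) -> bool:
        return not self.failed_rules


def rule_check(spec: CircuitSpec, rule4_tol: float = 30.0) -> RuleCheckReport:
    """Evaluate the prescriptive rules on a circuit.

    ``rule4_tol`` defaults to 30 deg: declared directions are expected to
    sit near the wiring-implied balance point, but discrete goal
    populations can legitimately straddle it (the fly's 12 FC2 labels
    deviate by up to 15 deg from their 8 distinct steering-pair midpoints).
    """
    inf = infer_goal_directions(spec)
    pairs = [(list(np.flatnonzero(spec.w_g_sl[:, j] > 0)),
              list(np.flatnonzero(spec.w_g_sr[:, j] > 0)))
             for j in range(spec.n_goal)]
    declared = spec.goal_dirs if spec.goal_dirs is not None else inf.eta
    deviation = wrap_diff(np.asarray(declared) - inf.eta)
    return RuleCheckReport(
        rule1=is_positive_basis(spec.compass_pfds),
        rule5=is_positive_basis(inf.eta),
        rule2_directions=(inf.sl_dirs, inf.sr_dirs),
        rule3_pairs=pairs,
        rule4_deviation=np.atleast_1d(deviation),
        rule4_tol=rule4_tol,
        inference=inf,
    )
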