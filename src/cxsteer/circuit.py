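"""Firing-rate neuron model and forward evaluation of steering circuits.

A steering circuit maps a heading ``H`` and goal ``G`` (both in degrees) to
a scalar turn command through three populations: compass neurons tuned to
``H`` by a phase-shifted cosine, goal neurons tuned to ``G`` likewise, and
two steering populations that sum weighted compass and goal input.  The
command is the weighted difference of the two steering populations' summed
rates.

Sign convention used throughout the package: **positive command turns the
agent counter-clockwise** (heading increases), and the population stored in
the ``sl`` slot of a :class:`CircuitSpec` is the one whose excess activity
drives positive turns.  Builders orient their wiring so that the closed loop
``H += command * dt`` is negative feedback toward the goal.

Two model flavours exist: the sigmoid rate model used for uniform /
rule-breaking / unintuitive circuits, and the softplus fly model (EPG /
FC2 / PFL3 populations with printed direction lists) which is evaluated
directly from ``(H, G)`` without an explicit compass rate layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import wrap_angle

__all__ = [
    "ActivationParams",
    "FlyModelParams",
    "CircuitSpec",
    "sigmoid_rate",
    "softplus_rate",
    "compass_rates",
    "goal_rates",
    "steering_command",
    "fly_steering",
    "SIGMOID_FLAVOR",
    "FLY_FLAVOR",
]

SIGMOID_FLAVOR = "sigmoid-rate"
FLY_FLAVOR = "fly-softplus"

# Printed direction lists of the fly (Drosophila) steering model: 12 FC2 goal
# neurons, and 12 PFL3 steering neurons per side.  The PFL3 lists are kept in
# their published left/right labelling; note that under this package's
# CCW-positive convention the published *right* population is the one that
# drives positive (heading-increasing) turns.
FC2_DIRS = (-15.0, -45.0, -75.0, -105.0, -135.0, -165.0,
            165.0, 135.0, 105.0, 75.0, 45.0, 15.0)
PFL3_L_DIRS = (67.5, 22.5, -22.5, -22.5, -67.5, -112.5,
               -112.5, -157.5, 157.5, 157.5, 112.5, 67.5)
PFL3_R_DIRS = (-67.5, -112.5, -157.5, -157.5, 157.5, 112.5,
               112.5, 67.5, 22.5, 22.5, -22.5, -67.5)


@dataclass(frozen=True)
class ActivationParams:
    """Sigmoid activation ``r = 1 / (1 + exp(-a (I - b)))``."""

    slope: float = 2.0
    bias: float = 0.6

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError("activation slope must be positive")


@dataclass(frozen=True)
class FlyModelParams:
    """Constants of the fly softplus steering model.

    ``f(x) = scale * log(1 + exp(slope * (x - shift)))`` applied to
    ``cos(H - theta_j) + goal_input_weight * cos(G - phi_j)``; the command is
    ``output_gain * (sum S_ccw - sum S_cw)``.
    """

    goal_input_weight: float = 0.3
    softplus_scale: float = 29.23
    softplus_slope: float = 2.17
    softplus_shift: float = 0.7
    output_gain: float = 0.00018
    fc2_dirs: tuple = FC2_DIRS
    pfl3_l_dirs: tuple = PFL3_L_DIRS
    pfl3_r_dirs: tuple = PFL3_R_DIRS

    def __post_init__(self):
        for name in ("fc2_dirs", "pfl3_l_dirs", "pfl3_r_dirs"):
            if len(getattr(self, name)) != 12:
                raise ValueError(f"{name} must list 12 directions")


@dataclass(eq=False)
class CircuitSpec:
    """Full parameterisation of one steering circuit.

    Weight matrices are dense, non-negative, with explicit zeros for
    prohibited connections; rows index postsynaptic steering neurons and
    columns presynaptic compass / goal neurons.  ``balance`` is the weight
    ``x`` in ``command = gain * ((1 - x) * sum r_sl - x * sum r_sr)``; at
    0.5 this reproduces the symmetric difference up to the gain.
    """

    compass_pfds: np.ndarray
    w_c_sl: np.ndarray
    w_c_sr: np.ndarray
    w_g_sl: np.ndarray
    w_g_sr: np.ndarray
    goal_dirs: np.ndarray | None = None
    gain: float = 1.0
    balance: float = 0.5
    activation: ActivationParams = field(default_factory=ActivationParams)
    flavor: str = SIGMOID_FLAVOR
    fly: FlyModelParams | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.compass_pfds = wrap_angle(np.atleast_1d(
            np.asarray(self.compass_pfds, dtype=float)))
        if self.goal_dirs is not None:
            self.goal_dirs = wrap_angle(np.atleast_1d(
                np.asarray(self.goal_dirs, dtype=float)))
        for name in ("w_c_sl", "w_c_sr", "w_g_sl", "w_g_sr"):
            setattr(self, name, np.atleast_2d(
                np.asarray(getattr(self, name), dtype=float)))
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_compass(self) -> int:
        return self.compass_pfds.size

    @property
    def n_goal(self) -> int:
        return self.w_g_sl.shape[1]

    @property
    def n_sl(self) -> int:
        return self.w_c_sl.shape[0]

    @property
    def n_sr(self) -> int:
        return self.w_c_sr.shape[0]

    @property
    def n_steering(self) -> int:
        return self.n_sl + self.n_sr

    def validate(self) -> None:
        """Check shape consistency and the excitatory-weight contract."""
        if self.w_c_sl.shape != (self.n_sl, self.n_compass):
            raise ValueError("w_c_sl shape inconsistent with populations")
        if self.w_c_sr.shape != (self.n_sr, self.n_compass):
            raise ValueError("w_c_sr shape inconsistent with populations")
        if self.w_g_sl.shape != (self.n_sl, self.n_goal):
            raise ValueError("w_g_sl shape inconsistent with populations")
        if self.w_g_sr.shape != (self.n_sr, self.n_goal):
            raise ValueError("w_g_sr shape inconsistent with populations")
        for name in ("w_c_sl", "w_c_sr", "w_g_sl", "w_g_sr"):
            w = getattr(self, name)
            if not np.all(np.isfinite(w)):
                raise ValueError(f"{name} contains non-finite weights")
            if np.any(w < 0):
                raise ValueError(f"{name} contains negative weights; "
                                 "connections are excitatory")
        if self.goal_dirs is not None and self.goal_dirs.size != self.n_goal:
            raise ValueError("goal_dirs length inconsistent with w_g_* width")
        if not 0.0 <= self.balance <= 1.0:
            raise ValueError("balance must lie in [0, 1]")
        if self.flavor not in (SIGMOID_FLAVOR, FLY_FLAVOR):
            raise ValueError(f"unknown model flavor {self.flavor!r}")
        if self.flavor == FLY_FLAVOR and self.fly is None:
            raise ValueError("fly flavor requires FlyModelParams")

    def with_gain(self, k: float) -> "CircuitSpec":
        """Copy of this spec with the output gain replaced."""
        return replace(self, gain=float(k))


# -- activation functions --------------------------------------------------

def sigmoid_rate(I, p: ActivationParams = ActivationParams()):
    """Sigmoid firing rate ``1 / (1 + exp(-a (I - b)))``, in ``(0, 1)``."""
    I = np.asarray(I, dtype=float)
    out = 1.0 / (1.0 + np.exp(-p.slope * (I - p.bias)))
    return float(out) if out.ndim == 0 else out


def softplus_rate(x, p: FlyModelParams = FlyModelParams()):
    """Fly softplus rate ``scale * log(1 + exp(slope * (x - shift)))``."""
    x = np.asarray(x, dtype=float)
    out = p.softplus_scale * np.log1p(np.exp(p.softplus_slope * (x - p.softplus_shift)))
    return float(out) if out.ndim == 0 else out


# -- population responses --------------------------------------------------

def compass_rates(H, spec: CircuitSpec):
    """Compass population rates for heading(s) ``H`` (deg).

    ``rate_j = sigmoid(cos(H - theta_j))``: every heading yields strictly
    positive activity in every compass neuron (broad cosine tuning).
    """
    a = np.radians(np.asarray(H, dtype=float))
    I = np.cos(a[..., None] - np.radians(spec.compass_pfds))
    return sigmoid_rate(I, spec.activation)


def goal_rates(G, spec: CircuitSpec):
    """Goal population rates ``sigmoid(cos(G - phi_j))`` for goal(s) ``G``."""
    if spec.goal_dirs is None:
        raise ValueError("spec has no goal directions; run goal inference")
    a = np.radians(np.asarray(G, dtype=float))
    I = np.cos(a[..., None] - np.radians(spec.goal_dirs))
    return sigmoid_rate(I, spec.activation)


def fly_steering(H, G, p: FlyModelParams, gain: float = 1.0):
    """Steering command of the fly softplus model (deg/s scale set by gain).

    Per-neuron responses follow ``f(cos(H - theta_j) + w cos(G - phi_j))``
    over the printed PFL3 lists.  Under the package's CCW-positive
    convention the printed *right* list drives positive turns, so the
    command is ``gain * l * (sum S_R_printed - sum S_L_printed)``; this
    makes ``H += command * dt`` negative feedback toward ``G``.
    """
    H = np.radians(np.asarray(H, dtype=float))
    G = np.radians(np.asarray(G, dtype=float))
    H, G = np.broadcast_arrays(H, G)
    fc2 = np.radians(np.asarray(p.fc2_dirs))
    goal_term = p.goal_input_weight * np.cos(G[..., None] - fc2)
    s_ccw = softplus_rate(
        np.cos(H[..., None] - np.radians(np.asarray(p.pfl3_r_dirs))) + goal_term, p)
    s_cw = softplus_rate(
        np.cos(H[..., None] - np.radians(np.asarray(p.pfl3_l_dirs))) + goal_term, p)
    out = gain * p.output_gain * (np.sum(s_ccw, axis=-1) - np.sum(s_cw, axis=-1))
    return float(out) if out.ndim == 0 else out


def steering_command(H, G, spec: CircuitSpec, return_rates: bool = False):
    """Scalar steering command (deg/s) for heading ``H`` and goal ``G``.

    Broadcasts over array-valued ``H`` / ``G``.  With ``return_rates=True``
    (scalar inputs only) also returns the four population rate vectors.
    """
    if spec.flavor == FLY_FLAVOR:
        cmd = fly_steering(H, G, spec.fly, gain=spec.gain)
        if return_rates:
            raise NotImplementedError("rate introspection is for the sigmoid flavor")
        return cmd
    H, G = np.broadcast_arrays(np.asarray(H, dtype=float),
                               np.asarray(G, dtype=float))
    r_c = compass_rates(H, spec)
    r_g = goal_rates(G, spec)
    i_sl = r_c @ spec.w_c_sl.T + r_g @ spec.w_g_sl.T
    i_sr = r_c @ spec.w_c_sr.T + r_g @ spec.w_g_sr.T
    r_sl = sigmoid_rate(i_sl, spec.activation)
    r_sr = sigmoid_rate(i_sr, spec.activation)
    x = spec.balance
    cmd = spec.gain * ((1.0 - x) * np.sum(r_sl, axis=-1) - x * np.sum(r_sr, axis=-1))
    cmd = float(cmd) if np.ndim(cmd) == 0 else cmd
    if return_rates:
        return cmd, {"compass": r_c, "goal": r_g, "sl": r_sl, "sr": r_sr}
    return cmd
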