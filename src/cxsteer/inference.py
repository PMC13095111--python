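"""Infer goal-neuron associated directions from circuit wiring.

A goal neuron has no intrinsic direction label: the direction the circuit
actually steers to when that neuron is active is fixed entirely by wiring.
Each steering neuron inherits a direction from the compass neurons it
samples (normalised weighted vector sum).  Each goal neuron innervates a
set of CCW-driving and a set of CW-driving steering neurons; combining each
set (again a normalised weighted sum) gives two unit vectors ``g_ccw`` and
``g_cw``, and the associated direction lies between them, weighted by the
circuit's output ``balance``.

Because the angle between the two set directions can exceed 180 deg, a
plain vector sum can point the wrong way (or vanish at exactly 180), so the
procedure works with the signed angle directly: with ``ang`` the signed
angle from ``g_ccw`` to ``g_cw`` and ``x`` the balance,

    eta = arg(g_ccw) + x * ang                     if ang > 0
    eta = arg(g_ccw) - (180 - (1 - x) * ang)       otherwise

i.e. the inner-angle midpoint when the CW set lies counter-clockwise of the
CCW set, and the outer-angle midpoint otherwise (at ``x = 0.5``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitSpec
from .geometry import unit_vectors, wrap_angle

__all__ = [
    "DegenerateDirectionError",
    "RuleViolationError",
    "GoalInferenceResult",
    "steering_directions",
    "infer_goal_directions",
]


class DegenerateDirectionError(ValueError):
    """A weighted direction sum has zero norm and no defined direction."""


class RuleViolationError(ValueError):
    """Circuit wiring violates a structural requirement of the framework."""


@dataclass(frozen=True)
class GoalInferenceResult:
    """Per-goal-neuron inference intermediates and final directions.

    Angles in degrees; ``sl``/``gl`` refer to the CCW-driving (positive)
    steering side under the package sign convention, ``sr``/``gr`` to the
    CW-driving side.  ``eta`` is the inferred associated direction and
    ``unit_dirs`` its complex unit-vector form ``e^{i eta}``.
    """

    sl_dirs: np.ndarray
    sr_dirs: np.ndarray
    gl_dirs: np.ndarray
    gr_dirs: np.ndarray
    u: np.ndarray
    v: np.ndarray
    signed_angles: np.ndarray
    eta: np.ndarray

    @property
    def unit_dirs(self) -> np.ndarray:
        return unit_vectors(self.eta)


def _normalised_dirs(weights: np.ndarray, source_dirs, what: str,
                     tol: float = 1e-12) -> np.ndarray:
    """Angles (deg) of normalised weighted unit-vector sums, one per row."""
    z = weights @ unit_vectors(source_dirs)
    norms = np.abs(z)
    if np.any(norms <= tol):
        bad = int(np.argmin(norms))
        raise DegenerateDirectionError(
            f"{what} {bad} has a zero-norm direction sum")
    return wrap_angle(np.degrees(np.angle(z)))


def steering_directions(spec: CircuitSpec):
    """Directions (deg) inherited by each steering neuron from the compass.

    Weighted complex sums of the sampled compass PFDs, normalised to unit
    length; a steering neuron with no compass input (zero-norm sum) is a
    structural defect and raises :class:`DegenerateDirectionError`.
    Returns ``(sl_dirs, sr_dirs)`` for the CCW- and CW-driving populations.
    """
    sl = _normalised_dirs(spec.w_c_sl, spec.compass_pfds, "ccw steering neuron")
    sr = _normalised_dirs(spec.w_c_sr, spec.compass_pfds, "cw steering neuron")
    return sl, sr


def infer_goal_directions(spec: CircuitSpec) -> GoalInferenceResult:
    """Run the general wiring-based goal-direction inference.

    Requires every goal neuron to innervate at least one steering neuron on
    each side (the pairing rule); otherwise no balance point exists and a
    :class:`RuleViolationError` is raised.  For the fly flavour the
    structural matrices stored on the spec (one compass sample per PFL3
    neuron, identity FC2 innervation) stand in for the forward model.
    """
    compass = spec.compass_pfds
    w_c_sl, w_c_sr = spec.w_c_sl, spec.w_c_sr
    w_g_sl, w_g_sr = spec.w_g_sl, spec.w_g_sr
    sl_ang = _normalised_dirs(w_c_sl, compass, "ccw steering neuron")
    sr_ang = _normalised_dirs(w_c_sr, compass, "cw steering neuron")

    for j in range(w_g_sl.shape[1]):
        if not np.any(w_g_sl[:, j] > 0) or not np.any(w_g_sr[:, j] > 0):
            raise RuleViolationError(
                f"goal neuron {j} must innervate both steering sides")

    # combined per-goal set directions (weighted sums of unit vectors, then
    # normalised): columns of w_g_* give each goal neuron's innervation
    gl_ang = _normalised_dirs(w_g_sl.T, sl_ang, "goal neuron ccw set")
    gr_ang = _normalised_dirs(w_g_sr.T, sr_ang, "goal neuron cw set")

    gl = unit_vectors(gl_ang)
    gr = unit_vectors(gr_ang)
    u = gl.real * gr.real + gl.imag * gr.imag          # gl . gr
    v = gl.real * gr.imag - gl.imag * gr.real          # gl_perp(ccw) . gr
    ang = np.degrees(np.arctan2(v, u))                 # in (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)

    x = spec.balance
    eta = np.where(ang > 0,
                   gl_ang + x * ang,
                   gl_ang - (180.0 - (1.0 - x) * ang))
    return GoalInferenceResult(
        sl_dirs=sl_ang, sr_dirs=sr_ang,
        gl_dirs=gl_ang, gr_dirs=gr_ang,
        u=u, v=v, signed_angles=ang, eta=wrap_angle(eta))
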