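"""Angular arithmetic and positive-basis geometry.

Directionally tuned neurons are treated as unit vectors in the plane, with
the angle of each vector giving the neuron's preferred firing (or associated)
direction.  A population can encode *every* azimuth through non-negative
firing rates only if those vectors form a *positive basis*: at least three
vectors with the origin strictly inside their convex hull, or equivalently
with every inner angle between circularly adjacent vectors strictly below
180 deg.  All public interfaces use degrees; canonical angles live in
``[0, 360)`` and wrapped differences in ``[-180, 180)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UndefinedDirectionError",
    "PositiveBasisReport",
    "wrap_angle",
    "wrap_diff",
    "unit_vectors",
    "is_positive_basis",
    "pva_decode",
    "signed_angle",
    "angular_rmse",
]


class UndefinedDirectionError(ValueError):
    """Raised when a direction is requested for a zero-length resultant."""


def wrap_angle(a):
    """Wrap angle(s) in degrees onto the canonical range ``[0, 360)``.

    Accepts scalars or arrays; rejects non-finite input.
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    out = np.mod(a, 360.0)
    # mod can return 360.0 for tiny negative inputs under floating point
    out = np.where(out >= 360.0, out - 360.0, out)
    return float(out) if out.ndim == 0 else out


def wrap_diff(a):
    """Wrap angular difference(s) in degrees onto ``[-180, 180)``."""
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    out = np.mod(a + 180.0, 360.0) - 180.0
    out = np.where(out >= 180.0, out - 360.0, out)
    return float(out) if out.ndim == 0 else out


def unit_vectors(angles_deg) -> np.ndarray:
    """Unit vectors ``e^{i*theta}`` (complex) for angles in degrees."""
    return np.exp(1j * np.radians(np.asarray(angles_deg, dtype=float)))


@dataclass(frozen=True)
class PositiveBasisReport:
    """Outcome of the positive-basis test for a set of directions.

    ``adjacent_gaps`` are the inner angles (deg) between circularly adjacent
    *distinct* directions, in sorted-direction order; they sum to 360 for any
    set with >= 2 distinct directions.  The set is a positive basis iff the
    largest gap is strictly below 180 deg.
    """

    is_positive_basis: bool
    adjacent_gaps: np.ndarray
    max_gap: float
    gap_sum: float
    n_directions: int
    n_distinct: int
    multiplicity: dict = field(default_factory=dict)


def is_positive_basis(dirs, tol: float = 1e-9) -> PositiveBasisReport:
    """Test whether directions (degrees) form a positive basis of the plane.

    Equivalent to asking whether the origin lies strictly inside the convex
    hull of the corresponding unit vectors.  Duplicate directions (within
    ``tol`` degrees after wrapping) are collapsed before gap computation;
    the report records their multiplicity.
    """
    angles = np.atleast_1d(np.asarray(dirs, dtype=float))
    if angles.size < 2:
        raise ValueError("need at least 2 directions")
    wrapped = wrap_angle(angles)
    order = np.argsort(wrapped)
    srt = wrapped[order]
    # collapse duplicates (also across the 0/360 seam)
    keep = np.ones(srt.size, dtype=bool)
    mult: dict[float, int] = {}
    last = None
    for i, a in enumerate(srt):
        if last is not None and (a - last <= tol):
            keep[i] = False
            mult[last] = mult.get(last, 1) + 1
        else:
            last = a
            mult[a] = 1
    distinct = srt[keep]
    if distinct.size > 1 and (360.0 - distinct[-1] + distinct[0]) <= tol:
        # first and last wrap onto each other
        mult[distinct[0]] = mult.get(distinct[0], 1) + mult.pop(distinct[-1])
        distinct = distinct[:-1]
    if distinct.size == 1:
        gaps = np.array([360.0])
        return PositiveBasisReport(False, gaps, 360.0, 360.0,
                                   angles.size, 1, mult)
    gaps = np.diff(np.append(distinct, distinct[0] + 360.0))
    return PositiveBasisReport(
        is_positive_basis=bool(np.max(gaps) < 180.0),
        adjacent_gaps=gaps,
        max_gap=float(np.max(gaps)),
        gap_sum=float(np.sum(gaps)),
        n_directions=int(angles.size),
        n_distinct=int(distinct.size),
        multiplicity=mult,
    )


def pva_decode(rates, dirs, tol: float = 1e-12) -> float:
    """Population-vector-average decode of an angle, in degrees.

    Returns the complex argument of ``sum_j rates_j * e^{i theta_j}``.  A
    resultant with (relative) norm below ``tol`` has no defined direction and
    raises :class:`UndefinedDirectionError`.
    """
    rates = np.asarray(rates, dtype=float)
    dirs = np.asarray(dirs, dtype=float)
    if rates.shape != dirs.shape:
        raise ValueError("rates and directions must have the same length")
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if not np.any(rates > 0):
        raise UndefinedDirectionError("all-zero rate vector")
    z = np.sum(rates * unit_vectors(dirs))
    if abs(z) <= tol * max(1.0, float(np.sum(rates))):
        raise UndefinedDirectionError("resultant vector has zero norm")
    return wrap_angle(np.degrees(np.angle(z)))


def signed_angle(u_dir: float, v_dir: float) -> float:
    """Signed angle (deg) from direction ``u_dir`` to ``v_dir``, in (-180, 180].

    Positive means ``v`` lies counter-clockwise of ``u``.  Identical to
    ``atan2(u_perp . v, u . v)`` with ``u_perp`` the counter-clockwise
    orthogonal of the unit vector at ``u_dir``.
    """
    d = np.mod(np.asarray(v_dir, dtype=float) - np.asarray(u_dir, dtype=float), 360.0)
    if not np.all(np.isfinite(d)):
        raise ValueError("angles must be finite")
    d = np.where(d > 180.0, d - 360.0, d)
    return float(d) if d.ndim == 0 else d


def angular_rmse(trace_a, trace_b) -> float:
    """Root-mean-square angular error (deg) between two angle traces.

    Per-sample differences are wrapped to ``[-180, 180)`` before squaring, so
    the metric respects the circular topology (a constant 180 deg offset
    yields exactly 180).
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("traces must be non-empty and of equal length")
    d = wrap_diff(a - b)
    return float(np.sqrt(np.mean(np.square(d))))
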