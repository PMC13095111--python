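"""Circuit-spec serialisation and trajectory / surface export.

Circuit specs round-trip losslessly through a versioned JSON document
(human-diffable, schema-checkable); trajectories and surfaces export as
CSV.  All angles in files are degrees; weight matrices are dense and
row-major with rows indexing postsynaptic steering neurons.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import ActivationParams, CircuitSpec, FlyModelParams
from .fitting import SteeringSurface
from .simulation import Trajectory

__all__ = [
    "SCHEMA_VERSION",
    "SpecValidationError",
    "write_spec",
    "read_spec",
    "write_trajectory",
    "read_trajectory",
    "write_surface",
    "read_surface",
]

SCHEMA_VERSION = 1


class SpecValidationError(ValueError):
    """A circuit-spec file violates the schema; the message names the field."""


def _spec_document(spec: CircuitSpec) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "model_flavor": spec.flavor,
        "compass_pfds_deg": spec.compass_pfds.tolist(),
        "goal_dirs_deg": None if spec.goal_dirs is None else spec.goal_dirs.tolist(),
        "weights": {
            "w_c_sl": spec.w_c_sl.tolist(),
            "w_c_sr": spec.w_c_sr.tolist(),
            "w_g_sl": spec.w_g_sl.tolist(),
            "w_g_sr": spec.w_g_sr.tolist(),
        },
        "gain": spec.gain,
        "balance": spec.balance,
        "activation": {"slope": spec.activation.slope,
                       "bias": spec.activation.bias},
        "fly": None,
        "provenance": spec.provenance,
    }
    if spec.fly is not None:
        p = spec.fly
        doc["fly"] = {
            "goal_input_weight": p.goal_input_weight,
            "softplus_scale": p.softplus_scale,
            "softplus_slope": p.softplus_slope,
            "softplus_shift": p.softplus_shift,
            "output_gain": p.output_gain,
            "fc2_dirs_deg": list(p.fc2_dirs),
            "pfl3_l_dirs_deg": list(p.pfl3_l_dirs),
            "pfl3_r_dirs_deg": list(p.pfl3_r_dirs),
        }
    return doc


def write_spec(spec: CircuitSpec, path) -> None:
    """Serialise a circuit spec to JSON (lossless, including sparsity zeros)."""
    Path(path).write_text(json.dumps(_spec_document(spec), indent=1) + "\n")


def _require(doc: dict, key: str, where: str = "spec"):
    if key not in doc:
        raise SpecValidationError(f"missing field {where}.{key}")
    return doc[key]


def read_spec(path) -> CircuitSpec:
    """Read and validate a circuit-spec JSON file.

    Unknown schema versions are rejected.  Negative weights violate the
    excitatory-connection contract and are reported with their field path.
    A file without goal directions gets them recomputed from its wiring and
    flagged ``"inferred"`` in provenance.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SpecValidationError(f"not valid JSON: {e}") from e
    version = _require(doc, "schema_version")
    if version != SCHEMA_VERSION:
        raise SpecValidationError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    weights = _require(doc, "weights")
    mats = {}
    for name in ("w_c_sl", "w_c_sr", "w_g_sl", "w_g_sr"):
        w = np.asarray(_require(weights, name, "spec.weights"), dtype=float)
        if np.any(w < 0):
            raise SpecValidationError(
                f"spec.weights.{name}: negative weight (connections are excitatory)")
        mats[name] = w
    act = doc.get("activation", {})
    fly = None
    if doc.get("fly") is not None:
        f = doc["fly"]
        fly = FlyModelParams(
            goal_input_weight=f["goal_input_weight"],
            softplus_scale=f["softplus_scale"],
            softplus_slope=f["softplus_slope"],
            softplus_shift=f["softplus_shift"],
            output_gain=f["output_gain"],
            fc2_dirs=tuple(f["fc2_dirs_deg"]),
            pfl3_l_dirs=tuple(f["pfl3_l_dirs_deg"]),
            pfl3_r_dirs=tuple(f["pfl3_r_dirs_deg"]),
        )
    goal_dirs = doc.get("goal_dirs_deg")
    try:
        spec = CircuitSpec(
            compass_pfds=np.asarray(_require(doc, "compass_pfds_deg"), dtype=float),
            goal_dirs=None if goal_dirs is None else np.asarray(goal_dirs, dtype=float),
            gain=float(doc.get("gain", 1.0)),
            balance=float(doc.get("balance", 0.5)),
            activation=ActivationParams(slope=act.get("slope", 2.0),
                                        bias=act.get("bias", 0.6)),
            flavor=_require(doc, "model_flavor"),
            fly=fly,
            provenance=dict(doc.get("provenance", {})),
            **mats,
        )
    except ValueError as e:
        raise SpecValidationError(str(e)) from e
    if spec.goal_dirs is None:
        from .inference import infer_goal_directions
        spec.goal_dirs = infer_goal_directions(spec).eta
        spec.provenance["goal_dirs"] = "inferred"
    return spec


def write_trajectory(traj: Trajectory, path) -> None:
    """Trajectory CSV with columns t, goal_deg, heading_deg, command_deg_per_s."""
    traj.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(t=df["t"].to_numpy(),
                      goal=df["goal_deg"].to_numpy(),
                      heading=df["heading_deg"].to_numpy(),
                      command=df["command_deg_per_s"].to_numpy())


def write_surface(surface: SteeringSurface, path) -> None:
    """Surface CSV: header row of goal angles, index column of headings."""
    df = pd.DataFrame(surface.command, index=surface.heading,
                      columns=surface.goal)
    df.index.name = "heading_deg"
    df.to_csv(path, float_format="%.10g")


def read_surface(path) -> SteeringSurface:
    df = pd.read_csv(path, index_col=0)
    return SteeringSurface(heading=df.index.to_numpy(dtype=float),
                           goal=df.columns.to_numpy(dtype=float),
                           command=df.to_numpy(dtype=float))
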