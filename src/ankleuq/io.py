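"""Model file I/O and CSV report writers.

The joint model is stored as a YAML document with explicit units and a
fixed schema; reading is strict — missing fields, unknown keys, a wrong
ligament set or out-of-range values are rejected with an error naming
the offending field, so that a 42-parameter file can never silently
masquerade as a 43-parameter model.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    LIGAMENT_NAMES,
    ContactPairSpec,
    InvalidParameterError,
    JointModel,
    LigamentSpec,
    Pose2D,
    SweepResult,
)
from .rcga import GAResult

__all__ = [
    "SchemaError",
    "read_model",
    "write_model",
    "sweep_to_frame",
    "write_sweep_csv",
    "read_sweep_csv",
    "write_trace_csv",
    "write_oat_csv",
]

_SCHEMA = "ankleuq-joint-model/1"
_UNITS = {"length": "mm", "force": "N", "pressure": "MPa", "angle": "rad"}

_LIGAMENT_KEYS = {
    "attach_moving", "attach_fixed", "stiffness_coeff", "shape_coeff",
}
_CONTACT_KEYS = {
    "center_moving", "center_fixed", "radius_inner", "clearance",
    "youngs_modulus", "poissons_ratio",
}
_TOP_KEYS = {"schema", "units", "reference_pose", "ligaments", "contact"}


class SchemaError(ValueError):
    """Model file does not match the expected schema."""


def _point(raw, where: str) -> tuple[float, float]:
    if not isinstance(raw, (list, tuple)) or len(raw) != 2:
        raise SchemaError(f"{where}: expected a 2-element [x, y] point")
    return float(raw[0]), float(raw[1])


def _check_keys(raw: dict, allowed: set[str], where: str) -> None:
    extra = set(raw) - allowed
    if extra:
        raise SchemaError(f"{where}: unknown key(s) {sorted(extra)}")
    missing = allowed - set(raw)
    if missing:
        raise SchemaError(f"{where}: missing key(s) {sorted(missing)}")


def read_model(path: str | Path) -> JointModel:
    """Read a joint model from a YAML file, validating the schema."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("model file must contain a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "model")
    if raw["schema"] != _SCHEMA:
        raise SchemaError(
            f"schema: expected {_SCHEMA!r}, got {raw['schema']!r}"
        )
    if raw["units"] != _UNITS:
        raise SchemaError(f"units: expected {_UNITS}, got {raw['units']}")

    pose_raw = raw["reference_pose"]
    _check_keys(pose_raw, {"tx", "ty", "theta"}, "reference_pose")
    pose = Pose2D(
        float(pose_raw["tx"]), float(pose_raw["ty"]), float(pose_raw["theta"])
    )

    ligs_raw = raw["ligaments"]
    if set(ligs_raw) != set(LIGAMENT_NAMES):
        raise SchemaError(
            f"ligaments: expected exactly {sorted(LIGAMENT_NAMES)}, "
            f"got {sorted(ligs_raw)}"
        )
    ligaments = []
    for name in LIGAMENT_NAMES:
        entry = ligs_raw[name]
        _check_keys(entry, _LIGAMENT_KEYS, f"ligaments.{name}")
        try:
            ligaments.append(
                LigamentSpec(
                    name=name,
                    attach_moving=_point(
                        entry["attach_moving"], f"ligaments.{name}.attach_moving"
                    ),
                    attach_fixed=_point(
                        entry["attach_fixed"], f"ligaments.{name}.attach_fixed"
                    ),
                    stiffness_coeff=float(entry["stiffness_coeff"]),
                    shape_coeff=float(entry["shape_coeff"]),
                )
            )
        except InvalidParameterError as exc:
            raise SchemaError(f"ligaments.{name}: {exc}") from exc

    c_raw = raw["contact"]
    _check_keys(c_raw, _CONTACT_KEYS, "contact")
    try:
        contact = ContactPairSpec(
            center_moving=_point(c_raw["center_moving"], "contact.center_moving"),
            center_fixed=_point(c_raw["center_fixed"], "contact.center_fixed"),
            radius_inner=float(c_raw["radius_inner"]),
            clearance=float(c_raw["clearance"]),
            youngs_modulus=float(c_raw["youngs_modulus"]),
            poissons_ratio=float(c_raw["poissons_ratio"]),
        )
    except InvalidParameterError as exc:
        raise SchemaError(f"contact: {exc}") from exc
    return JointModel(tuple(ligaments), contact, pose)


def write_model(model: JointModel, path: str | Path) -> None:
    """Write a joint model to YAML (lossless round-trip with read_model)."""
    doc = {
        "schema": _SCHEMA,
        "units": dict(_UNITS),
        "reference_pose": {
            "tx": float(model.reference_pose.tx),
            "ty": float(model.reference_pose.ty),
            "theta": float(model.reference_pose.theta),
        },
        "ligaments": {
            lig.name: {
                "attach_moving": [float(v) for v in lig.attach_moving],
                "attach_fixed": [float(v) for v in lig.attach_fixed],
                "stiffness_coeff": float(lig.stiffness_coeff),
                "shape_coeff": float(lig.shape_coeff),
            }
            for lig in model.ligaments
        },
        "contact": {
            "center_moving": [float(v) for v in model.contact.center_moving],
            "center_fixed": [float(v) for v in model.contact.center_fixed],
            "radius_inner": float(model.contact.radius_inner),
            "clearance": float(model.contact.clearance),
            "youngs_modulus": float(model.contact.youngs_modulus),
            "poissons_ratio": float(model.contact.poissons_ratio),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


_SWEEP_COLUMNS = [
    "M_ext_Nm", "dtheta_deg",
    "F_ATT_N", "F_TC_N", "F_PTT_N", "F_ATF_N", "F_CF_N", "F_PTF_N",
    "F_contact_N", "converged",
]


def sweep_to_frame(sweep: SweepResult) -> pd.DataFrame:
    data = {
        "M_ext_Nm": sweep.moments,
        "dtheta_deg": sweep.angular_displacement,
    }
    for j, col in enumerate(_SWEEP_COLUMNS[2:9]):
        data[col] = sweep.element_forces[:, j]
    data["converged"] = sweep.converged.astype(bool)
    return pd.DataFrame(data, columns=_SWEEP_COLUMNS)


def write_sweep_csv(sweep: SweepResult, path: str | Path) -> None:
    sweep_to_frame(sweep).to_csv(path, index=False)


def read_sweep_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sweep CSV: missing column(s) {missing}")
    return df


def write_trace_csv(result: GAResult, path: str | Path) -> None:
    """Per-generation best/worst/average objective trace."""
    pd.DataFrame(
        {
            "generation": np.arange(result.best_trace.size),
            "best_h": result.best_trace,
            "worst_h": result.worst_trace,
            "avg_h": result.avg_trace,
        }
    ).to_csv(path, index=False)


def write_oat_csv(oat_result, path: str | Path) -> None:
    oat_result.to_frame().to_csv(path, index=False)
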