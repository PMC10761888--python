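"""CSV/JSON input and output.

All tables are plain UTF-8 CSV with a header row and '.' decimals.
Kinematic records travel in long format (one row per sample); curve and
scalar tables are one row per sample/observation.  Ground truth from the
synthetic generator is stored as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import SchemaError
from .preprocess import ContinuousRecord, ObservationKinematics
from .simulate import GroundTruth

__all__ = [
    "read_records",
    "write_records",
    "write_curves",
    "read_scalars",
    "write_scalars",
    "write_ground_truth",
]

RECORD_COLUMNS = ["subject_id", "session", "time_s", "angle_deg"]
SCALAR_COLUMNS = ["subject_id", "session", "ndi", "RoM", "RoV"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns: {missing}")


def read_records(path: str | Path) -> list[ContinuousRecord]:
    """Read long-format continuous records, one per (subject, session)."""
    df = pd.read_csv(path)
    _require_columns(df, RECORD_COLUMNS, f"record table {path}")
    records = []
    for (sid, sess), grp in df.groupby(["subject_id", "session"], sort=False):
        t = grp["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise SchemaError(
                f"time_s not strictly increasing for ({sid}, {sess})"
            )
        records.append(
            ContinuousRecord(
                subject_id=str(sid),
                session=str(sess),
                time_s=t,
                angle_deg=grp["angle_deg"].to_numpy(float),
            )
        )
    return records


def write_records(records: list[ContinuousRecord], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "subject_id": r.subject_id,
                "session": r.session,
                "time_s": r.time_s,
                "angle_deg": r.angle_deg,
            }
        )
        for r in records
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def write_curves(
    observations: list[ObservationKinematics], path: str | Path
) -> None:
    """Per-observation normalized mean curves in long format."""
    frames = [
        pd.DataFrame(
            {
                "subject_id": o.subject_id,
                "session": o.session,
                "t_norm": o.mean_angle.grid,
                "angle_deg": o.mean_angle.values,
                "velocity_dps": o.mean_velocity.values,
            }
        )
        for o in observations
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_scalars(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SCALAR_COLUMNS, f"scalar table {path}")
    return df


def write_scalars(scalars: pd.DataFrame, path: str | Path) -> None:
    _require_columns(scalars, SCALAR_COLUMNS, "scalar table")
    scalars.to_csv(path, index=False, float_format="%.12g")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_beta0": truth.true_beta0,
        "true_b": truth.true_b.tolist(),
        "n_basis": truth.basis.n_funcs,
        "true_integrals": truth.true_integrals.tolist(),
        "linear_predictor": truth.linear_predictor.tolist(),
        "omega_coefs": truth.omega_coefs.tolist(),
        "angle_coefs": truth.angle_coefs.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
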