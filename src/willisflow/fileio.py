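"""Readers and writers for the package's file schemas.

Clinical units at the file boundary (mm, cm/s, mmHg, ml); SI inside.  All
numeric columns are serialized with 17 significant digits so every
writer/reader pair round-trips binary64 values losslessly and repeated runs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .calibration import CalibrationInput, VelocityTarget
from .network import PatientGeometry
from .units import MM_TO_M, MMHG_TO_PA

FLOAT_FORMAT = "%.17g"

GEOMETRY_COLUMNS = ["investigation_id", "segment_name", "point_index", "diameter_mm"]
MEASUREMENT_COLUMNS = [
    "investigation_id",
    "site",
    "v_mean_cm_s",
    "v_sys_cm_s",
    "v_dia_cm_s",
]
VITALS_COLUMNS = ["investigation_id", "sbp_mmHg", "dbp_mmHg", "hr_bpm"]


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_geometry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, GEOMETRY_COLUMNS, path)
    bad = df[df["diameter_mm"] < 0]
    if not bad.empty:
        raise SchemaError(
            f"{path}: negative diameter at row {int(bad.index[0]) + 2}"
        )
    return df


def geometries_from_frame(
    df: pd.DataFrame, heart_periods: Mapping[str, float] | None = None
) -> dict[str, PatientGeometry]:
    """One PatientGeometry per investigation (diameters converted to metres)."""
    out: dict[str, PatientGeometry] = {}
    for inv_id, sub in df.groupby("investigation_id", sort=True):
        points = {
            seg: tuple(
                float(d) * MM_TO_M
                for d in grp.sort_values("point_index")["diameter_mm"]
            )
            for seg, grp in sub.groupby("segment_name", sort=True)
        }
        period = (heart_periods or {}).get(str(inv_id), 0.8)
        out[str(inv_id)] = PatientGeometry(str(inv_id), points, period)
    return out


def read_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, MEASUREMENT_COLUMNS[:3], path)
    for optional in MEASUREMENT_COLUMNS[3:]:
        if optional not in df.columns:
            df[optional] = float("nan")
    bad = df[df["v_mean_cm_s"] <= 0]
    if not bad.empty:
        raise SchemaError(
            f"{path}: non-positive mean velocity at row {int(bad.index[0]) + 2}"
        )
    return df


def read_vitals_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, VITALS_COLUMNS, path)
    return df


def calibration_inputs_from_frames(
    measurements: pd.DataFrame, vitals: pd.DataFrame
) -> dict[str, CalibrationInput]:
    """Join the measurement and vitals tables into per-investigation inputs."""
    vit = vitals.set_index(vitals["investigation_id"].astype(str))
    out: dict[str, CalibrationInput] = {}
    for inv_id, sub in measurements.groupby("investigation_id", sort=True):
        inv_id = str(inv_id)
        if inv_id not in vit.index:
            raise SchemaError(f"investigation {inv_id} missing from vitals table")
        row = vit.loc[inv_id]
        targets: dict[str, VelocityTarget] = {}
        for _, r in sub.iterrows():
            if pd.notna(r["v_sys_cm_s"]) and pd.notna(r["v_dia_cm_s"]):
                targets[r["site"]] = VelocityTarget(
                    mean=r["v_mean_cm_s"] * 1e-2,
                    systolic=r["v_sys_cm_s"] * 1e-2,
                    diastolic=r["v_dia_cm_s"] * 1e-2,
                )
            else:
                targets[r["site"]] = VelocityTarget(mean=r["v_mean_cm_s"] * 1e-2)
        out[inv_id] = CalibrationInput(
            systolic_bp=float(row["sbp_mmHg"]) * MMHG_TO_PA,
            diastolic_bp=float(row["dbp_mmHg"]) * MMHG_TO_PA,
            heart_period=60.0 / float(row["hr_bpm"]),
            tcd_targets=targets,
            mean_bp=(
                float(row["map_mmHg"]) * MMHG_TO_PA
                if "map_mmHg" in row and pd.notna(row["map_mmHg"])
                else None
            ),
            stroke_volume=(
                float(row["stroke_volume_ml"]) * 1e-6
                if "stroke_volume_ml" in row and pd.notna(row["stroke_volume_ml"])
                else 70e-6
            ),
        )
    return out


def write_simulation_csv(result, path) -> None:
    """Tidy long-format waveforms: time_s, variable, value (SI)."""
    frames = []
    for name in result.system.seg_names:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": result.time,
                    "variable": f"flow:{name}",
                    "value": result.segment_flow(name),
                }
            )
        )
    for name in result.system.node_names:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": result.time,
                    "variable": f"pressure:{name}",
                    "value": result.node_pressure(name),
                }
            )
        )
    write_csv(pd.concat(frames, ignore_index=True), path)


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
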