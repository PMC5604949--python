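"""Readers and writers for the breath / trajectory / report CSV dialects.

CSV was chosen over a bespoke binary format because breath-by-breath gas
exchange has no entrenched interchange standard; column names mirror
metabolic-cart export naming where practical.  All files are UTF-8 with
'.' decimal separators and a required header.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gp import GPHyperparameters
from .optimizers import Trajectory, TrajectoryStep
from .respiratory import BreathSeries
from .simulator import SubjectProfile

__all__ = [
    "read_breath_csv",
    "write_breath_csv",
    "read_angle_csv",
    "write_angle_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_subject_yaml",
    "write_subject_yaml",
]

log = logging.getLogger(__name__)

BREATH_COLUMNS = ["t_s", "h_s", "vo2_ml_min", "vco2_ml_min"]
TRAJ_COLUMNS = ["iter", "method", "phase", "x_cmd_hz", "x_meas_hz", "cost",
                "cost_units", "duration_s", "hyp_sigma2", "hyp_l",
                "hyp_noise2"]

#: Tolerated discrepancy between t differences and h values (seconds).
TIME_CONSISTENCY_TOL_S = 1e-3


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_breath_csv(path) -> BreathSeries:
    """Read a breath-by-breath CSV (t_s, h_s, vo2_ml_min, vco2_ml_min
    and optional x_meas_hz); warns if t and h disagree beyond 1 ms."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, BREATH_COLUMNS, path)
    for col in BREATH_COLUMNS:
        bad = df.index[df[col].isna() | ~np.isfinite(df[col].astype(float))]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(f"{path}: malformed value in column {col!r} "
                             f"at line {int(bad[0]) + 2}")
    t = df["t_s"].to_numpy(float)
    h = df["h_s"].to_numpy(float)
    if len(t) > 1:
        mismatch = np.abs(np.diff(t) - h[1:])
        if np.any(mismatch > TIME_CONSISTENCY_TOL_S):
            j = int(np.argmax(mismatch > TIME_CONSISTENCY_TOL_S))
            log.warning("%s: t/h inconsistency of %.4f s at line %d",
                        path, float(mismatch[j]), j + 3)
    from .respiratory import brockway_power

    vo2 = df["vo2_ml_min"].to_numpy(float)
    vco2 = df["vco2_ml_min"].to_numpy(float)
    return BreathSeries(
        t=t, h=h, power=brockway_power(vo2, vco2), vo2=vo2, vco2=vco2,
        x_meas=df["x_meas_hz"].to_numpy(float)
        if "x_meas_hz" in df.columns else None,
    )


def write_breath_csv(series: BreathSeries, path) -> None:
    """Write a breath series in the standard dialect.

    Gas columns are required by the dialect; if the series carries only
    power they are backed out at a fixed respiratory exchange ratio.
    """
    if series.vo2 is None or series.vco2 is None:
        from .respiratory import BROCKWAY_CO2_J_PER_ML, BROCKWAY_O2_J_PER_ML
        from .simulator import DEFAULT_RER

        p = np.maximum(series.power, 0.0)
        vo2 = p * 60.0 / (BROCKWAY_O2_J_PER_ML
                          + BROCKWAY_CO2_J_PER_ML * DEFAULT_RER)
        vco2 = DEFAULT_RER * vo2
    else:
        vo2, vco2 = series.vo2, series.vco2
    df = pd.DataFrame({"t_s": series.t, "h_s": series.h,
                       "vo2_ml_min": vo2, "vco2_ml_min": vco2})
    if series.x_meas is not None:
        df["x_meas_hz"] = series.x_meas
    df.to_csv(path, index=False, float_format="%.10g")


def read_angle_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a thigh-angle CSV (t_s, angle_deg); returns (t, angle)."""
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "angle_deg"], path)
    return df["t_s"].to_numpy(float), df["angle_deg"].to_numpy(float)


def write_angle_csv(t: np.ndarray, angle: np.ndarray, path) -> None:
    pd.DataFrame({"t_s": t, "angle_deg": angle}).to_csv(
        path, index=False, float_format="%.10g")


def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_trajectory_csv(path, x_pref: float | None = None) -> Trajectory:
    df = pd.read_csv(path)
    _require_columns(df, TRAJ_COLUMNS[:8], path)
    traj = Trajectory(method=str(df["method"].iloc[0]) if len(df) else "",
                      x_pref=x_pref)
    for _, row in df.iterrows():
        hp = None
        if "hyp_sigma2" in df.columns and np.isfinite(row.get("hyp_sigma2",
                                                              np.nan)):
            hp = GPHyperparameters(float(row["hyp_sigma2"]),
                                   float(row["hyp_l"]),
                                   float(row["hyp_noise2"]))
        traj.append(TrajectoryStep(
            iter=int(row["iter"]), method=str(row["method"]),
            phase=str(row["phase"]), x_cmd=float(row["x_cmd_hz"]),
            x_meas=float(row["x_meas_hz"]), cost=float(row["cost"]),
            cost_units=str(row["cost_units"]),
            duration_s=float(row["duration_s"]), hp=hp))
    return traj


def read_subject_yaml(path) -> SubjectProfile:
    """Read a SubjectProfile from YAML (field names match the dataclass)."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    valid = set(SubjectProfile.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown subject field(s) {sorted(unknown)}")
    return SubjectProfile(**raw)


def write_subject_yaml(subject: SubjectProfile, path) -> None:
    fields = {k: getattr(subject, k)
              for k in SubjectProfile.__dataclass_fields__}
    with open(path, "w") as f:
        yaml.safe_dump(fields, f, sort_keys=False)
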