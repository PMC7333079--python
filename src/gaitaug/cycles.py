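"""Gait-cycle containers and the shared cycle-dataset table format.

A gait cycle is one stride (initial contact to next initial contact of the
same foot), time-normalized to 100 points.  The cycle-dataset format is a
long-form table with one row per (cycle, time point):

``subject_id, gait, trial, source, speed_mps, bw_kg, bh_m, time_index`` plus
12 inertial channels (fixed order, see :data:`IMU_COLUMNS`) and 8
biomechanical channels (:data:`BIOMECH_COLUMNS`).  Angles are stored in
degrees, moments in N m, and ground reaction forces normalized to body weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_POINTS = 100

# sensor order is proximal -> distal; per sensor: A-P acceleration (m/s^2),
# longitudinal acceleration (m/s^2), medial-lateral angular velocity (rad/s)
IMU_COLUMNS = [
    f"{sensor}_{ch}"
    for sensor in ("lowerback", "thigh_r", "shank_r", "foot_r")
    for ch in ("acc_ap", "acc_long", "gyro_ml")
]

BIOMECH_COLUMNS = [
    "hip_angle_deg",
    "knee_angle_deg",
    "ankle_angle_deg",
    "hip_moment_nm",
    "knee_moment_nm",
    "ankle_moment_nm",
    "grf_ap_bw",
    "grf_v_bw",
]

META_COLUMNS = ["subject_id", "gait", "trial", "source", "speed_mps", "bw_kg", "bh_m"]
KEY_COLUMNS = ["subject_id", "gait", "trial", "source"]
ALL_COLUMNS = META_COLUMNS + ["time_index"] + IMU_COLUMNS + BIOMECH_COLUMNS


@dataclass
class GaitCycle:
    """One segmented stride: biomechanics, inertial channels, metadata.

    Angles are stored in radians and GRFs in body-weight units internally;
    the dataset table uses degrees (conversion happens at the table boundary).
    """

    subject_id: str
    gait: str  # 'walk' | 'run'
    speed: float  # m/s
    bw: float  # body weight (kg)
    bh: float  # body height (m)
    hip_angle: np.ndarray  # (100,) rad
    knee_angle: np.ndarray
    ankle_angle: np.ndarray
    grf_ap: np.ndarray  # (100,) BW units
    grf_v: np.ndarray
    hip_moment: np.ndarray | None = None  # (100,) N m
    knee_moment: np.ndarray | None = None
    ankle_moment: np.ndarray | None = None
    imu: np.ndarray | None = None  # (100, 12)
    trial: int = 0
    source: str = "measured"

    def __post_init__(self):
        for name in ("hip_angle", "knee_angle", "ankle_angle", "grf_ap", "grf_v"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_POINTS,):
                raise ValueError(f"{name} must have {N_POINTS} points, got {arr.shape}")
            setattr(self, name, arr)
        if self.gait not in ("walk", "run"):
            raise ValueError(f"gait must be 'walk' or 'run', got {self.gait!r}")


def cycles_to_table(cycles: list) -> pd.DataFrame:
    """Long-form cycle-dataset table from a list of GaitCycle."""
    frames = []
    for c in cycles:
        rows = {
            "subject_id": c.subject_id,
            "gait": c.gait,
            "trial": c.trial,
            "source": c.source,
            "speed_mps": c.speed,
            "bw_kg": c.bw,
            "bh_m": c.bh,
            "time_index": np.arange(N_POINTS),
            "hip_angle_deg": np.degrees(c.hip_angle),
            "knee_angle_deg": np.degrees(c.knee_angle),
            "ankle_angle_deg": np.degrees(c.ankle_angle),
            "hip_moment_nm": c.hip_moment if c.hip_moment is not None else np.nan,
            "knee_moment_nm": c.knee_moment if c.knee_moment is not None else np.nan,
            "ankle_moment_nm": c.ankle_moment if c.ankle_moment is not None else np.nan,
            "grf_ap_bw": c.grf_ap,
            "grf_v_bw": c.grf_v,
        }
        imu = c.imu if c.imu is not None else np.full((N_POINTS, 12), np.nan)
        for j, col in enumerate(IMU_COLUMNS):
            rows[col] = imu[:, j]
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)[ALL_COLUMNS]


def table_to_cycles(df: pd.DataFrame) -> list:
    """Inverse of :func:`cycles_to_table` (validates 100 rows per cycle key)."""
    validate_table(df)
    cycles = []
    for key, g in df.groupby(KEY_COLUMNS + ["speed_mps"], sort=False):
        g = g.sort_values("time_index")
        subject, gait, trial, source, speed = key
        cycles.append(
            GaitCycle(
                subject_id=subject,
                gait=gait,
                trial=int(trial),
                source=source,
                speed=float(speed),
                bw=float(g["bw_kg"].iloc[0]),
                bh=float(g["bh_m"].iloc[0]),
                hip_angle=np.radians(g["hip_angle_deg"].to_numpy()),
                knee_angle=np.radians(g["knee_angle_deg"].to_numpy()),
                ankle_angle=np.radians(g["ankle_angle_deg"].to_numpy()),
                grf_ap=g["grf_ap_bw"].to_numpy(),
                grf_v=g["grf_v_bw"].to_numpy(),
                hip_moment=g["hip_moment_nm"].to_numpy(),
                knee_moment=g["knee_moment_nm"].to_numpy(),
                ankle_moment=g["ankle_moment_nm"].to_numpy(),
                imu=g[IMU_COLUMNS].to_numpy(),
            )
        )
    return cycles


def validate_table(df: pd.DataFrame) -> None:
    """Check the cycle-dataset contract: columns present, 100 points per cycle."""
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cycle table is missing columns: {missing}")
    counts = df.groupby(KEY_COLUMNS + ["speed_mps"]).size()
    bad = counts[counts != N_POINTS]
    if len(bad):
        raise ValueError(f"cycles without exactly {N_POINTS} rows:\n{bad}")


def imu_matrix(df: pd.DataFrame) -> tuple:
    """Stack a cycle table into (X, Y, meta): X (n, 100, 12), Y dict of (n, 100).

    Cycle order follows first appearance in the table.  Y contains the eight
    biomechanical channels keyed by column name; meta is a per-cycle DataFrame.
    """
    validate_table(df)
    metas, xs, ys = [], [], {c: [] for c in BIOMECH_COLUMNS}
    for key, g in df.groupby(KEY_COLUMNS + ["speed_mps"], sort=False):
        g = g.sort_values("time_index")
        xs.append(g[IMU_COLUMNS].to_numpy())
        for c in BIOMECH_COLUMNS:
            ys[c].append(g[c].to_numpy())
        metas.append(g.iloc[0][META_COLUMNS])
    X = np.stack(xs)
    Y = {c: np.stack(v) for c, v in ys.items()}
    meta = pd.DataFrame(metas).reset_index(drop=True)
    return X, Y, meta
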