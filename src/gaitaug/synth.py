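"""Synthetic measured-like gait benchmark.

Generates a cohort dataset shaped like a typical treadmill/overground
protocol: 10 subjects, three walking speed bands (0.9-1.0, 1.2-1.4,
1.8-2.0 m/s) and three running bands (3.1-3.3, 3.9-4.1, 4.7-4.9 m/s), ~10
trials per band.  Joint-angle and GRF cycles come from smooth gait-shaped
templates whose coefficients vary with speed, subject style, and trial; trunk
translation is reconstructed from the GRFs, joint moments follow from inverse
dynamics, and inertial channels from the virtual sensor model.  "Measured"
cycles additionally receive white sensor noise and a low-frequency
soft-tissue artifact — the reality gap that separates them from the smooth
simulated data.

Walking vertical GRF is double-peaked, running single-peaked with a flight
phase; every generated vertical GRF is non-negative, exactly zero in swing,
and scaled so its full-cycle mean is 0.5 body weight per leg (steady-gait
impulse balance).  No claim is made of matching any particular cohort —
the templates exist so every pipeline stage can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cycles import N_POINTS, GaitCycle, cycles_to_table
from .imu import default_sensors, simulate_imu_cycle
from .motion import inverse_dynamics_moments, reconstruct_motion
from .msk.params import Anthropometry, scale_model

WALK_BANDS = ((0.9, 1.0), (1.2, 1.4), (1.8, 2.0))
RUN_BANDS = ((3.1, 3.3), (3.9, 4.1), (4.7, 4.9))

_TAU = np.arange(N_POINTS) / N_POINTS


def _bump(tau, center, width):
    """Periodic Gaussian bump on the unit circle."""
    d = np.mod(tau - center + 0.5, 1.0) - 0.5
    return np.exp(-((d / width) ** 2))


@dataclass
class SubjectProfile:
    """Reproducible per-subject anthropometry, movement style, and noise levels."""

    subject_id: str
    bw: float  # kg
    bh: float  # m
    angle_offset: np.ndarray  # (3,) rad, added to hip/knee/ankle
    amp_factor: np.ndarray  # (3,) multiplicative excursion scaling
    timing_shift: float  # cycle fraction, shifts bump centers
    trunk_lean: float  # rad
    acc_noise_sd: float  # m/s^2
    gyro_noise_sd: float  # rad/s
    artifact_amp: float  # soft-tissue artifact, fraction of channel peak


def subject_profile(seed: int, index: int) -> SubjectProfile:
    rng = np.random.default_rng([seed, index])
    return SubjectProfile(
        subject_id=f"S{index + 1:02d}",
        bw=float(rng.uniform(55.0, 95.0)),
        bh=float(rng.uniform(1.60, 1.92)),
        angle_offset=np.radians(rng.uniform(-3.0, 3.0, size=3)),
        amp_factor=rng.uniform(0.92, 1.08, size=3),
        timing_shift=float(rng.uniform(-0.015, 0.015)),
        trunk_lean=float(np.radians(rng.uniform(-2.0, 2.0))),
        acc_noise_sd=float(rng.uniform(0.30, 0.60)),
        gyro_noise_sd=float(rng.uniform(0.03, 0.06)),
        artifact_amp=float(rng.uniform(0.03, 0.07)),
    )


def gait_template(speed: float, gait: str, prof: SubjectProfile, rng=None) -> dict:
    """Speed- and style-dependent angle (rad) and GRF (BW) cycles.

    ``rng`` adds trial-level variation: smooth low-order Fourier perturbations
    of the angles and a bounded multiplicative GRF jitter.
    """
    tau = _TAU
    ts_shift = prof.timing_shift

    if gait == "walk":
        dv = speed - 1.3
        stance_frac = np.clip(0.62 - 0.03 * dv, 0.45, 0.70)
        hip = np.radians(8.0 + (18.0 + 3.0 * dv) * np.cos(2 * np.pi * tau) + 4.0 * np.sin(2 * np.pi * tau))
        knee = -np.radians(
            5.0
            + (12.0 + 4.0 * dv) * _bump(tau, 0.17 + ts_shift, 0.09)
            + (55.0 + 6.0 * dv) * _bump(tau, 0.73 + ts_shift, 0.11)
        )
        ankle = np.radians(
            -6.0 * _bump(tau, 0.05 + ts_shift, 0.05)
            + 10.0 * _bump(tau, 0.42 + ts_shift, 0.18)
            - 18.0 * _bump(tau, 0.62 + ts_shift, 0.07)
        )
        double_hump = 0.30
        env_power = 0.9
        ap_amp = 0.16 + 0.06 * dv
        impact = 0.0
    else:
        dv = speed - 4.0
        stance_frac = np.clip(0.36 - 0.012 * dv, 0.25, 0.45)
        hip = np.radians(12.0 + (25.0 + 3.0 * dv) * np.cos(2 * np.pi * tau) + 6.0 * np.sin(2 * np.pi * tau))
        knee = -np.radians(
            12.0
            + 25.0 * _bump(tau, 0.14 + ts_shift, 0.10)
            + (75.0 + 5.0 * dv) * _bump(tau, 0.70 + ts_shift, 0.11)
        )
        ankle = np.radians(
            12.0 * _bump(tau, 0.18 + ts_shift, 0.12)
            - 22.0 * _bump(tau, 0.36 + ts_shift, 0.07)
            + 5.0 * _bump(tau, 0.70 + ts_shift, 0.20)
        )
        double_hump = 0.0
        env_power = 1.1
        ap_amp = 0.25 + 0.05 * dv
        impact = 0.12

    # subject style
    hip = prof.amp_factor[0] * hip + prof.angle_offset[0]
    knee = prof.amp_factor[1] * knee + prof.angle_offset[1]
    ankle = prof.amp_factor[2] * ankle + prof.angle_offset[2]

    # stance-normalized GRF shapes, exactly zero in swing
    s = tau / stance_frac
    in_stance = s < 1.0
    s = np.clip(s, 0.0, 1.0)
    env = np.where(in_stance, np.sin(np.pi * s) ** env_power, 0.0)
    shape = 1.0 + double_hump * np.cos(2 * np.pi * s) + impact * _bump(s, 0.12, 0.08)
    grf_v = env * shape
    grf_ap = np.where(in_stance, -ap_amp * np.sin(2 * np.pi * s) * np.sin(np.pi * s) ** 0.5, 0.0)

    if rng is not None:
        for arr, amp in ((hip, 0.015), (knee, 0.015), (ankle, 0.012)):
            arr += _smooth_noise(rng, amp)
        grf_v = grf_v * (1.0 + np.clip(_smooth_noise(rng, 0.03), -0.5, 0.5))
        grf_ap = grf_ap * (1.0 + np.clip(_smooth_noise(rng, 0.04), -0.5, 0.5))

    # impulse balance: mean single-leg vertical GRF = 0.5 BW over the cycle
    grf_v *= 0.5 / grf_v.mean()
    return {"hip": hip, "knee": knee, "ankle": ankle, "grf_ap": grf_ap, "grf_v": grf_v}


def _smooth_noise(rng, sd: float, order: int = 3) -> np.ndarray:
    """Zero-mean smooth periodic perturbation (low-order Fourier series)."""
    out = np.zeros(N_POINTS)
    for k in range(1, order + 1):
        a, b = rng.normal(scale=sd / np.sqrt(order), size=2)
        out += a * np.cos(2 * np.pi * k * _TAU) + b * np.sin(2 * np.pi * k * _TAU)
    return out


def synthesize_cycle(
    prof: SubjectProfile,
    gait: str,
    speed: float,
    trial: int,
    rng,
    *,
    add_sensor_noise: bool = True,
) -> GaitCycle:
    """One complete cycle: template biomechanics -> motion -> moments -> IMU."""
    model = scale_model(Anthropometry(prof.bw, prof.bh))
    ch = gait_template(speed, gait, prof, rng=rng)
    motion = reconstruct_motion(
        ch["hip"], ch["knee"], ch["ankle"], ch["grf_ap"], ch["grf_v"],
        speed, model, gait, trunk_lean_rad=prof.trunk_lean,
    )
    moments = inverse_dynamics_moments(motion, ch["grf_ap"], ch["grf_v"])
    imu = simulate_imu_cycle(motion, default_sensors(model))

    if add_sensor_noise:
        imu = imu.copy()
        for j in range(12):
            is_gyro = j % 3 == 2
            sd = prof.gyro_noise_sd if is_gyro else prof.acc_noise_sd
            peak = np.abs(imu[:, j]).max()
            phase = rng.uniform(0, 2 * np.pi)
            artifact = prof.artifact_amp * peak * np.sin(4 * np.pi * _TAU + phase)
            imu[:, j] += rng.normal(scale=sd, size=N_POINTS) + artifact

    return GaitCycle(
        subject_id=prof.subject_id,
        gait=gait,
        speed=speed,
        bw=prof.bw,
        bh=prof.bh,
        hip_angle=ch["hip"],
        knee_angle=ch["knee"],
        ankle_angle=ch["ankle"],
        grf_ap=ch["grf_ap"],
        grf_v=ch["grf_v"],
        hip_moment=moments[:, 0],
        knee_moment=moments[:, 1],
        ankle_moment=moments[:, 2],
        imu=imu,
        trial=trial,
        source="measured" if add_sensor_noise else "simulated",
    )


def generate_dataset(
    n_subjects: int = 10, trials_per_band: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Generate the full benchmark cohort in the cycle-dataset format.

    Deterministic per seed.  Requires at least 4 subjects so train/test splits
    remain possible at reduced scale.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects for a usable benchmark")
    if trials_per_band < 1:
        raise ValueError("trials_per_band must be >= 1")

    cycles = []
    for i in range(n_subjects):
        prof = subject_profile(seed, i)
        trial = 0
        for gait, bands in (("walk", WALK_BANDS), ("run", RUN_BANDS)):
            for band in bands:
                for k in range(trials_per_band):
                    rng = np.random.default_rng([seed, i, trial, 7])
                    speed = float(rng.uniform(*band))
                    cycles.append(
                        synthesize_cycle(prof, gait, speed, trial, rng)
                    )
                    trial += 1
    return cycles_to_table(cycles)


def generate_benchmark_split(dataset: pd.DataFrame) -> tuple:
    """Fixed disjoint (train, test) subject split mirroring a 7/3 pattern.

    The first three subjects (by sorted id) are held out for testing; the rest
    train.  Independent of trial ordering.  Requires >= 4 subjects.
    """
    subjects = sorted(dataset["subject_id"].unique())
    if len(subjects) < 4:
        raise ValueError(f"need at least 4 subjects to split, got {len(subjects)}")
    test = subjects[:3]
    train = subjects[3:]
    return train, test
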