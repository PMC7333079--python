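"""Virtual inertial sensors: sagittal accelerometer and gyroscope synthesis.

Four sensors ride on the lower back (trunk), right thigh, right shank, and
right foot.  Each contributes two accelerometer channels (A-P and
longitudinal specific force, m/s^2) and one gyroscope channel (medial-lateral
angular velocity, rad/s), giving the fixed 100 x 12 input of the estimator:

    [lowerback, thigh_r, shank_r, foot_r] x [acc_ap, acc_long, gyro_ml]

Sensor axes are defined in the segment frame so that in quiet upright standing
every accelerometer reads (0, +g) and every gyroscope reads zero.  The
medial-lateral gyroscope axis points left (+z of the sagittal plane), so the
reported angular velocity is the counterclockwise segment rate.  Specific
force is computed by double spectral differentiation of the sensor-point world
trajectory (cycles are periodic up to the forward translation), minus gravity,
rotated into the segment frame; this includes the tangential and centripetal
terms automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cycles import N_POINTS
from .motion import Motion, fft_derivative
from .msk.kinematics import CHAIN, BodyKinematics, rot_apply
from .msk.params import ModelParams

#: fixed sensor role order of the 12-channel matrix (proximal -> distal)
SENSOR_ORDER = ("trunk", "thigh_r", "shank_r", "foot_r")


@dataclass
class SensorSpec:
    """One virtual inertial sensor fixed on a model segment.

    ``offset`` is the sensor position in the segment frame (metres, frame
    aligned with the world at the neutral pose).  The axis vectors define the
    A-P and longitudinal accelerometer directions in the same frame.
    """

    segment: str
    offset: tuple
    ap_axis: tuple = (1.0, 0.0)
    long_axis: tuple = (0.0, 1.0)

    def __post_init__(self):
        if self.segment not in CHAIN:
            raise ValueError(f"unknown segment {self.segment!r}")


def default_sensors(params: ModelParams) -> list:
    """Sensor placements emulating lower back, lateral thigh/shank, foot dorsum."""
    bh = params.body_height
    return [
        SensorSpec("trunk", (-0.05 * bh / 1.75, 0.10 * bh / 1.75)),
        SensorSpec("thigh_r", (0.02, -0.55 * params.segments["thigh_r"].length)),
        SensorSpec("shank_r", (0.02, -0.45 * params.segments["shank_r"].length)),
        SensorSpec("foot_r", (0.45 * params.segments["foot_r"].length, 0.01)),
    ]


def _segment_angle(motion: Motion, segment: str) -> np.ndarray:
    idx = list(CHAIN[segment])
    return motion.q[:, idx].sum(axis=1)


def gyro_signal(motion: Motion, sensor: SensorSpec) -> np.ndarray:
    """Medial-lateral angular velocity (rad/s, 100 points) of the host segment.

    The segment rate is the trunk angular rate plus the joint angular rates
    along the chain from the trunk to the host segment (angles add along the
    chain, counterclockwise-positive).
    """
    phi = _segment_angle(motion, sensor.segment)
    return fft_derivative(phi, motion.duration)


def accel_signal(motion: Motion, sensor: SensorSpec) -> np.ndarray:
    """Specific force at the sensor point, (100, 2) = (A-P, longitudinal) m/s^2.

    Second spectral time-derivative of the sensor-point world trajectory
    (secular forward translation removed first), minus gravity, expressed in
    the sensor axes.  Standing still this reads (0, +g).
    """
    p = motion.params
    kin = BodyKinematics(motion.q, params=p)
    pos, _, _ = kin.point_on(sensor.segment, np.asarray(sensor.offset, dtype=float))
    t = np.arange(N_POINTS) / N_POINTS * motion.duration
    pos = pos.copy()
    pos[:, 0] -= motion.speed * t
    acc = fft_derivative(pos, motion.duration, order=2, axis=0)
    f = acc - np.array([0.0, -p.gravity])[None, :]

    phi = _segment_angle(motion, sensor.segment)
    ap = rot_apply(phi, np.asarray(sensor.ap_axis, dtype=float))
    lo = rot_apply(phi, np.asarray(sensor.long_axis, dtype=float))
    return np.stack([np.einsum("ki,ki->k", f, ap), np.einsum("ki,ki->k", f, lo)], axis=1)


def simulate_imu_cycle(motion: Motion, sensors: list) -> np.ndarray:
    """Assemble the 100 x 12 inertial matrix in the fixed channel order.

    Exactly one sensor per role (trunk, right thigh, right shank, right foot)
    is required; the output channel order is by role, not input position.
    """
    by_segment = {s.segment: s for s in sensors}
    if len(sensors) != 4 or set(by_segment) != set(SENSOR_ORDER):
        raise ValueError(
            f"need exactly one sensor per role {SENSOR_ORDER}, got "
            f"{[s.segment for s in sensors]}"
        )
    out = np.empty((N_POINTS, 12))
    for i, segment in enumerate(SENSOR_ORDER):
        s = by_segment[segment]
        acc = accel_signal(motion, s)
        out[:, 3 * i : 3 * i + 2] = acc
        out[:, 3 * i + 2] = gyro_signal(motion, s)
    return out
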