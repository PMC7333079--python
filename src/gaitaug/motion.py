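"""Full-cycle motions: spectral calculus, kinematic reconstruction, inverse dynamics.

A :class:`Motion` holds the generalized-coordinate trajectory of one full gait
cycle on the 100-point normalized grid, together with the cycle duration and
forward speed.  Motions come from two places: expanded optimal-control
solutions (dynamically consistent) and the kinematic reconstruction below
(approximate, used to synthesize sensor data directly from angle/GRF cycles).

Cycles are periodic up to the forward translation of the trunk, so derivatives
are taken spectrally (FFT) after removing the secular term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycles import N_POINTS
from .msk.dynamics import NQ, equations_of_motion_residual
from .msk.kinematics import BodyKinematics
from .msk.params import ModelParams

STANCE_THRESHOLD_BW = 0.05  # vertical GRF threshold defining ground contact


@dataclass
class Motion:
    """One full gait cycle of the planar model.

    q : (100, 9) generalized coordinates; q[:, 0] carries the secular forward
    translation (speed * duration per cycle), everything else is periodic.
    """

    q: np.ndarray
    duration: float  # full-cycle duration (s)
    speed: float  # m/s
    params: ModelParams
    provenance: dict | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (N_POINTS, NQ):
            raise ValueError(f"q must be ({N_POINTS}, {NQ}), got {self.q.shape}")

    def q_periodic(self) -> np.ndarray:
        """Coordinates with the secular forward translation removed."""
        qp = self.q.copy()
        t = np.arange(N_POINTS) / N_POINTS * self.duration
        qp[:, 0] -= self.speed * t
        return qp

    def derivatives(self) -> tuple:
        """(qd, qdd) on the cycle grid via spectral differentiation."""
        qp = self.q_periodic()
        qd = fft_derivative(qp, self.duration, axis=0)
        qd[:, 0] += self.speed
        qdd = fft_derivative(qd, self.duration, axis=0)
        return qd, qdd


def fft_derivative(y: np.ndarray, period: float, order: int = 1, axis: int = 0) -> np.ndarray:
    """Derivative of a periodic signal sampled uniformly over one period."""
    y = np.asarray(y, dtype=float)
    n = y.shape[axis]
    freqs = np.fft.rfftfreq(n, d=period / n)
    Y = np.fft.rfft(y, axis=axis)
    shape = [1] * y.ndim
    shape[axis] = len(freqs)
    Y = Y * (2j * np.pi * freqs.reshape(shape)) ** order
    return np.fft.irfft(Y, n=n, axis=axis)


def fft_integrate(y: np.ndarray, period: float, axis: int = 0) -> np.ndarray:
    """Zero-mean antiderivative of a zero-mean periodic signal."""
    y = np.asarray(y, dtype=float)
    n = y.shape[axis]
    freqs = np.fft.rfftfreq(n, d=period / n)
    Y = np.fft.rfft(y, axis=axis)
    shape = [1] * y.ndim
    shape[axis] = len(freqs)
    w = np.zeros(len(freqs), dtype=complex)
    w[1:] = 1.0 / (2j * np.pi * freqs[1:])
    Y = Y * w.reshape(shape)
    Y[(slice(None),) * axis + (0,)] = 0.0
    return np.fft.irfft(Y, n=n, axis=axis)


def cycle_duration(speed: float, gait: str) -> float:
    """Stride time (s) as a smooth decreasing function of speed, per gait."""
    if gait == "walk":
        return float(np.clip(1.45 - 0.25 * speed, 0.85, 1.45))
    return float(np.clip(0.80 - 0.033 * speed, 0.55, 0.80))


def reconstruct_motion(
    hip: np.ndarray,
    knee: np.ndarray,
    ankle: np.ndarray,
    grf_ap: np.ndarray,
    grf_v: np.ndarray,
    speed: float,
    params: ModelParams,
    gait: str,
    trunk_sway_rad: float = 0.035,
    trunk_lean_rad: float = 0.0,
    hip_height_factor: float = 0.97,
) -> Motion:
    """Approximate full-body motion from right-leg angles and GRFs.

    The left leg repeats the right with a half-cycle shift (symmetric gait).
    The trunk translation is made dynamically consistent with the ground
    reactions: the centre-of-mass acceleration implied by the total GRF is
    integrated spectrally, which yields the familiar sinusoidal pelvis
    excursions without requiring a foot-ground constraint.  Trunk pitch is a
    small step-frequency oscillation around a configurable lean.

    This reconstruction is deliberately approximate (no foot-contact
    enforcement); the optimal-control path produces dynamically consistent
    motions instead.
    """
    T = cycle_duration(speed, gait)
    g = params.gravity

    ap_l = np.roll(grf_ap, N_POINTS // 2)
    v_l = np.roll(grf_v, N_POINTS // 2)
    # COM acceleration implied by total GRF (BW units); means removed so the
    # velocity fluctuation is periodic (steady gait impulse balance)
    ax = g * (grf_ap + ap_l)
    ay = g * (grf_v + v_l - 1.0)
    ax -= ax.mean()
    ay -= ay.mean()
    vx = fft_integrate(ax, T)
    vy = fft_integrate(ay, T)
    px = fft_integrate(vx, T)
    py = fft_integrate(vy, T)

    t = np.arange(N_POINTS) / N_POINTS * T
    tau = np.arange(N_POINTS) / N_POINTS

    q = np.zeros((N_POINTS, NQ))
    q[:, 0] = speed * t + px
    q[:, 1] = hip_height_factor * params.leg_length + py
    q[:, 2] = trunk_lean_rad + trunk_sway_rad * np.sin(4 * np.pi * tau)
    q[:, 3], q[:, 4], q[:, 5] = hip, knee, ankle
    q[:, 6] = np.roll(hip, N_POINTS // 2)
    q[:, 7] = np.roll(knee, N_POINTS // 2)
    q[:, 8] = np.roll(ankle, N_POINTS // 2)
    return Motion(q=q, duration=T, speed=float(speed), params=params)


def _neutral_com_offset(params: ModelParams) -> np.ndarray:
    kin = BodyKinematics(np.zeros((1, NQ)), params=params)
    M = params.total_mass
    com = sum(params.segments[s].mass * kin.com_p[s][0] for s in params.segments)
    return com / M


def inverse_dynamics_moments(
    motion: Motion, grf_ap: np.ndarray, grf_v: np.ndarray
) -> np.ndarray:
    """Net joint moments (100, 6) consistent with the motion and measured GRFs.

    The right-foot GRF (body-weight units) is applied at a centre of pressure
    that progresses linearly heel-to-toe over the stance phase; the left foot
    uses the half-cycle-shifted copy.  Joint moments are the generalized
    forces required to close the equations of motion (joint-angle rows); trunk
    residual forces are absorbed by the unactuated root and reflect the
    reconstruction approximation.
    """
    p = motion.params
    qd, qdd = motion.derivatives()
    kin = BodyKinematics(motion.q, qd, qdd, params=p)
    mg = p.total_mass * p.gravity

    Q_ext = np.zeros((N_POINTS, NQ))
    for side, (ap, vv) in (("r", (grf_ap, grf_v)), ("l", (np.roll(grf_ap, 50), np.roll(grf_v, 50)))):
        F = np.stack([ap, vv], axis=1) * mg
        cop = _cop_offsets(vv, p)
        pt, _, _ = kin.point_on(f"foot_{side}", cop)
        J = kin.point_jacobian(pt, f"foot_{side}")
        Q_ext += np.einsum("kij,ki->kj", J, F)

    # inertial generalized forces minus external = required actuation
    res = equations_of_motion_residual(
        kin, qdd, np.zeros((N_POINTS, 6)), np.zeros((N_POINTS, 4, 2)), p
    )
    tau = res[:, 3:9] - Q_ext[:, 3:9]
    # report net moments including the passive contribution the model would add
    return tau


def _cop_offsets(grf_v: np.ndarray, p: ModelParams) -> np.ndarray:
    """Foot-frame centre-of-pressure offsets progressing heel to toe in stance."""
    stance = grf_v > STANCE_THRESHOLD_BW
    n_st = max(int(stance[: np.argmin(stance) or len(stance)].sum()), 1)
    idx = np.arange(N_POINTS)
    s = np.clip(idx / n_st, 0.0, 1.0)
    heel = np.asarray(p.heel_offset)
    toe = np.asarray(p.toe_offset)
    return heel[None, :] + s[:, None] * (toe - heel)[None, :]
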