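"""Implicit multibody + muscle + contact dynamics of the planar model.

The full model state is

* muscle mode (58): q (9), qdot (9), muscle activations (16),
  contractile-element lengths (16), contact deformations (8)
* torque mode (26): q (9), qdot (9), contact deformations (8) -- six ideal
  joint torques replace the sixteen muscles for fast desk-scale work

``implicit_dynamics(x, xdot, u, p)`` returns a residual that is zero exactly
when (x, xdot, u) satisfy kinematic consistency, the equations of motion,
muscle activation/contraction dynamics, and the contact-deformation dynamics.
All terms are smooth in their arguments, as required by gradient-based
trajectory optimization.  Every function accepts a single state ``(nx,)`` or a
batch ``(K, nx)``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .contact import N_CONTACT_STATES, contact_forces_and_rates
from .kinematics import CHAIN, CONTACT_FOOT, BodyKinematics, zcross
from .muscles import (
    N_MUSCLES,
    MuscleArrays,
    activation_rate,
    fiber_residual,
    mt_length,
    muscle_joint_torques,
)
from .params import SEGMENT_NAMES, ModelParams

NQ = 9
NX_MUSCLE = 2 * NQ + 2 * N_MUSCLES + N_CONTACT_STATES  # 58
NX_TORQUE = 2 * NQ + N_CONTACT_STATES  # 26
NU_MUSCLE = N_MUSCLES
NU_TORQUE = 6

# angle coordinates (q[3:9]) in joint order [hip_r, knee_r, ankle_r, hip_l, ...]
JOINT_Q_IDX = (3, 4, 5, 6, 7, 8)


def state_dim(mode: str) -> int:
    return NX_MUSCLE if mode == "muscle" else NX_TORQUE


def control_dim(mode: str) -> int:
    return NU_MUSCLE if mode == "muscle" else NU_TORQUE


def split_state(x: np.ndarray, mode: str) -> dict:
    """View a (K, nx) state batch as named blocks."""
    out = {"q": x[:, 0:NQ], "qd": x[:, NQ : 2 * NQ]}
    if mode == "muscle":
        out["a"] = x[:, 18:34]
        out["lce"] = x[:, 34:50]
        out["d"] = x[:, 50:58]
    else:
        out["d"] = x[:, 18:26]
    return out


def _as_batch(x, dim, name):
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != dim:
        raise ValueError(f"{name} must have {dim} entries, got shape {x.shape}")
    return x, single


def passive_joint_moments(qj: np.ndarray, qdj: np.ndarray, p: ModelParams) -> np.ndarray:
    """Passive limit moments + light damping on the 6 joints (K, 6).

    Exactly zero inside the free range when the joint is at rest (C1 hinge
    quadratics outside the range).
    """
    lo = np.array([r[0] for r in p.joint_free_range] * 2)
    hi = np.array([r[1] for r in p.joint_free_range] * 2)
    over = np.maximum(qj - hi[None, :], 0.0)
    under = np.maximum(lo[None, :] - qj, 0.0)
    return -p.passive_stiffness * over**2 + p.passive_stiffness * under**2 - p.passive_damping * qdj


def equations_of_motion_residual(
    kin: BodyKinematics,
    qdd: np.ndarray,
    joint_torques: np.ndarray,
    contact_F: np.ndarray,
    p: ModelParams,
) -> np.ndarray:
    """Generalized-force residual (K, 9): inertial - applied; zero in balance."""
    K = kin.K
    g = np.array([0.0, -p.gravity])
    res = np.zeros((K, NQ))

    for name in SEGMENT_NAMES:
        seg = p.segments[name]
        f_inert = seg.mass * (kin.com_a[name] - g)  # (K, 2)
        res[:, 0:2] += f_inert
        for j in CHAIN[name]:
            lever = zcross(kin.com_p[name] - kin.pivot[j])
            res[:, j] += np.einsum("ki,ki->k", f_inert, lever) + seg.inertia * kin.alpha[name]

    for c, foot in enumerate(CONTACT_FOOT):
        F = contact_F[:, c]
        res[:, 0:2] -= F
        for j in CHAIN[foot]:
            lever = zcross(kin.contact_p[:, c] - kin.pivot[j])
            res[:, j] -= np.einsum("ki,ki->k", F, lever)

    res[:, 3:9] -= joint_torques
    return res


def _joint_torques(x_blocks, u, p: ModelParams, ma: MuscleArrays, mode: str) -> np.ndarray:
    qj = x_blocks["q"][:, 3:9]
    qdj = x_blocks["qd"][:, 3:9]
    tau = passive_joint_moments(qj, qdj, p)
    if mode == "muscle":
        l_mt = mt_length(qj, ma)
        tau = tau + muscle_joint_torques(l_mt, x_blocks["lce"], ma)
    else:
        tau = tau + u * p.torque_scale
    return tau


def implicit_dynamics_full(
    x: np.ndarray,
    xdot: np.ndarray,
    u: np.ndarray,
    p: ModelParams,
    mode: str = "muscle",
    ma: MuscleArrays | None = None,
) -> tuple:
    """Batched residual plus the contact forces used to form it.

    Returns ``(residual (K, nx), contact_F (K, 4, 2))``; the transcription
    reuses the contact forces for the GRF tracking channels so one kinematics
    evaluation serves both.
    """
    b = split_state(x, mode)
    bd = split_state(xdot, mode)
    ma = ma if ma is not None else (MuscleArrays(p) if mode == "muscle" else None)

    # accelerations: qdd is the qdot-block of xdot
    kin = BodyKinematics(b["q"], b["qd"], bd["qd"], params=p)

    contact_F, d_rate = contact_forces_and_rates(b["d"], kin.contact_p, kin.contact_v, p.contact)
    tau = _joint_torques(b, u, p, ma, mode)

    res = np.empty_like(x)
    res[:, 0:NQ] = bd["q"] - b["qd"]
    res[:, NQ : 2 * NQ] = equations_of_motion_residual(kin, bd["qd"], tau, contact_F, p)
    if mode == "muscle":
        qj = b["q"][:, 3:9]
        l_mt = mt_length(qj, ma)
        res[:, 18:34] = bd["a"] - activation_rate(b["a"], u, ma)
        res[:, 34:50] = fiber_residual(b["a"], b["lce"], bd["lce"], l_mt, ma)
        res[:, 50:58] = bd["d"] - d_rate
    else:
        res[:, 18:26] = bd["d"] - d_rate
    return res, contact_F


def implicit_dynamics(
    x: np.ndarray,
    xdot: np.ndarray,
    u: np.ndarray,
    p: ModelParams,
    mode: str = "muscle",
    _ma: MuscleArrays | None = None,
) -> np.ndarray:
    """Full implicit dynamics residual f(x, xdot, u) (same shape as x).

    Blocks, in state order: kinematic consistency (9), equations of motion
    (9, generalized forces in N / N m), muscle activation and fiber dynamics
    (16 + 16, muscle mode only), contact-deformation dynamics (8).
    """
    nx, nu = state_dim(mode), control_dim(mode)
    x, single = _as_batch(x, nx, "x")
    xdot, _ = _as_batch(xdot, nx, "xdot")
    u, _ = _as_batch(u, nu, "u")
    if not (x.shape == xdot.shape and x.shape[0] == u.shape[0]):
        raise ValueError("x, xdot, u batch sizes disagree")
    res, _ = implicit_dynamics_full(x, xdot, u, p, mode, _ma)
    return res[0] if single else res


def ground_reactions(x: np.ndarray, p: ModelParams, mode: str = "muscle") -> np.ndarray:
    """Per-foot ground reaction force [[Fx_r, Fy_r], [Fx_l, Fy_l]] in N.

    Sums the heel and toe contact-point forces of each foot; identically zero
    (up to the smooth tails) when no point is loaded.
    """
    x, single = _as_batch(x, state_dim(mode), "x")
    b = split_state(x, mode)
    kin = BodyKinematics(b["q"], b["qd"], params=p)
    F, _ = contact_forces_and_rates(b["d"], kin.contact_p, kin.contact_v, p.contact)
    out = np.stack([F[:, 0] + F[:, 1], F[:, 2] + F[:, 3]], axis=1)  # (K, 2, 2)
    return out[0] if single else out


def joint_moments(
    x: np.ndarray, p: ModelParams, u: np.ndarray | None = None, mode: str = "muscle"
) -> np.ndarray:
    """Net sagittal joint moments (N m), order [hip_r, knee_r, ankle_r, hip_l, ...].

    Muscle mode: sum of tendon force x moment arm over crossing muscles plus
    the passive joint moment.  Torque mode: the applied ideal torque plus the
    passive moment (requires ``u``).
    """
    x, single = _as_batch(x, state_dim(mode), "x")
    b = split_state(x, mode)
    if mode == "torque":
        if u is None:
            raise ValueError("torque mode requires the control vector u")
        u, _ = _as_batch(u, NU_TORQUE, "u")
        tau = _joint_torques(b, u, p, None, mode)
    else:
        tau = _joint_torques(b, None, p, MuscleArrays(p), mode)
    return tau[0] if single else tau


# ---------------------------------------------------------------------------
# mirroring (left-right leg swap)
# ---------------------------------------------------------------------------


def _mirror_perm(mode: str) -> np.ndarray:
    perm = np.arange(state_dim(mode))
    perm[3:6], perm[6:9] = np.arange(6, 9), np.arange(3, 6)
    perm[12:15], perm[15:18] = np.arange(15, 18), np.arange(12, 15)
    if mode == "muscle":
        perm[18:26], perm[26:34] = np.arange(26, 34), np.arange(18, 26)
        perm[34:42], perm[42:50] = np.arange(42, 50), np.arange(34, 42)
        perm[50:54], perm[54:58] = np.arange(54, 58), np.arange(50, 54)
    else:
        perm[18:22], perm[22:26] = np.arange(22, 26), np.arange(18, 22)
    return perm


def mirror_state(x: np.ndarray, mode: str = "muscle") -> np.ndarray:
    """Swap the right- and left-leg state blocks (trunk block unchanged)."""
    x, single = _as_batch(x, state_dim(mode), "x")
    out = x[:, _mirror_perm(mode)]
    return out[0] if single else out


def mirror_controls(u: np.ndarray, mode: str = "muscle") -> np.ndarray:
    u, single = _as_batch(u, control_dim(mode), "u")
    h = control_dim(mode) // 2
    out = np.concatenate([u[:, h:], u[:, :h]], axis=1)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# helpers used by tests and initial guesses
# ---------------------------------------------------------------------------


def forward_dynamics_torque(x: np.ndarray, u: np.ndarray, p: ModelParams) -> np.ndarray:
    """Explicit xdot for the torque-driven model (EOM solved for qdd)."""
    x = np.asarray(x, dtype=float)
    xdot = np.zeros_like(x)
    xdot[0:NQ] = x[NQ : 2 * NQ]

    def eom(qdd):
        xd = xdot.copy()
        xd[NQ : 2 * NQ] = qdd
        return implicit_dynamics(x, xd, u, p, mode="torque")[NQ : 2 * NQ]

    b0 = eom(np.zeros(NQ))
    A = np.empty((NQ, NQ))
    for i in range(NQ):
        e = np.zeros(NQ)
        e[i] = 1.0
        A[:, i] = eom(e) - b0
    qdd = np.linalg.solve(A, -b0)
    xdot[NQ : 2 * NQ] = qdd

    # contact rates are explicit
    b = split_state(np.atleast_2d(x), "torque")
    kin = BodyKinematics(b["q"], b["qd"], params=p)
    _, d_rate = contact_forces_and_rates(b["d"], kin.contact_p, kin.contact_v, p.contact)
    xdot[18:26] = d_rate[0]
    return xdot


def mechanical_energy(x: np.ndarray, p: ModelParams, mode: str = "torque") -> float:
    """Total mechanical energy of the rigid bodies (J)."""
    x, _ = _as_batch(x, state_dim(mode), "x")
    b = split_state(x, mode)
    kin = BodyKinematics(b["q"], b["qd"], params=p)
    E = np.zeros(x.shape[0])
    for name in SEGMENT_NAMES:
        seg = p.segments[name]
        v2 = np.einsum("ki,ki->k", kin.com_v[name], kin.com_v[name])
        E += 0.5 * seg.mass * v2 + 0.5 * seg.inertia * kin.omega[name] ** 2
        E += seg.mass * p.gravity * kin.com_p[name][:, 1]
    return E if len(E) > 1 else float(E[0])


def standing_state(p: ModelParams, mode: str = "torque") -> np.ndarray:
    """Static upright state in equilibrium with gravity (feet flat on ground).

    The hip height is solved so the summed vertical ground reaction equals
    body weight, with the contact deformations at their steady-state values.
    """
    from .contact import smooth_pos

    mg = p.total_mass * p.gravity
    stand_h = p.leg_length  # hip height with zero penetration

    def fy_balance(y):
        pen = smooth_pos(-(y - stand_h), p.contact.pen_smooth)
        return 4.0 * p.contact.k_normal * pen - mg

    y = brentq(fy_balance, stand_h - 0.05, stand_h + 0.05)
    pen = smooth_pos(-(y - stand_h), p.contact.pen_smooth)

    x = np.zeros(state_dim(mode))
    x[1] = y
    d0 = 18 if mode == "torque" else 50
    x[d0 + 1 : d0 + 8 : 2] = pen  # vertical deformations at steady state
    if mode == "muscle":
        ma = MuscleArrays(p)
        x[34:50] = ma.lopt  # fibers at optimal length
    return x
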