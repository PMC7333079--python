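"""Hill-type muscle model with smooth force-length/velocity curves.

Sixteen muscles (eight per leg) act through constant moment arms.  The
musculotendon length is an affine function of the joint angles of the
muscle's own side, l_mt = l_ref - sum_j r_j q_j with l_ref the length in the
neutral pose.  Fiber dynamics are formulated implicitly as a force equilibrium
between a stiff (smoothly engaged) series tendon and the contractile +
parallel-elastic forces; activation follows first-order dynamics with
separate activation/deactivation time constants blended smoothly.

All functions are vectorized: joint-angle inputs have shape (K, 6) ordered
[hip_r, knee_r, ankle_r, hip_l, knee_l, ankle_l]; muscle state arrays have
shape (K, 16) with right-leg muscles first.
"""

from __future__ import annotations

import numpy as np

from .contact import smooth_pos
from .params import ModelParams

N_MUSCLES = 16

TENDON_STRAIN_REF = 0.04  # tendon strain at maximum isometric force
FL_WIDTH = 0.45  # active force-length Gaussian width (normalized length)
PE_STRAIN_REF = 0.5  # passive force = fmax at 1 + PE_STRAIN_REF optimal lengths
VMAX_FACTOR = 10.0  # maximum shortening velocity (optimal lengths / s)
_EPS = 1e-4


class MuscleArrays:
    """Per-muscle parameter vectors extracted once from ModelParams."""

    def __init__(self, p: ModelParams):
        ms = p.muscles
        if len(ms) != N_MUSCLES:
            raise ValueError(f"expected {N_MUSCLES} muscles, got {len(ms)}")
        self.fmax = np.array([m.fmax for m in ms])
        self.lopt = np.array([m.lopt for m in ms])
        self.lslack = np.array([m.lslack for m in ms])
        self.tau_act = np.array([m.tau_act for m in ms])
        self.tau_deact = np.array([m.tau_deact for m in ms])
        # (16, 6) moment-arm matrix onto [hip_r, knee_r, ankle_r, hip_l, knee_l, ankle_l]
        R = np.zeros((N_MUSCLES, 6))
        for i, m in enumerate(ms):
            col = 0 if m.side == "r" else 3
            R[i, col : col + 3] = m.arms
        self.arms = R
        self.l_ref = self.lslack + self.lopt  # musculotendon length at q = 0


def mt_length(q_joints: np.ndarray, ma: MuscleArrays) -> np.ndarray:
    """Musculotendon lengths (K, 16): l_ref - R q (so dl/dq_j = -r_j)."""
    return ma.l_ref[None, :] - q_joints @ ma.arms.T


def tendon_force(l_mt: np.ndarray, l_ce: np.ndarray, ma: MuscleArrays) -> np.ndarray:
    """Series tendon force (K, 16); zero (smoothly) when slack."""
    strain = (l_mt - l_ce - ma.lslack[None, :]) / ma.lslack[None, :]
    return ma.fmax[None, :] * smooth_pos(strain, 1e-3) / TENDON_STRAIN_REF


def fiber_residual(
    a: np.ndarray, l_ce: np.ndarray, l_ce_dot: np.ndarray, l_mt: np.ndarray, ma: MuscleArrays
) -> np.ndarray:
    """Implicit contractile dynamics: tendon/fiber force equilibrium, /fmax."""
    lnorm = l_ce / ma.lopt[None, :]
    fl = np.exp(-(((lnorm - 1.0) / FL_WIDTH) ** 2))
    v = l_ce_dot / (VMAX_FACTOR * ma.lopt[None, :])
    fv = 1.0 + 0.5 * np.tanh(4.0 * v) + 0.5 * np.tanh(2.0 * v)
    fpe = (smooth_pos(lnorm - 1.0, _EPS) / PE_STRAIN_REF) ** 2
    f_fiber = ma.fmax[None, :] * (a * fl * fv + fpe)
    return (tendon_force(l_mt, l_ce, ma) - f_fiber) / ma.fmax[None, :]


def activation_rate(a: np.ndarray, u: np.ndarray, ma: MuscleArrays) -> np.ndarray:
    """First-order activation dynamics with smooth act/deact blending."""
    s = 0.5 + 0.5 * np.tanh((u - a) / 0.01)
    inv_tau = s / ma.tau_act[None, :] + (1.0 - s) / ma.tau_deact[None, :]
    return (u - a) * inv_tau


def muscle_joint_torques(l_mt: np.ndarray, l_ce: np.ndarray, ma: MuscleArrays) -> np.ndarray:
    """Net muscle torques on the 6 joints (K, 6): sum_m F_t,m * r_m,j."""
    return tendon_force(l_mt, l_ce, ma) @ ma.arms
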