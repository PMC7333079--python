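"""Smoothed compliant ground contact with heel/toe points per foot.

Each contact point carries two first-order deformation states (horizontal,
vertical).  The vertical deformation tracks the smoothed penetration depth and
drives a spring force with bounded velocity damping, so the vertical ground
reaction is non-negative by construction.  The horizontal deformation is a
shear spring that charges with the contact-point velocity while loaded and
relaxes out of contact; the shear force is saturated inside the friction cone
(|Fx| <= mu * Fy always).
"""

from __future__ import annotations

import numpy as np

from .params import ContactParams

# per contact point, the deformation state order is (dx, dy)
N_CONTACT_STATES = 8  # 4 points x 2


def smooth_pos(z: np.ndarray, eps: float) -> np.ndarray:
    """Smooth positive part: 0.5 * (z + sqrt(z^2 + eps^2)); C-infinity, >= 0."""
    return 0.5 * (z + np.sqrt(z * z + eps * eps))


def contact_forces_and_rates(
    d: np.ndarray, p_c: np.ndarray, v_c: np.ndarray, cp: ContactParams
) -> tuple:
    """Contact forces and deformation-state rates.

    Parameters
    ----------
    d : (K, 8) deformation states [heel_r (dx, dy), toe_r, heel_l, toe_l]
    p_c, v_c : (K, 4, 2) contact point world positions / velocities
    cp : contact parameters

    Returns
    -------
    F : (K, 4, 2) world-frame force on each contact point
    d_rate : (K, 8) time derivatives of the deformation states
    """
    d = np.atleast_2d(d)
    dx = d[:, 0::2]  # (K, 4)
    dy = d[:, 1::2]
    y_c = p_c[..., 1]
    vx_c = v_c[..., 0]
    vy_c = v_c[..., 1]

    pen = smooth_pos(-y_c, cp.pen_smooth)
    dy_rate = (pen - dy) / cp.tau_contact

    damp = 1.0 + cp.damping_ratio * (-vy_c) / np.sqrt(vy_c**2 + cp.v_damp**2)
    fy = cp.k_normal * dy * damp  # >= 0 whenever dy >= 0 (damp in (1-zeta, 1+zeta))

    load = pen / (pen + cp.pen_smooth)  # smooth 0..1 contact weight
    dx_rate = load * vx_c - (1.0 - load) * dx / cp.tau_release
    cone = cp.mu * fy
    fx = -cone * np.tanh(cp.k_shear * dx / (cone + cp.force_eps))

    F = np.stack([fx, fy], axis=-1)
    d_rate = np.empty_like(d)
    d_rate[:, 0::2] = dx_rate
    d_rate[:, 1::2] = dy_rate
    return F, d_rate
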