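"""Planar forward kinematics of the 7-segment chain, vectorized over time.

All public functions take generalized coordinates ``q`` (and optionally
velocities/accelerations) with shape ``(K, 9)`` where K is the number of time
samples.  Segment absolute angles are counterclockwise-positive and add along
the chain; see :mod:`gaitaug.msk.params` for the coordinate conventions.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, SEGMENT_NAMES

# generalized-coordinate indices
IX, IY, ITRUNK = 0, 1, 2
IHIP_R, IKNEE_R, IANKLE_R = 3, 4, 5
IHIP_L, IKNEE_L, IANKLE_L = 6, 7, 8

# which angle coordinates contribute to each segment's absolute angle
CHAIN = {
    "trunk": (ITRUNK,),
    "thigh_r": (ITRUNK, IHIP_R),
    "shank_r": (ITRUNK, IHIP_R, IKNEE_R),
    "foot_r": (ITRUNK, IHIP_R, IKNEE_R, IANKLE_R),
    "thigh_l": (ITRUNK, IHIP_L),
    "shank_l": (ITRUNK, IHIP_L, IKNEE_L),
    "foot_l": (ITRUNK, IHIP_L, IKNEE_L, IANKLE_L),
}

# neutral (q = 0) axis of each segment: trunk points up, legs point down,
# feet point anterior
NEUTRAL_AXIS = {
    "trunk": (0.0, 1.0),
    "thigh_r": (0.0, -1.0),
    "shank_r": (0.0, -1.0),
    "foot_r": (1.0, 0.0),
    "thigh_l": (0.0, -1.0),
    "shank_l": (0.0, -1.0),
    "foot_l": (1.0, 0.0),
}

CONTACT_POINT_NAMES = ("heel_r", "toe_r", "heel_l", "toe_l")
CONTACT_FOOT = ("foot_r", "foot_r", "foot_l", "foot_l")


def rot_apply(phi: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Apply the CCW rotation R(phi) to 2-vector(s) c. phi: (K,), c: (2,) or (K,2)."""
    cphi, sphi = np.cos(phi), np.sin(phi)
    cx, cy = (c[..., 0], c[..., 1]) if np.ndim(c) > 1 else (c[0], c[1])
    return np.stack([cx * cphi - cy * sphi, cx * sphi + cy * cphi], axis=-1)


def zcross(v: np.ndarray) -> np.ndarray:
    """Planar cross product z-hat x v (rotates v by +90 degrees)."""
    return np.stack([-v[..., 1], v[..., 0]], axis=-1)


class BodyKinematics:
    """Positions/velocities/accelerations of joints, COMs, and contact points.

    Computed once per (q, qd, qdd) batch and reused by dynamics, ground
    reactions, and the virtual sensor model.  When ``qd``/``qdd`` are None the
    corresponding derivative quantities are zero.
    """

    def __init__(self, q: np.ndarray, qd=None, qdd=None, *, params: ModelParams):
        q = np.atleast_2d(np.asarray(q, dtype=float))
        K = q.shape[0]
        if q.shape[1] != 9:
            raise ValueError(f"q must have 9 coordinates, got shape {q.shape}")
        qd = np.zeros_like(q) if qd is None else np.atleast_2d(np.asarray(qd, dtype=float))
        qdd = np.zeros_like(q) if qdd is None else np.atleast_2d(np.asarray(qdd, dtype=float))
        self.q, self.qd, self.qdd = q, qd, qdd
        self.K = K
        self.params = params

        segs = params.segments
        # absolute segment angle, rate, acceleration
        self.phi, self.omega, self.alpha = {}, {}, {}
        for name in SEGMENT_NAMES:
            idx = list(CHAIN[name])
            self.phi[name] = q[:, idx].sum(axis=1)
            self.omega[name] = qd[:, idx].sum(axis=1)
            self.alpha[name] = qdd[:, idx].sum(axis=1)

        root_p = q[:, 0:2]
        root_v = qd[:, 0:2]
        root_a = qdd[:, 0:2]

        # proximal (origin) point of each segment
        self.origin_p = {"trunk": root_p, "thigh_r": root_p, "thigh_l": root_p}
        self.origin_v = {"trunk": root_v, "thigh_r": root_v, "thigh_l": root_v}
        self.origin_a = {"trunk": root_a, "thigh_r": root_a, "thigh_l": root_a}

        for side in ("r", "l"):
            th, sh = f"thigh_{side}", f"shank_{side}"
            knee = self.point_on(th, (0.0, -segs[th].length))
            self.origin_p[sh], self.origin_v[sh], self.origin_a[sh] = knee
            ankle = self.point_on(sh, (0.0, -segs[sh].length))
            self.origin_p[f"foot_{side}"], self.origin_v[f"foot_{side}"], self.origin_a[
                f"foot_{side}"
            ] = ankle

        # pivot point of each angle coordinate (for Jacobian columns)
        self.pivot = {
            ITRUNK: root_p,
            IHIP_R: root_p,
            IHIP_L: root_p,
            IKNEE_R: self.origin_p["shank_r"],
            IKNEE_L: self.origin_p["shank_l"],
            IANKLE_R: self.origin_p["foot_r"],
            IANKLE_L: self.origin_p["foot_l"],
        }

        # COM kinematics
        self.com_p, self.com_v, self.com_a = {}, {}, {}
        for name in SEGMENT_NAMES:
            if name == "trunk":
                c = (0.0, segs["trunk"].com_offset)
            elif name.startswith("foot"):
                c = params.foot_com_offset
            else:
                c = (0.0, -segs[name].com_offset)
            self.com_p[name], self.com_v[name], self.com_a[name] = self.point_on(name, c)

        # contact points (heel, toe per foot)
        self.contact_p = np.empty((K, 4, 2))
        self.contact_v = np.empty((K, 4, 2))
        for i, (cp, foot) in enumerate(zip(CONTACT_POINT_NAMES, CONTACT_FOOT)):
            off = params.heel_offset if cp.startswith("heel") else params.toe_offset
            p, v, _ = self.point_on(foot, off)
            self.contact_p[:, i], self.contact_v[:, i] = p, v

    def point_on(self, segment: str, offset) -> tuple:
        """Kinematics of a point fixed on a segment at ``offset`` (segment frame)."""
        phi, om, al = self.phi[segment], self.omega[segment], self.alpha[segment]
        w = rot_apply(phi, np.asarray(offset, dtype=float))
        zw = zcross(w)
        p = self.origin_p[segment] + w
        v = self.origin_v[segment] + om[:, None] * zw
        a = self.origin_a[segment] + al[:, None] * zw - (om**2)[:, None] * w
        return p, v, a

    def point_jacobian(self, p: np.ndarray, segment: str) -> np.ndarray:
        """d p / d q for a world point p (K,2) fixed on ``segment`` -> (K, 2, 9)."""
        J = np.zeros((self.K, 2, 9))
        J[:, 0, IX] = 1.0
        J[:, 1, IY] = 1.0
        for j in CHAIN[segment]:
            J[:, :, j] = zcross(p - self.pivot[j])
        return J
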