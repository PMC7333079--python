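"""Per-subject multivariate-normal gait-cycle distributions and sampling.

Each walking/running cycle of a subject is flattened to a 501-vector: the 100
time points of the right hip, knee, and ankle angles (rad), the A-P and
vertical GRFs (body-weight units), and the cycle speed (m/s).  A multivariate
normal is fitted per subject and gait; random draws provide tracking targets
for the optimal-control simulations.

The 501-entry layout below is the single source of truth; assembling,
disassembling, and target splitting all index through it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cycles import N_POINTS, GaitCycle

CYCLE_VECTOR_DIM = 5 * N_POINTS + 1  # 501

#: ordered channel blocks of the cycle vector
LAYOUT = {
    "hip_angle": slice(0, 100),
    "knee_angle": slice(100, 200),
    "ankle_angle": slice(200, 300),
    "grf_ap": slice(300, 400),
    "grf_v": slice(400, 500),
}
SPEED_INDEX = 500

#: variance floor scale per channel class (units of the stored channel)
CHANNEL_SCALE = {
    "hip_angle": 0.5,
    "knee_angle": 0.5,
    "ankle_angle": 0.5,
    "grf_ap": 1.0,
    "grf_v": 1.0,
}
VAR_FLOOR_FACTOR = 1e-4

#: tracked channels of the half-cycle problem, right leg then left leg
TRACKED_CHANNELS = [
    ("hip_angle", "r"),
    ("knee_angle", "r"),
    ("ankle_angle", "r"),
    ("grf_ap", "r"),
    ("grf_v", "r"),
    ("hip_angle", "l"),
    ("knee_angle", "l"),
    ("ankle_angle", "l"),
    ("grf_ap", "l"),
    ("grf_v", "l"),
]

SPEED_RANGE = (0.5, 6.0)  # sampled speeds are clipped here (m/s)
MIN_PEAK_VGRF = 0.5  # samples with max vertical GRF below this (BW) are redrawn


def assemble_cycle_vector(cycle: GaitCycle) -> np.ndarray:
    """Concatenate a cycle's tracked channels and speed into the 501-vector."""
    z = np.empty(CYCLE_VECTOR_DIM)
    for name, sl in LAYOUT.items():
        arr = getattr(cycle, name if name.endswith("angle") else name)
        if arr is None:
            raise ValueError(f"cycle is missing channel {name}")
        z[sl] = arr
    z[SPEED_INDEX] = cycle.speed
    return z


def disassemble_cycle_vector(z: np.ndarray) -> dict:
    """Inverse of :func:`assemble_cycle_vector`: named channels + speed."""
    z = np.asarray(z, dtype=float)
    if z.shape != (CYCLE_VECTOR_DIM,):
        raise ValueError(f"cycle vector must have {CYCLE_VECTOR_DIM} entries, got {z.shape}")
    out = {name: z[sl].copy() for name, sl in LAYOUT.items()}
    out["speed"] = float(z[SPEED_INDEX])
    return out


@dataclass
class GaitDistribution:
    """Fitted N(mu, Sigma) over cycle vectors of one subject and gait."""

    mean: np.ndarray  # (501,)
    cov: np.ndarray  # (501, 501), symmetric PSD after eigenvalue clipping
    subject_id: str
    gait: str
    n_cycles: int
    # eigenfactorization used for degenerate-subspace sampling
    _eigvals: np.ndarray = field(default=None, repr=False)
    _eigvecs: np.ndarray = field(default=None, repr=False)

    def factor(self):
        if self._eigvals is None:
            w, V = np.linalg.eigh(self.cov)
            self._eigvals = np.clip(w, 0.0, None)
            self._eigvecs = V
        return self._eigvals, self._eigvecs


def fit_distribution(vectors: np.ndarray, subject_id: str, gait: str) -> GaitDistribution:
    """Sample mean and unbiased sample covariance of stacked cycle vectors.

    With ~30 cycles in 501 dimensions the covariance is rank-deficient; small
    negative eigenvalues from roundoff are clipped to zero so sampling stays in
    the support subspace.
    """
    Z = np.atleast_2d(np.asarray(vectors, dtype=float))
    if Z.shape[0] < 2:
        raise ValueError(f"need at least 2 cycles to fit a distribution, got {Z.shape[0]}")
    if Z.shape[1] != CYCLE_VECTOR_DIM:
        raise ValueError(f"cycle vectors must have {CYCLE_VECTOR_DIM} entries")
    mu = Z.mean(axis=0)
    S = np.cov(Z, rowvar=False, ddof=1)
    S = 0.5 * (S + S.T)
    return GaitDistribution(mean=mu, cov=S, subject_id=subject_id, gait=gait, n_cycles=Z.shape[0])


def draw_samples(
    dist: GaitDistribution, n: int, seed: int, reject: bool = True
) -> tuple[np.ndarray, int]:
    """Draw n cycle vectors from the fitted distribution.

    Sampling goes through the eigenfactorization (rank-deficient covariances
    produce samples confined to the support affine subspace).  Speeds are
    clipped to a physical range; samples whose peak vertical GRF is below
    ``MIN_PEAK_VGRF`` body weights are rejected and redrawn (multivariate
    normal tails occasionally produce untrackable targets).

    Returns (samples (n, 501), number of rejected draws).
    """
    rng = np.random.default_rng(seed)
    w, V = dist.factor()
    L = V * np.sqrt(w)[None, :]

    out = np.empty((n, CYCLE_VECTOR_DIM))
    filled, rejected = 0, 0
    while filled < n:
        m = n - filled
        Z = dist.mean[None, :] + rng.standard_normal((m, CYCLE_VECTOR_DIM)) @ L.T
        Z[:, SPEED_INDEX] = np.clip(Z[:, SPEED_INDEX], *SPEED_RANGE)
        if reject:
            ok = Z[:, LAYOUT["grf_v"]].max(axis=1) >= MIN_PEAK_VGRF
        else:
            ok = np.ones(m, dtype=bool)
        k = int(ok.sum())
        out[filled : filled + k] = Z[ok]
        filled += k
        rejected += m - k
        if rejected > 100 * n + 100:
            raise RuntimeError("sample rejection rate implausibly high; check the fit")
    return out, rejected


@dataclass
class TrackingTargets:
    """Half-cycle tracking targets for the optimal control problem.

    ``mean``/``var`` have shape (10, N): the right-leg targets are the first
    half of each sampled channel, the left-leg targets the second half, both
    resampled to the N collocation nodes.  ``var`` is floored so the tracking
    weight 1/sigma^2 stays finite.
    """

    mean: np.ndarray  # (10, N)
    var: np.ndarray  # (10, N)
    speed: float  # m/s
    n_nodes: int


def split_tracking(z: np.ndarray, dist: GaitDistribution, n_nodes: int = 50) -> TrackingTargets:
    """Split a sampled 501-vector into right/left half-cycle tracking targets.

    Node k (k = 1..N) sits at phase k/N of the half cycle; target values and
    the matching diagonal entries of the fitted covariance are linearly
    interpolated from the 100-point cycle (periodic wrap at the full cycle).
    """
    z = np.asarray(z, dtype=float)
    var_diag = np.diag(dist.cov)
    # fractional cycle positions of nodes 1..N for the right (first) half
    pos_r = np.arange(1, n_nodes + 1) * (50.0 / n_nodes)
    pos_l = pos_r + 50.0
    grid = np.arange(N_POINTS + 1)

    mean = np.empty((10, n_nodes))
    var = np.empty((10, n_nodes))
    for j, (name, side) in enumerate(TRACKED_CHANNELS):
        block = z[LAYOUT[name]]
        vblock = var_diag[LAYOUT[name]]
        ext = np.append(block, block[0])  # periodic wrap
        vext = np.append(vblock, vblock[0])
        pos = pos_r if side == "r" else pos_l
        pos = np.mod(pos, N_POINTS)
        # restore the exact endpoint when mod maps 100 -> 0 (same value by wrap)
        mean[j] = np.interp(pos, grid, ext)
        var[j] = np.interp(pos, grid, vext)
        floor = VAR_FLOOR_FACTOR * CHANNEL_SCALE[name] ** 2
        var[j] = np.maximum(var[j], floor)

    return TrackingTargets(
        mean=mean, var=var, speed=float(np.clip(z[SPEED_INDEX], *SPEED_RANGE)), n_nodes=n_nodes
    )


def save_distribution(path, dist: GaitDistribution) -> None:
    np.savez_compressed(
        path,
        mean=dist.mean,
        cov=dist.cov,
        subject_id=dist.subject_id,
        gait=dist.gait,
        n_cycles=dist.n_cycles,
    )


def load_distribution(path) -> GaitDistribution:
    d = np.load(path, allow_pickle=False)
    return GaitDistribution(
        mean=d["mean"],
        cov=d["cov"],
        subject_id=str(d["subject_id"]),
        gait=str(d["gait"]),
        n_cycles=int(d["n_cycles"]),
    )
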