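"""Half-cycle tracking optimal control by direct collocation.

The model is driven to follow randomly sampled joint-angle and GRF targets
over a half gait cycle while minimizing effort, subject to the implicit
dynamics discretized with the Backward Euler rule at N nodes and a left-right
symmetry closure: the initial state equals the mirrored final state shifted
backwards by the forward travel v*T.

Transcription
-------------
Decision variables are the states and controls at nodes 1..N plus the free
half-cycle duration T (N*(nx+nu)+1 variables).  The node-0 state is not a
variable: it is expressed through the symmetry map
``x_0 = mirror(x_N) - v*T*e_x``, so the node-1 Backward-Euler block (nx rows)
is the periodicity/symmetry constraint of the problem.  The objective is

    J = (1/N) sum_k [ (1/10) sum_j (s_jk - m_jk)^2 / sigma_jk^2
                      + (W_effort/nu) sum_i u_ik^2 ]  +  W_reg * J_reg

with J_reg the time-averaged sum of squared finite-difference derivatives of
all states and controls, each scaled by its bound range.  The resulting NLP is
solved with a trust-region interior-point / SQP method using sparse
constraint Jacobians evaluated by structure-exploiting (colored) finite
differences: the Backward-Euler blocks couple only neighbouring nodes, so two
perturbation passes per variable index suffice regardless of N.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, NonlinearConstraint, minimize

from .cycles import N_POINTS, GaitCycle
from .motion import Motion, cycle_duration
from .msk import dynamics as dyn
from .msk.dynamics import NQ
from .msk.kinematics import BodyKinematics
from .msk.muscles import MuscleArrays
from .msk.params import ModelParams
from .sampler import TrackingTargets

_FD_EPS = 1e-7


@dataclass
class OCPWeights:
    """Objective weights: tracking is implicit (weight 1), effort and regularization."""

    effort: float = 0.1
    reg: float = 1e-5


@dataclass
class CollocationGrid:
    """Backward-Euler grid: N nodes over the free half-cycle duration T."""

    n_nodes: int = 50
    t_bounds: tuple = (0.2, 0.9)

    def __post_init__(self):
        if self.n_nodes < 2 or self.n_nodes % 2:
            raise ValueError("n_nodes must be an even integer >= 2")


@dataclass
class OCPResult:
    states: np.ndarray  # (N, nx)
    controls: np.ndarray  # (N, nu)
    duration: float  # half-cycle duration T (s)
    objective: float
    tracking_term: float
    effort_term: float
    reg_term: float
    status: str  # 'converged' | 'failed'
    n_iter: int
    max_residual: float  # scaled dynamics+symmetry residual, max over nodes
    mode: str
    speed: float
    message: str = ""


def state_bounds(p: ModelParams, mode: str) -> tuple:
    """Generous physiological state bounds (configuration, not ground truth)."""
    lb_q = np.array([-5.0, 0.4, -1.0, -1.2, -2.8, -1.3, -1.2, -2.8, -1.3])
    ub_q = np.array([10.0, 1.3 * p.leg_length, 1.0, 2.2, 0.3, 1.3, 2.2, 0.3, 1.3])
    lb_qd = np.concatenate([[-10.0, -10.0], np.full(7, -30.0)])
    ub_qd = -lb_qd
    lb_d = np.tile([-0.2, 0.0], 4)
    ub_d = np.tile([0.2, 0.2], 4)
    if mode == "muscle":
        ma = MuscleArrays(p)
        lb = np.concatenate([lb_q, lb_qd, np.zeros(16), 0.2 * ma.lopt, lb_d])
        ub = np.concatenate([ub_q, ub_qd, np.full(16, 5.0), 2.5 * ma.lopt, ub_d])
    else:
        lb = np.concatenate([lb_q, lb_qd, lb_d])
        ub = np.concatenate([ub_q, ub_qd, ub_d])
    return lb, ub


def control_bounds(mode: str) -> tuple:
    if mode == "muscle":
        return np.zeros(16), np.full(16, 5.0)
    return np.full(6, -5.0), np.full(6, 5.0)


class TrackingNLP:
    """The transcribed NLP for one tracking problem (see module docstring)."""

    def __init__(
        self,
        targets: TrackingTargets,
        model: ModelParams,
        grid: CollocationGrid,
        weights: OCPWeights,
        mode: str = "muscle",
    ):
        if targets.mean.shape != (10, grid.n_nodes):
            raise ValueError(
                f"targets have {targets.mean.shape[1]} nodes but the grid has {grid.n_nodes}"
            )
        self.targets = targets
        self.model = model
        self.grid = grid
        self.weights = weights
        self.mode = mode
        self.nx = dyn.state_dim(mode)
        self.nu = dyn.control_dim(mode)
        self.N = grid.n_nodes
        self.n_decision = self.N * (self.nx + self.nu) + 1
        self.n_constraints = self.N * self.nx
        self.n_symmetry_rows = self.nx  # the node-1 closure block

        self.x_lb, self.x_ub = state_bounds(model, mode)
        self.u_lb, self.u_ub = control_bounds(mode)
        self._ma = MuscleArrays(model) if mode == "muscle" else None
        self._mirror_perm = dyn._mirror_perm(mode)
        mg = model.total_mass * model.gravity
        # residual row scaling: kinematic (rad/s, m/s), forces (N), torques (N m),
        # muscle (1/s, normalized), contact (m/s)
        scale = np.empty(self.nx)
        scale[0:NQ] = 10.0
        scale[NQ : NQ + 2] = mg
        scale[NQ + 2 : 2 * NQ] = 0.1 * mg * model.body_height
        if mode == "muscle":
            scale[18:34] = 50.0
            scale[34:50] = 1.0
            scale[50:58] = 1.0
        else:
            scale[18:26] = 1.0
        self._res_scale = scale
        # J_reg per-variable ranges
        self._x_range = np.maximum(self.x_ub - self.x_lb, 1e-6)
        self._u_range = np.maximum(self.u_ub - self.u_lb, 1e-6)
        self._coloring = self._build_coloring()
        # one colored-FD pass serves both the constraint Jacobian and the
        # objective gradient; cache it per decision vector
        self._deriv_cache: tuple | None = None
        self._value_cache: tuple | None = None

    # -- packing ------------------------------------------------------------
    def pack(self, X: np.ndarray, U: np.ndarray, T: float) -> np.ndarray:
        return np.concatenate([X.ravel(), U.ravel(), [T]])

    def unpack(self, w: np.ndarray) -> tuple:
        N, nx, nu = self.N, self.nx, self.nu
        X = w[: N * nx].reshape(N, nx)
        U = w[N * nx : N * (nx + nu)].reshape(N, nu)
        return X, U, float(w[-1])

    def bounds(self) -> Bounds:
        lb = np.concatenate(
            [np.tile(self.x_lb, self.N), np.tile(self.u_lb, self.N), [self.grid.t_bounds[0]]]
        )
        ub = np.concatenate(
            [np.tile(self.x_ub, self.N), np.tile(self.u_ub, self.N), [self.grid.t_bounds[1]]]
        )
        return Bounds(lb, ub)

    def x0_of(self, X: np.ndarray, T: float) -> np.ndarray:
        """Symmetry closure: initial state from the mirrored final state."""
        x0 = X[-1][self._mirror_perm].copy()
        x0[0] -= self.targets.speed * T
        return x0

    def u0_of(self, U: np.ndarray) -> np.ndarray:
        h = self.nu // 2
        return np.concatenate([U[-1, h:], U[-1, :h]])

    # -- model evaluation ---------------------------------------------------
    def _node_residuals(self, w: np.ndarray) -> np.ndarray:
        """Per-node residual block matrix (N, nb); one shared dynamics pass.

        Within each node block the rows are, in order:

        * tracking rows: (s_j - m_j) / (sigma_j sqrt(10 N))           (10)
        * effort rows: u_i sqrt(W_effort / (nu N))                     (nu)
        * regularization rows: (dv / range_v) sqrt(W_reg / (h T))      (nx + nu)
        * scaled dynamics rows (node 1 = symmetry closure)             (nx)

        The objective equals the sum of squares of the non-dynamics rows; the
        dynamics rows are the equality constraints.  This layout feeds both
        the general NLP interface and the penalty Gauss-Newton solver.
        """
        return self._node_residuals_many(w[None, :])[0]

    def _node_residuals_many(self, W: np.ndarray) -> np.ndarray:
        """Node residual blocks for M decision vectors at once -> (M, N, nb).

        All model evaluations are vectorized over nodes, so the colored-FD
        derivative sweep stacks its perturbed points into a single dynamics
        call through this path.
        """
        M = W.shape[0]
        N, nx, nu = self.N, self.nx, self.nu
        X = W[:, : N * nx].reshape(M, N, nx)
        U = W[:, N * nx : N * (nx + nu)].reshape(M, N, nu)
        T = W[:, -1]
        h = T / N

        x0 = X[:, -1, self._mirror_perm].copy()
        x0[:, 0] -= self.targets.speed * T
        Xprev = np.concatenate([x0[:, None, :], X[:, :-1]], axis=1)
        Xdot = (X - Xprev) / h[:, None, None]

        res, contact_F = dyn.implicit_dynamics_full(
            X.reshape(M * N, nx),
            Xdot.reshape(M * N, nx),
            U.reshape(M * N, nu),
            self.model,
            self.mode,
            ma=self._ma,
        )
        cons = (res / self._res_scale[None, :]).reshape(M, N, nx)
        contact_F = contact_F.reshape(M, N, 4, 2)

        mg = self.model.total_mass * self.model.gravity
        s = np.empty((M, 10, N))
        s[:, 0:3] = X[:, :, 3:6].transpose(0, 2, 1)  # right hip, knee, ankle angles
        s[:, 5:8] = X[:, :, 6:9].transpose(0, 2, 1)  # left
        s[:, 3] = (contact_F[:, :, 0, 0] + contact_F[:, :, 1, 0]) / mg  # right A-P (BW)
        s[:, 4] = (contact_F[:, :, 0, 1] + contact_F[:, :, 1, 1]) / mg  # right vertical
        s[:, 8] = (contact_F[:, :, 2, 0] + contact_F[:, :, 3, 0]) / mg
        s[:, 9] = (contact_F[:, :, 2, 1] + contact_F[:, :, 3, 1]) / mg

        u0 = np.concatenate([U[:, -1, nu // 2 :], U[:, -1, : nu // 2]], axis=1)
        Uprev = np.concatenate([u0[:, None, :], U[:, :-1]], axis=1)
        dx = (X - Xprev) / self._x_range[None, None, :]
        du = (U - Uprev) / self._u_range[None, None, :]

        out = np.empty((M, N, self.n_block_rows))
        track_w = np.sqrt(self.targets.var * 10 * N)
        out[:, :, 0:10] = ((s - self.targets.mean[None]) / track_w[None]).transpose(0, 2, 1)
        out[:, :, 10 : 10 + nu] = U * np.sqrt(self.weights.effort / (nu * N))
        r0 = 10 + nu
        w_reg = np.sqrt(self.weights.reg / (h * T))[:, None, None]
        out[:, :, r0 : r0 + nx] = dx * w_reg
        out[:, :, r0 + nx : r0 + nx + nu] = du * w_reg
        out[:, :, r0 + nx + nu :] = cons
        return out

    @property
    def n_block_rows(self) -> int:
        return 10 + self.nu + (self.nx + self.nu) + self.nx

    def _values(self, w: np.ndarray) -> np.ndarray:
        key = w.tobytes()
        if self._value_cache is None or self._value_cache[0] != key:
            self._value_cache = (key, self._node_residuals(w))
        return self._value_cache[1]

    def constraints(self, w: np.ndarray) -> np.ndarray:
        """Scaled Backward-Euler residuals at nodes 1..N (node 1 = symmetry closure)."""
        blocks = self._values(w)
        return blocks[:, -self.nx :].ravel()

    def objective_terms_vector(self, w: np.ndarray) -> np.ndarray:
        """Per-node objective contributions t_k (sums to the objective)."""
        blocks = self._values(w)
        return (blocks[:, : -self.nx] ** 2).sum(axis=1)

    def objective(self, w: np.ndarray) -> float:
        return float(self.objective_terms_vector(w).sum())

    def objective_terms(self, w: np.ndarray) -> dict:
        blocks = self._values(w)
        nu, nx = self.nu, self.nx
        track = float((blocks[:, 0:10] ** 2).sum())
        effort = float((blocks[:, 10 : 10 + nu] ** 2).sum())
        reg = float((blocks[:, 10 + nu : 10 + nu + nx + nu] ** 2).sum())
        return {"tracking": track, "effort": effort, "regularization": reg}

    # -- structured finite differences ---------------------------------------
    def _build_coloring(self) -> list:
        """Perturbation groups: (kind, index, parity) plus the dense T column.

        Backward-Euler block k depends on nodes k and k-1 (node 1 on node N
        through the symmetry map), so perturbing one variable index at all
        even nodes and, separately, at all odd nodes isolates every Jacobian
        entry.  N is even, which keeps node N and node 1 in different groups.
        """
        groups = []
        for j in range(self.nx):
            for par in (0, 1):
                groups.append(("x", j, par))
        for j in range(self.nu):
            for par in (0, 1):
                groups.append(("u", j, par))
        groups.append(("T", 0, 0))
        return groups

    def _group_columns(self, kind: str, j: int, par: int) -> np.ndarray:
        """Decision-vector indices of one perturbation group (nodes 1..N)."""
        nodes = np.arange(1, self.N + 1)
        nodes = nodes[nodes % 2 == par]
        if kind == "x":
            return (nodes - 1) * self.nx + j
        if kind == "u":
            return self.N * self.nx + (nodes - 1) * self.nu + j
        return np.array([self.n_decision - 1])

    def _derivatives(self, w: np.ndarray):
        """Sparse Jacobian of the full node-residual blocks, one colored sweep.

        Each perturbation group touches one variable index at all even (or all
        odd) nodes; a node block sees at most one perturbed node, so every
        Jacobian entry is identified.  N is even, keeping node N (which node 1
        sees through the symmetry map) and node 1 in different groups.
        """
        key = w.tobytes()
        if self._deriv_cache is not None and self._deriv_cache[0] == key:
            return self._deriv_cache[1]

        r0 = self._values(w)
        nx, nu, N, nb = self.nx, self.nu, self.N, self.n_block_rows
        rows_all, cols_all, vals_all = [], [], []

        # all perturbed points evaluated in one batched dynamics call
        n_groups = len(self._coloring)
        WP = np.tile(w, (n_groups, 1))
        eps_list = []
        for gi, (kind, j, par) in enumerate(self._coloring):
            cols = self._group_columns(kind, j, par)
            eps = _FD_EPS * (1.0 + np.abs(w[cols]))
            WP[gi, cols] += eps
            eps_list.append(eps)
        DR = self._node_residuals_many(WP) - r0[None]  # (n_groups, N, nb)

        for gi, (kind, j, par) in enumerate(self._coloring):
            cols = self._group_columns(kind, j, par)
            eps = eps_list[gi]
            dr = DR[gi]

            if kind == "T":
                flat = dr.ravel()
                (nz,) = np.nonzero(flat)
                rows_all.append(nz)
                cols_all.append(np.full(len(nz), cols[0]))
                vals_all.append(flat[nz] / eps[0])
                continue

            nodes = np.arange(1, N + 1)
            eps_by_node = dict(zip(nodes[nodes % 2 == par].tolist(), eps))
            for k in range(1, N + 1):
                # which perturbed node does block k see?
                if k % 2 == par:
                    src = k
                elif k >= 2 and (k - 1) % 2 == par:
                    src = k - 1
                elif k == 1 and N % 2 == par:
                    src = N
                else:
                    continue
                e = eps_by_node[src]
                col = (src - 1) * nx + j if kind == "x" else N * nx + (src - 1) * nu + j
                blk = dr[k - 1]
                (nz,) = np.nonzero(blk)
                if len(nz):
                    rows_all.append((k - 1) * nb + nz)
                    cols_all.append(np.full(len(nz), col))
                    vals_all.append(blk[nz] / e)

        J = sp.csr_matrix(
            (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(N * nb, self.n_decision),
        )
        self._deriv_cache = (key, J)
        return J

    def _row_split(self) -> tuple:
        """Boolean masks (objective rows, constraint rows) over the block layout."""
        nb, nx = self.n_block_rows, self.nx
        mask = np.zeros(self.N * nb, dtype=bool)
        for k in range(self.N):
            mask[k * nb + nb - nx : (k + 1) * nb] = True
        return ~mask, mask

    def constraint_jacobian(self, w: np.ndarray):
        obj_rows, con_rows = self._row_split()
        return self._derivatives(w)[con_rows]

    def objective_gradient(self, w: np.ndarray) -> np.ndarray:
        obj_rows, _ = self._row_split()
        J = self._derivatives(w)[obj_rows]
        r = self._values(w)[:, : -self.nx].ravel()
        return 2.0 * (J.T @ r)

    def max_scaled_residual(self, w: np.ndarray) -> float:
        return float(np.abs(self.constraints(w)).max())


def build_ocp(
    targets: TrackingTargets,
    model: ModelParams,
    grid: CollocationGrid | None = None,
    weights: OCPWeights | None = None,
    mode: str = "muscle",
) -> TrackingNLP:
    """Transcribe one tracking problem into a sparse NLP."""
    grid = grid or CollocationGrid(n_nodes=targets.n_nodes)
    weights = weights or OCPWeights()
    return TrackingNLP(targets, model, grid, weights, mode)


def _targets_to_full_cycle(tt: TrackingTargets) -> dict:
    """Right-leg 100-point channels implied by the half-cycle targets.

    The right-leg targets cover the first half of the cycle and the left-leg
    targets (being the mirrored continuation) its second half.
    """
    N = tt.n_nodes
    phases = np.concatenate([np.arange(1, N + 1) / (2 * N), 0.5 + np.arange(1, N + 1) / (2 * N)])
    grid = np.arange(N_POINTS) / N_POINTS
    names = ("hip", "knee", "ankle", "grf_ap", "grf_v")
    out = {}
    for i, name in enumerate(names):
        vals = np.concatenate([tt.mean[i], tt.mean[i + 5]])
        # periodic interpolation onto the 100-point grid
        out[name] = np.interp(grid, phases, vals, period=1.0)
    return out


def initial_guess(nlp: TrackingNLP) -> np.ndarray:
    """Initial guess from a kinematic reconstruction of the tracking targets.

    The target angle/GRF cycles are reconstructed into a full-body motion
    (trunk translation integrated from the target GRFs), which supplies the
    coordinates and velocities at the collocation nodes; contact deformations
    start at the values that reproduce the target vertical GRFs with a linear
    heel-to-toe load shift over stance.  Muscle activations start low with
    fibers at optimal length.
    """
    from .motion import reconstruct_motion

    tt, model, N = nlp.targets, nlp.model, nlp.N
    v = tt.speed
    gait = "walk" if v < 2.55 else "run"
    ch = _targets_to_full_cycle(tt)
    motion = reconstruct_motion(
        ch["hip"], ch["knee"], ch["ankle"], ch["grf_ap"], ch["grf_v"], v, model, gait
    )
    T0 = float(np.clip(motion.duration / 2, *nlp.grid.t_bounds))
    qd, _ = motion.derivatives()

    # sample the reconstruction at node k <-> cycle point 50 k / N (first half)
    pts = np.arange(1, N + 1) * (50.0 / N)
    grid = np.arange(N_POINTS + 1, dtype=float)
    shift = np.zeros(NQ)
    shift[0] = v * motion.duration
    q_ext = np.vstack([motion.q, motion.q[0] + shift])
    qd_ext = np.vstack([qd, qd[0]])

    X = np.zeros((N, nlp.nx))
    for j in range(NQ):
        X[:, j] = np.interp(pts, grid, q_ext[:, j])
        X[:, NQ + j] = np.interp(pts, grid, qd_ext[:, j])

    # contact deformations from the target GRFs: split each foot's vertical
    # load heel/toe by stance progress, invert the contact spring.  Over the
    # simulated half cycle the right leg goes through early stance and the
    # left leg (half a cycle ahead) finishes its own stance.
    d0 = 50 if nlp.mode == "muscle" else 18
    mg = model.total_mass * model.gravity
    k_n = model.contact.k_normal
    phase_half = np.arange(1, N + 1) / (2 * N)  # fraction of the full cycle
    v_r = np.maximum(tt.mean[4], 0.0) * mg
    v_l = np.maximum(tt.mean[9], 0.0) * mg
    loaded = ((v_r > 0.05 * mg).sum() + (v_l > 0.05 * mg).sum()) / (2 * N)
    stance_frac = float(np.clip(loaded, 0.2, 0.75))
    for base, vgrf, phase in ((0, v_r, phase_half), (4, v_l, phase_half + 0.5)):
        s = np.clip(phase / stance_frac, 0.0, 1.0)
        X[:, d0 + base + 1] = (1.0 - s) * vgrf / k_n  # heel dy
        X[:, d0 + base + 3] = s * vgrf / k_n  # toe dy

    if nlp.mode == "muscle":
        from .msk.muscles import mt_length

        X[:, 18:34] = 0.05
        # fibers at zero tendon strain for the guessed posture (equilibrium-ish)
        l_mt = mt_length(X[:, 3:9], nlp._ma)
        X[:, 34:50] = np.clip(
            l_mt - nlp._ma.lslack[None, :], 0.25 * nlp._ma.lopt, 2.4 * nlp._ma.lopt
        )
        U = np.full((N, nlp.nu), 0.05)
    else:
        U = np.zeros((N, nlp.nu))
    X = np.clip(X, nlp.x_lb, nlp.x_ub)
    return nlp.pack(X, U, T0)


def interpolate_solution(result: OCPResult, nlp_fine: TrackingNLP) -> np.ndarray:
    """Warm start for a finer grid: interpolate a coarse solution onto it.

    Solving N=20 first and refining to N=50 is much cheaper than solving the
    fine grid cold.
    """
    Nc = result.states.shape[0]
    Nf = nlp_fine.N
    x0 = result.states[-1][dyn._mirror_perm(result.mode)].copy()
    x0[0] -= result.speed * result.duration
    Xc = np.vstack([x0, result.states])
    u0 = dyn.mirror_controls(result.controls[-1], result.mode)
    Uc = np.vstack([u0, result.controls])
    tc = np.arange(Nc + 1) / Nc
    tf = np.arange(1, Nf + 1) / Nf
    Xf = np.empty((Nf, nlp_fine.nx))
    for j in range(nlp_fine.nx):
        Xf[:, j] = np.interp(tf, tc, Xc[:, j])
    Uf = np.empty((Nf, nlp_fine.nu))
    for j in range(nlp_fine.nu):
        Uf[:, j] = np.interp(tf, tc, Uc[:, j])
    return nlp_fine.pack(Xf, Uf, result.duration)


def solve_ocp(
    nlp: TrackingNLP,
    w0: np.ndarray | None = None,
    *,
    max_iter: int = 2000,
    feasibility_tol: float = 1e-4,
    method: str = "penalty-gn",
    rho_schedule: tuple = (1e2, 1e4, 1e6, 1e8),
    verbose: int = 0,
) -> OCPResult:
    """Solve the transcribed NLP; non-converged problems are flagged, not kept.

    The default method minimizes the exact-penalty least-squares merit
    ``sum r_obj^2 + rho * sum c^2`` with a trust-region Gauss-Newton solver
    over an increasing penalty schedule (warm-started between stages); the
    quadratic-penalty path converges to the constrained optimum as rho grows
    and exploits the least-squares structure of tracking, effort, and
    regularization.  ``method='trust-constr'`` runs a conventional SQP-style
    interior-point solve instead.  Convergence means the scaled dynamics +
    symmetry residual is within ``feasibility_tol`` at every node.
    """
    bounds = nlp.bounds()
    if np.any(bounds.lb > bounds.ub):
        return _failed_result(nlp, "infeasible bounds (lower > upper)")
    w0 = initial_guess(nlp) if w0 is None else np.asarray(w0, dtype=float)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if method == "penalty-gn":
                w, n_iter, message = _solve_penalty_gn(
                    nlp, w0, bounds, rho_schedule, max_iter, feasibility_tol, verbose
                )
            elif method == "trust-constr":
                con = NonlinearConstraint(nlp.constraints, 0.0, 0.0, jac=nlp.constraint_jacobian)
                res = minimize(
                    nlp.objective,
                    w0,
                    jac=nlp.objective_gradient,
                    method="trust-constr",
                    constraints=[con],
                    bounds=bounds,
                    options={"maxiter": max_iter, "gtol": 1e-7, "xtol": 1e-12, "verbose": verbose},
                )
                w, n_iter, message = res.x, int(res.nit), str(res.message)
            else:
                raise ValueError(f"unknown method {method!r}")
    except Exception as exc:  # solver blow-up -> failed status with diagnostics
        return _failed_result(nlp, f"solver exception: {exc!r}")

    X, U, T = nlp.unpack(w)
    max_res = nlp.max_scaled_residual(w)
    terms = nlp.objective_terms(w)
    status = "converged" if max_res <= feasibility_tol else "failed"
    return OCPResult(
        states=X,
        controls=U,
        duration=T,
        objective=nlp.objective(w),
        tracking_term=terms["tracking"],
        effort_term=terms["effort"],
        reg_term=terms["regularization"],
        status=status,
        n_iter=n_iter,
        max_residual=max_res,
        mode=nlp.mode,
        speed=nlp.targets.speed,
        message=message,
    )


def _solve_penalty_gn(nlp, w0, bounds, rho_schedule, max_iter, feasibility_tol, verbose):
    """Quadratic-penalty homotopy with a projected Levenberg-Marquardt inner loop.

    Each stage minimizes ``sum r_obj^2 + rho * sum c^2`` by damped Gauss-Newton
    steps on the sparse normal equations; trial points are projected onto the
    box bounds.  Later stages are warm-started, so the work concentrates in the
    first stage.
    """
    _, con_rows = nlp._row_split()
    w = np.clip(w0, bounds.lb, bounds.ub)
    nfev_total = 0
    per_stage = max(max_iter // max(len(rho_schedule), 1), 20)

    for stage, rho in enumerate(rho_schedule):
        sq = np.sqrt(rho)
        scale_vec = np.ones(nlp.N * nlp.n_block_rows)
        scale_vec[con_rows] = sq

        def resid(wv):
            return nlp._values(wv).ravel() * scale_vec

        r = resid(w)
        cost = float(r @ r)
        lam = 1e-4
        it = 0
        while it < per_stage:
            it += 1
            J = nlp._derivatives(w)
            Js = J.multiply(scale_vec[:, None]).tocsr()
            g = Js.T @ r
            if np.max(np.abs(g)) < 1e-10 * (1.0 + cost):
                break
            H = (Js.T @ Js).toarray()
            dH = np.clip(np.diag(H), 1e-8, None)
            accepted = False
            for _ in range(24):
                try:
                    step = np.linalg.solve(H + lam * np.diag(dH), -g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                w_try = np.clip(w + step, bounds.lb, bounds.ub)
                r_try = resid(w_try)
                nfev_total += 1
                cost_try = float(r_try @ r_try)
                if cost_try < cost:
                    rel_drop = (cost - cost_try) / max(cost, 1e-300)
                    w, r, cost = w_try, r_try, cost_try
                    lam = max(lam / 3.0, 1e-10)
                    accepted = True
                    break
                lam *= 4.0
            if not accepted:
                break  # stalled at this penalty level
            if rel_drop < 1e-10:
                break
        if verbose:
            print(
                f"  rho={rho:g}: feas={nlp.max_scaled_residual(w):.2e} "
                f"obj={nlp.objective(w):.4g} iters={it}"
            )
        if rho >= rho_schedule[-1] and nlp.max_scaled_residual(w) <= feasibility_tol:
            break

    # SVD-based trust-region polish at the final penalty: robust to the
    # ill-conditioning that stalls the normal-equation steps
    if nlp.max_scaled_residual(w) > feasibility_tol:
        from scipy.optimize import least_squares

        sq = np.sqrt(rho_schedule[-1])
        scale_vec = np.ones(nlp.N * nlp.n_block_rows)
        scale_vec[con_rows] = sq
        margin = 1e-12 * (1.0 + np.abs(bounds.lb) + np.abs(bounds.ub))
        sol = least_squares(
            lambda wv: nlp._values(wv).ravel() * scale_vec,
            np.clip(w, bounds.lb + margin, bounds.ub - margin),
            jac=lambda wv: nlp._derivatives(wv).toarray() * scale_vec[:, None],
            bounds=(bounds.lb, bounds.ub),
            method="trf",
            tr_solver="exact",
            x_scale="jac",
            max_nfev=120,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if nlp.objective(sol.x) < np.inf:
            w = sol.x
            nfev_total += sol.nfev
        if verbose:
            print(f"  polish: feas={nlp.max_scaled_residual(w):.2e} obj={nlp.objective(w):.4g}")

    return w, nfev_total, "penalty Gauss-Newton schedule complete"


def _failed_result(nlp: TrackingNLP, message: str) -> OCPResult:
    return OCPResult(
        states=np.zeros((nlp.N, nlp.nx)),
        controls=np.zeros((nlp.N, nlp.nu)),
        duration=float(np.mean(nlp.grid.t_bounds)),
        objective=np.nan,
        tracking_term=np.nan,
        effort_term=np.nan,
        reg_term=np.nan,
        status="failed",
        n_iter=0,
        max_residual=np.inf,
        mode=nlp.mode,
        speed=nlp.targets.speed,
        message=message,
    )


def expand_to_full_cycle(
    result: OCPResult,
    nlp: TrackingNLP,
    *,
    subject_id: str = "sim",
    trial: int = 0,
    provenance: dict | None = None,
) -> tuple[GaitCycle, Motion]:
    """Expand a converged half-cycle solution to a full 100-point cycle.

    The second half is the mirrored first half translated forward by v*T.
    Right-leg angles, net joint moments, and BW-normalized GRFs are emitted as
    a :class:`GaitCycle`; the full coordinate trajectory is returned as a
    :class:`Motion` for virtual-sensor synthesis.
    """
    if result.status != "converged":
        raise ValueError(f"cannot expand a non-converged solution ({result.message})")
    model, mode, N = nlp.model, nlp.mode, nlp.N
    T, v = result.duration, result.speed

    # half-cycle samples at 50 equally spaced points, starting at the closure
    # state; cubic interpolation keeps the implied accelerations smooth
    from scipy.interpolate import CubicSpline

    Xh = np.vstack([nlp.x0_of(result.states, T), result.states])  # (N+1, nx)
    Uh = np.vstack([nlp.u0_of(result.controls), result.controls])
    t_nodes = np.arange(N + 1) / N
    t_half = np.arange(N_POINTS // 2) / (N_POINTS // 2)
    X50 = CubicSpline(t_nodes, Xh, axis=0)(t_half)
    U50 = CubicSpline(t_nodes, Uh, axis=0)(t_half)

    Xm = dyn.mirror_state(X50, mode)
    Xm[:, 0] += v * T
    Xfull = np.vstack([X50, Xm])
    Ufull = np.vstack([U50, dyn.mirror_controls(U50, mode)])

    mg = model.total_mass * model.gravity
    grf = dyn.ground_reactions(Xfull, model, mode)[:, 0, :] / mg  # right foot, BW
    if mode == "torque":
        moments = dyn.joint_moments(Xfull, model, u=Ufull, mode=mode)
    else:
        moments = dyn.joint_moments(Xfull, model, mode=mode)

    cycle = GaitCycle(
        subject_id=subject_id,
        gait="walk" if v < 2.55 else "run",
        speed=v,
        bw=model.body_weight,
        bh=model.body_height,
        hip_angle=Xfull[:, 3],
        knee_angle=Xfull[:, 4],
        ankle_angle=Xfull[:, 5],
        grf_ap=grf[:, 0],
        grf_v=grf[:, 1],
        hip_moment=moments[:, 0],
        knee_moment=moments[:, 1],
        ankle_moment=moments[:, 2],
        trial=trial,
        source="simulated",
    )
    motion = Motion(
        q=Xfull[:, 0:NQ],
        duration=2 * T,
        speed=v,
        params=model,
        provenance=provenance,
    )
    return cycle, motion
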