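"""Collocation transcription, solver behavior, and full-cycle expansion.

The heavy solves run once per module (torque mode, N = 20) and are shared
across tests; the self-consistency round trip is the module's primary
correctness oracle.
"""

import dataclasses

import numpy as np
import pytest

from gaitaug.msk import dynamics as dyn
from gaitaug.ocp import (
    CollocationGrid,
    OCPWeights,
    build_ocp,
    expand_to_full_cycle,
    initial_guess,
    solve_ocp,
)
from gaitaug.sampler import TrackingTargets, split_tracking

FEAS_TOL = 1e-4


@pytest.fixture(scope="module")
def targets20(walk_fit):
    dist, _ = walk_fit
    return split_tracking(dist.mean, dist, n_nodes=20)


@pytest.fixture(scope="module")
def nlp20(targets20, walk_fit):
    _, model = walk_fit
    return build_ocp(targets20, model, mode="torque")


@pytest.fixture(scope="module")
def solved20(nlp20):
    res = solve_ocp(nlp20, max_iter=900)
    assert res.status == "converged", res.message
    return res


def _self_targets(nlp, res, sigma_deg=2.0, sigma_grf=0.05):
    """Tracking targets equal to the solved motion's own tracked channels."""
    X = res.states
    mg = nlp.model.total_mass * nlp.model.gravity
    grf = dyn.ground_reactions(X, nlp.model, nlp.mode) / mg
    s = np.empty((10, nlp.N))
    s[0:3] = X[:, 3:6].T
    s[5:8] = X[:, 6:9].T
    s[3], s[4] = grf[:, 0, 0], grf[:, 0, 1]
    s[8], s[9] = grf[:, 1, 0], grf[:, 1, 1]
    var = np.empty((10, nlp.N))
    var[0:3] = var[5:8] = np.radians(sigma_deg) ** 2
    var[3:5] = var[8:10] = sigma_grf**2
    return TrackingTargets(mean=s, var=var, speed=res.speed, n_nodes=nlp.N)


class TestTranscription:
    def test_decision_variable_counts(self, targets20, walk_fit):
        _, model = walk_fit
        # full-profile problem: 50 nodes, 58 states + 16 controls, free duration
        tt50 = dataclasses.replace(
            targets20,
            mean=np.repeat(targets20.mean, 3, axis=1)[:, :50],
            var=np.repeat(targets20.var, 3, axis=1)[:, :50],
            n_nodes=50,
        )
        nlp_muscle = build_ocp(tt50, model, mode="muscle")
        assert nlp_muscle.n_decision == 50 * (58 + 16) + 1 == 3701
        assert nlp_muscle.n_symmetry_rows == 58
        nlp_torque = build_ocp(targets20, model, mode="torque")
        assert nlp_torque.n_decision == 20 * (26 + 6) + 1 == 641
        assert nlp_torque.n_constraints == 20 * 26

    def test_node_count_mismatch_rejected(self, targets20, walk_fit):
        _, model = walk_fit
        with pytest.raises(ValueError):
            build_ocp(targets20, model, grid=CollocationGrid(n_nodes=50), mode="torque")

    def test_objective_zero_when_tracking_own_channels_zero_weights(self, nlp20, walk_fit):
        _, model = walk_fit
        w0 = initial_guess(nlp20)
        X, U, T = nlp20.unpack(w0)
        tt = _self_targets(nlp20, _dummy_result(nlp20, X, U, T))
        nlp0 = build_ocp(
            tt, model, weights=OCPWeights(effort=0.0, reg=0.0), mode="torque"
        )
        assert nlp0.objective(w0) == pytest.approx(0.0, abs=1e-16)

    def test_odd_node_count_rejected(self):
        with pytest.raises(ValueError):
            CollocationGrid(n_nodes=21)


def _dummy_result(nlp, X, U, T):
    from gaitaug.ocp import OCPResult

    return OCPResult(
        states=X, controls=U, duration=T, objective=0.0, tracking_term=0.0,
        effort_term=0.0, reg_term=0.0, status="converged", n_iter=0,
        max_residual=0.0, mode=nlp.mode, speed=nlp.targets.speed,
    )


class TestSolve:
    def test_converged_residuals_within_tolerance(self, nlp20, solved20):
        assert solved20.max_residual <= FEAS_TOL
        w = nlp20.pack(solved20.states, solved20.controls, solved20.duration)
        res_nodes = np.abs(nlp20.constraints(w)).reshape(nlp20.N, nlp20.nx)
        assert res_nodes.max() <= FEAS_TOL  # at every node, every equation

    def test_objective_decomposition_sums(self, solved20):
        total = solved20.tracking_term + solved20.effort_term + solved20.reg_term
        assert total == pytest.approx(solved20.objective, rel=1e-9)

    def test_duration_is_plausible_walking_half_cycle(self, solved20):
        assert 0.35 <= solved20.duration <= 0.8

    def test_restart_from_solution_stays_put(self, nlp20, solved20):
        w = nlp20.pack(solved20.states, solved20.controls, solved20.duration)
        res = solve_ocp(nlp20, w0=w, max_iter=120, rho_schedule=(1e8,))
        assert res.status == "converged"
        assert res.objective <= solved20.objective + 1e-6  # never worsens

    def test_infeasible_bounds_fail_cleanly(self, targets20, walk_fit):
        _, model = walk_fit
        nlp = build_ocp(targets20, model, mode="torque")
        nlp.x_lb = nlp.x_ub + 1.0  # force lb > ub
        res = solve_ocp(nlp)
        assert res.status == "failed"
        assert "bounds" in res.message

    def test_self_consistency_round_trip(self, nlp20, solved20, walk_fit):
        """Tracking the model's own motion recovers it: the primary oracle."""
        _, model = walk_fit
        tt = _self_targets(nlp20, solved20)
        nlp2 = build_ocp(tt, model, mode="torque")
        res2 = solve_ocp(nlp2, max_iter=900)
        assert res2.status == "converged"
        assert res2.tracking_term < 1.0  # near-zero tracking residual
        ang_rmse = np.degrees(
            np.sqrt(np.mean((res2.states[:, 3:9] - solved20.states[:, 3:9]) ** 2))
        )
        assert ang_rmse < 2.0

    def test_stiffer_tracking_reduces_deviation(self, nlp20, solved20, walk_fit):
        """Shrinking sigma pulls the simulated channels closer to the targets."""
        _, model = walk_fit
        devs = []
        for scale in (4.0, 0.25):
            tt = dataclasses.replace(nlp20.targets, var=nlp20.targets.var * scale**2)
            nlp = build_ocp(tt, model, mode="torque")
            res = solve_ocp(nlp, max_iter=600)
            assert res.status == "converged"
            w = nlp.pack(res.states, res.controls, res.duration)
            blocks = nlp._values(w)
            s_minus_m = blocks[:, 0:10] * np.sqrt(tt.var * 10 * nlp.N).T
            devs.append(float(np.mean(s_minus_m**2)))
        assert devs[1] < devs[0]  # sigma/4 tracks tighter than 4*sigma


class TestExpansion:
    @pytest.fixture(scope="class")
    def expanded(self, solved20, nlp20):
        return expand_to_full_cycle(solved20, nlp20, subject_id="S04")

    def test_hundred_points_per_channel(self, expanded):
        cycle, motion = expanded
        for arr in (cycle.hip_angle, cycle.grf_v, cycle.hip_moment):
            assert arr.shape == (100,)
        assert motion.q.shape == (100, 9)

    def test_second_half_mirrors_first(self, expanded):
        _, motion = expanded
        np.testing.assert_allclose(motion.q[50:, 3], motion.q[:50, 6], atol=1e-12)
        np.testing.assert_allclose(motion.q[50:, 6], motion.q[:50, 3], atol=1e-12)

    def test_forward_translation_identity(self, expanded, solved20):
        _, motion = expanded
        v2T = solved20.speed * 2 * solved20.duration
        # wrap-around: one full cycle advances the trunk by v * 2T
        step = motion.q[50, 0] - motion.q[0, 0]
        assert 2 * step == pytest.approx(v2T, rel=1e-6)

    def test_non_converged_input_rejected(self, nlp20):
        from gaitaug.ocp import _failed_result

        with pytest.raises(ValueError):
            expand_to_full_cycle(_failed_result(nlp20, "nope"), nlp20)
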