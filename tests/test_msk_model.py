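"""Model scaling, implicit dynamics, contact forces, moments, and mirroring."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gaitaug.msk import (
    Anthropometry,
    ValidationError,
    forward_dynamics_torque,
    ground_reactions,
    implicit_dynamics,
    joint_moments,
    mechanical_energy,
    mirror_controls,
    mirror_state,
    scale_model,
    standing_state,
    state_dim,
)
from gaitaug.msk.dynamics import NX_MUSCLE, NX_TORQUE, _mirror_perm
from gaitaug.msk.muscles import MuscleArrays, mt_length, tendon_force
from gaitaug.msk.params import JOINT_NAMES, SEGMENT_NAMES, WINTER_TABLE


class TestScaling:
    @pytest.mark.parametrize("bw,bh", [(75.0, 1.75), (52.3, 1.58), (96.1, 1.93)])
    def test_segment_masses_sum_to_body_weight(self, bw, bh):
        p = scale_model(Anthropometry(bw, bh))
        assert p.total_mass == pytest.approx(bw, abs=1e-9)

    def test_lengths_follow_fraction_table(self):
        p = scale_model(Anthropometry(75.0, 1.75))
        assert p.segments["thigh_r"].length == pytest.approx(
            WINTER_TABLE["thigh"]["length"] * 1.75
        )
        assert p.segments["shank_l"].length == pytest.approx(
            WINTER_TABLE["shank"]["length"] * 1.75
        )

    def test_structure_counts(self, model75):
        assert len(SEGMENT_NAMES) == 7
        assert len(JOINT_NAMES) == 6
        assert len(model75.muscles) == 16
        assert state_dim("muscle") == 58
        assert state_dim("torque") == 26

    def test_forces_scale_with_weight_lengths_with_height(self):
        a = scale_model(Anthropometry(75.0, 1.75))
        b = scale_model(Anthropometry(90.0, 1.75))
        c = scale_model(Anthropometry(75.0, 1.40))
        assert b.muscles[0].fmax == pytest.approx(a.muscles[0].fmax * 90 / 75)
        assert c.muscles[0].lopt == pytest.approx(a.muscles[0].lopt * 1.40 / 1.75)

    @pytest.mark.parametrize("bw,bh", [(0.0, 1.75), (-3.0, 1.75), (75.0, 0.0), (75.0, np.nan)])
    def test_invalid_anthropometry_rejected(self, bw, bh):
        with pytest.raises(ValidationError):
            scale_model(Anthropometry(bw, bh))


class TestImplicitDynamics:
    @pytest.mark.parametrize("mode", ["torque", "muscle"])
    def test_free_fall_closed_form(self, model75, mode):
        """Airborne, zero velocity, qdd = -g: the equations of motion close exactly."""
        nx = state_dim(mode)
        x = np.zeros(nx)
        x[1] = 5.0  # well above ground
        if mode == "muscle":
            ma = MuscleArrays(model75)
            x[34:50] = 1.2 * ma.lopt  # slack tendons: no applied muscle torque
        xdot = np.zeros(nx)
        xdot[10] = -model75.gravity
        u = np.zeros(16 if mode == "muscle" else 6)
        res = implicit_dynamics(x, xdot, u, model75, mode=mode)
        # muscle mode carries tiny smooth slack-tendon force tails (< 0.1 N m)
        tol = 1e-8 if mode == "torque" else 0.1
        assert np.abs(res[9:18]).max() < tol

    def test_kinematic_consistency_block(self, model75):
        x = np.zeros(26)
        x[1], x[9] = 5.0, 1.0  # qdot_x = 1
        xdot = np.zeros(26)  # but xdot_q = 0
        res = implicit_dynamics(x, xdot, np.zeros(6), model75, mode="torque")
        assert res[0] == pytest.approx(-1.0)

    def test_dimension_mismatch_rejected(self, model75):
        with pytest.raises(ValueError):
            implicit_dynamics(np.zeros(25), np.zeros(26), np.zeros(6), model75, mode="torque")
        with pytest.raises(ValueError):
            implicit_dynamics(np.zeros(26), np.zeros(26), np.zeros(5), model75, mode="torque")

    def test_energy_conserved_passive_airborne(self, model75):
        """No muscles, no contact, no damping: mechanical energy is constant."""
        import copy

        p = copy.deepcopy(model75)
        p.passive_damping = 0.0
        x0 = np.zeros(26)
        x0[1], x0[2], x0[3], x0[4] = 5.0, 0.1, 0.3, -0.5
        x0[9:13] = [1.0, 2.0, 1.5, -2.0]
        sol = solve_ivp(
            lambda t, x: forward_dynamics_torque(x, np.zeros(6), p),
            [0, 0.3],
            x0,
            rtol=1e-9,
            atol=1e-10,
        )
        E0 = mechanical_energy(sol.y[:, 0], p)
        E1 = mechanical_energy(sol.y[:, -1], p)
        assert abs(E1 - E0) < 1e-5 * abs(E0)


class TestGroundReactions:
    def test_airborne_is_zero(self, model75):
        x = np.zeros(26)
        x[1] = 5.0
        grf = ground_reactions(x, model75, mode="torque")
        assert np.abs(grf).max() < 1e-6

    def test_static_standing_supports_body_weight(self, model75):
        x = standing_state(model75, mode="torque")
        grf = ground_reactions(x, model75, mode="torque")
        total_v = grf[:, 1].sum()
        assert total_v == pytest.approx(model75.total_mass * model75.gravity, rel=0.01)

    def test_friction_cone_everywhere(self, model75, rng):
        """|A-P force| <= mu * vertical force for arbitrary (bounded) states."""
        X = np.zeros((200, 26))
        X[:, 0] = rng.uniform(-1, 1, 200)
        X[:, 1] = rng.uniform(0.7, 1.2, 200)
        X[:, 2:9] = rng.uniform(-0.5, 0.5, (200, 7))
        X[:, 9:18] = rng.uniform(-3, 3, (200, 9))
        X[:, 18:26:2] = rng.uniform(-0.05, 0.05, (200, 4))
        X[:, 19:26:2] = rng.uniform(0.0, 0.02, (200, 4))
        grf = ground_reactions(X, model75, mode="torque")
        assert np.all(grf[:, :, 1] >= -1e-12)
        assert np.all(np.abs(grf[:, :, 0]) <= model75.contact.mu * grf[:, :, 1] + 1e-9)


class TestJointMoments:
    def test_zero_at_rest_inside_free_range(self, model75):
        x = np.zeros(26)
        x[1] = 5.0
        m = joint_moments(x, model75, u=np.zeros(6), mode="torque")
        assert np.abs(m).max() == 0.0

    def test_torque_mode_scales_controls(self, model75):
        x = np.zeros(26)
        x[1] = 5.0
        u = np.array([1.0, -0.5, 0.2, 0.0, 0.0, 0.0])
        m = joint_moments(x, model75, u=u, mode="torque")
        np.testing.assert_allclose(m, u * model75.torque_scale, atol=1e-12)

    def test_single_muscle_force_times_arm(self, model75):
        """With one taut tendon (rest slack), the moment is F_t x its constant arm."""
        ma = MuscleArrays(model75)
        x = np.zeros(58)
        x[1] = 5.0
        x[34:50] = 1.2 * ma.lopt  # long fibers -> every tendon slack
        i = 6  # right soleus: shorten its fiber to stretch the tendon by 4 mm
        x[34 + i] = ma.lopt[i] - 0.004
        strain = (ma.lopt[i] + 0.004 - ma.lopt[i]) / ma.lslack[i]
        f_expected = ma.fmax[i] * 0.5 * (strain + np.hypot(strain, 1e-3)) / 0.04
        m = joint_moments(x, model75, mode="muscle")
        assert m[2] == pytest.approx(f_expected * ma.arms[i, 2], rel=1e-2)
        assert abs(m[0]) < 0.2  # soleus does not cross the hip (slack-tendon tails only)


class TestMirror:
    @pytest.mark.parametrize("mode", ["torque", "muscle"])
    def test_involution(self, rng, mode):
        x = rng.normal(size=state_dim(mode))
        np.testing.assert_array_equal(mirror_state(mirror_state(x, mode), mode), x)

    def test_identical_legs_fixed_point(self):
        x = np.zeros(26)
        x[1] = 1.0
        x[3:6] = x[6:9] = [0.4, -0.3, 0.1]
        x[19:22] = x[23:26] = 0.0
        np.testing.assert_array_equal(mirror_state(x, "torque"), x)

    def test_leg_blocks_swap(self, rng):
        x = rng.normal(size=58)
        xm = mirror_state(x, "muscle")
        assert xm[3] == x[6] and xm[6] == x[3]  # hips swap
        np.testing.assert_array_equal(xm[0:3], x[0:3])  # trunk untouched

    @pytest.mark.parametrize("mode", ["torque", "muscle"])
    def test_commutes_with_dynamics(self, model75, rng, mode):
        """Mirroring all arguments permutes the residual the same way."""
        nx = state_dim(mode)
        nu = 16 if mode == "muscle" else 6
        x = np.zeros(nx)
        x[0:9] = rng.normal(scale=0.3, size=9)
        x[1] += 1.0
        x[9:18] = rng.normal(scale=1.0, size=9)
        if mode == "muscle":
            ma = MuscleArrays(model75)
            x[18:34] = rng.uniform(0.05, 0.5, 16)
            x[34:50] = ma.lopt * rng.uniform(0.9, 1.1, 16)
            x[50:58] = rng.uniform(0, 0.01, 8)
        else:
            x[18:26] = rng.uniform(0, 0.01, 8)
        xdot = rng.normal(scale=0.5, size=nx)
        u = rng.uniform(0, 1, nu)
        perm = _mirror_perm(mode)
        res_mirrored_args = implicit_dynamics(
            mirror_state(x, mode), mirror_state(xdot, mode), mirror_controls(u, mode),
            model75, mode=mode,
        )
        res = implicit_dynamics(x, xdot, u, model75, mode=mode)
        np.testing.assert_allclose(res_mirrored_args, res[perm], rtol=1e-9, atol=1e-10)
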