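"""Cycle-vector layout, distribution fitting, sampling, and target splitting."""

import numpy as np
import pytest

from gaitaug.cycles import GaitCycle
from gaitaug.sampler import (
    CYCLE_VECTOR_DIM,
    LAYOUT,
    SPEED_INDEX,
    GaitDistribution,
    assemble_cycle_vector,
    disassemble_cycle_vector,
    draw_samples,
    fit_distribution,
    split_tracking,
)


def _cycle(speed=1.3, **overrides):
    base = dict(
        subject_id="S01",
        gait="walk",
        speed=speed,
        bw=75.0,
        bh=1.75,
        hip_angle=np.linspace(0, 0.5, 100),
        knee_angle=np.linspace(-1, 0, 100),
        ankle_angle=np.zeros(100),
        grf_ap=np.zeros(100),
        grf_v=np.full(100, 0.5),
    )
    base.update(overrides)
    return GaitCycle(**base)


class TestCycleVector:
    def test_length_and_stacking(self):
        z = assemble_cycle_vector(_cycle())
        assert z.shape == (CYCLE_VECTOR_DIM,) == (501,)
        Z = np.stack([assemble_cycle_vector(_cycle(speed=1.0 + 0.01 * i)) for i in range(30)])
        assert Z.shape == (30, 501)

    def test_round_trip(self):
        c = _cycle()
        d = disassemble_cycle_vector(assemble_cycle_vector(c))
        np.testing.assert_array_equal(d["hip_angle"], c.hip_angle)
        np.testing.assert_array_equal(d["grf_v"], c.grf_v)
        assert d["speed"] == c.speed

    def test_wrong_length_channel_rejected(self):
        with pytest.raises(ValueError):
            _cycle(hip_angle=np.zeros(99))
        with pytest.raises(ValueError):
            disassemble_cycle_vector(np.zeros(500))


class TestFit:
    def test_identical_rows(self):
        row = assemble_cycle_vector(_cycle())
        d = fit_distribution(np.tile(row, (30, 1)), "S01", "walk")
        np.testing.assert_allclose(d.mean, row, rtol=0, atol=1e-12)
        assert np.abs(d.cov).max() < 1e-20

    def test_hand_computed_two_point_covariance(self):
        """Rows differing by (2, 2) in two coordinates: var = cov = 2 (unbiased)."""
        Z = np.zeros((2, 501))
        Z[1, 0] = Z[1, 1] = 2.0
        d = fit_distribution(Z, "S01", "walk")
        assert d.cov[0, 0] == pytest.approx(2.0)
        assert d.cov[1, 1] == pytest.approx(2.0)
        assert d.cov[0, 1] == pytest.approx(2.0)

    def test_psd_after_clipping(self, rng):
        Z = rng.normal(size=(30, 501))
        d = fit_distribution(Z, "S01", "walk")
        np.testing.assert_allclose(d.cov, d.cov.T)
        w, _ = d.factor()
        assert w.min() >= 0.0

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            fit_distribution(np.zeros((1, 501)), "S01", "walk")


class TestDraw:
    def test_zero_covariance_returns_mean(self):
        mu = assemble_cycle_vector(_cycle())
        d = GaitDistribution(mean=mu, cov=np.zeros((501, 501)), subject_id="S", gait="walk", n_cycles=5)
        S, rej = draw_samples(d, 5, seed=0)
        np.testing.assert_allclose(S, np.tile(mu, (5, 1)))
        assert rej == 0

    def test_seed_determinism(self, walk_fit):
        dist, _ = walk_fit
        A, _ = draw_samples(dist, 8, seed=42)
        B, _ = draw_samples(dist, 8, seed=42)
        np.testing.assert_array_equal(A, B)

    def test_moments_converge_on_low_rank_subblock(self):
        """Sample mean/covariance of an embedded 2D block within 5% at n = 10,000."""
        mu = np.zeros(501)
        mu[400:500] = 1.0  # keep peak vGRF above the rejection threshold
        mu[SPEED_INDEX] = 1.3
        cov = np.zeros((501, 501))
        cov[:2, :2] = [[1.0, 0.6], [0.6, 2.0]]
        d = GaitDistribution(mean=mu, cov=cov, subject_id="S", gait="walk", n_cycles=30)
        S, _ = draw_samples(d, 10_000, seed=1)
        emp = np.cov(S[:, :2], rowvar=False)
        np.testing.assert_allclose(S[:, :2].mean(axis=0), [0, 0], atol=0.05)
        np.testing.assert_allclose(emp, cov[:2, :2], rtol=0.05, atol=0.02)
        # off-block coordinates stay in the support subspace
        assert S[:, 2:400].std() == 0.0

    def test_speed_clipped_and_low_grf_rejected(self):
        mu = np.zeros(501)
        mu[SPEED_INDEX] = 10.0  # far above the physical range
        mu[400:500] = 1.0
        cov = np.zeros((501, 501))
        d = GaitDistribution(mean=mu, cov=cov, subject_id="S", gait="run", n_cycles=3)
        S, _ = draw_samples(d, 3, seed=0)
        assert np.all(S[:, SPEED_INDEX] <= 6.0)


class TestSplitTracking:
    def test_mean_sample_right_targets_follow_layout(self, walk_fit):
        dist, _ = walk_fit
        tt = split_tracking(dist.mean, dist, n_nodes=50)
        hip = dist.mean[LAYOUT["hip_angle"]]
        # node k (1-based) sits at cycle point k; right-leg targets = points 1..50
        np.testing.assert_allclose(tt.mean[0], hip[np.r_[1:50, 50]], atol=1e-12)

    def test_left_leg_indexing_contract(self, walk_fit):
        dist, _ = walk_fit
        tt = split_tracking(dist.mean, dist, n_nodes=50)
        vgrf = dist.mean[LAYOUT["grf_v"]]
        for k in (1, 10, 37):  # left vGRF target at node k = point 50 + k
            assert tt.mean[9, k - 1] == pytest.approx(vgrf[(50 + k) % 100])

    def test_variance_floor(self):
        mu = np.zeros(501)
        mu[400:500] = 1.0
        mu[SPEED_INDEX] = 1.0
        d = GaitDistribution(mean=mu, cov=np.zeros((501, 501)), subject_id="S", gait="walk", n_cycles=9)
        tt = split_tracking(mu, d, n_nodes=20)
        assert tt.var.min() > 0.0
        assert np.all(tt.var[0] == pytest.approx(1e-4 * 0.5**2))

    def test_shapes_and_speed(self, walk_fit):
        dist, _ = walk_fit
        tt = split_tracking(dist.mean, dist, n_nodes=20)
        assert tt.mean.shape == tt.var.shape == (10, 20)
        assert tt.speed == pytest.approx(dist.mean[SPEED_INDEX])
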