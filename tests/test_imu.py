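"""Virtual inertial sensors: static readings, chain rates, numeric-oracle agreement."""

import numpy as np
import pytest

from gaitaug.cycles import N_POINTS
from gaitaug.imu import SensorSpec, accel_signal, default_sensors, gyro_signal, simulate_imu_cycle
from gaitaug.motion import Motion, reconstruct_motion
from gaitaug.msk.kinematics import BodyKinematics
from gaitaug.synth import gait_template, subject_profile


def _static_motion(model, q=None):
    qs = np.zeros((N_POINTS, 9))
    qs[:, 1] = 1.0
    if q is not None:
        qs[:] = q
    return Motion(q=qs, duration=1.0, speed=0.0, params=model)


def _gait_motion(model, gait="walk", speed=1.3):
    prof = subject_profile(3, 5)
    ch = gait_template(speed, gait, prof)
    return reconstruct_motion(
        ch["hip"], ch["knee"], ch["ankle"], ch["grf_ap"], ch["grf_v"], speed, model, gait
    )


def _fd_oracle(pos, period, refine=20):
    """Centered second differences of a periodic trajectory on a refined grid."""
    n = pos.shape[0]
    spec = np.fft.rfft(pos, axis=0)
    spec[-1] *= 0.5  # split the Nyquist bin for trigonometric resampling
    fine = np.fft.irfft(spec, n * refine, axis=0) * refine
    dt = period / (n * refine)
    acc = (np.roll(fine, -1, axis=0) - 2 * fine + np.roll(fine, 1, axis=0)) / dt**2
    return acc[::refine]


class TestStatic:
    def test_accelerometers_read_gravity_gyros_zero(self, model75):
        motion = _static_motion(model75)
        for sensor in default_sensors(model75):
            acc = accel_signal(motion, sensor)
            np.testing.assert_allclose(acc[:, 0], 0.0, atol=1e-9)  # A-P
            np.testing.assert_allclose(acc[:, 1], model75.gravity, atol=1e-9)  # longitudinal
            np.testing.assert_allclose(gyro_signal(motion, sensor), 0.0, atol=1e-12)


class TestGyroChain:
    def test_trunk_oscillation_propagates_to_all_segments(self, model75):
        """Joints frozen: every segment's gyro equals the trunk rate."""
        t = np.arange(N_POINTS) / N_POINTS
        q = np.zeros((N_POINTS, 9))
        q[:, 1] = 1.0
        q[:, 2] = 0.1 * np.sin(2 * np.pi * t)
        motion = Motion(q=q, duration=0.8, speed=0.0, params=model75)
        expected = 0.1 * 2 * np.pi / 0.8 * np.cos(2 * np.pi * t)
        for sensor in default_sensors(model75):
            np.testing.assert_allclose(gyro_signal(motion, sensor), expected, atol=1e-6)

    def test_thigh_rate_is_trunk_plus_hip(self, model75):
        t = np.arange(N_POINTS) / N_POINTS
        q = np.zeros((N_POINTS, 9))
        q[:, 1] = 1.0
        q[:, 2] = 0.05 * np.sin(2 * np.pi * t)
        q[:, 3] = 0.2 * np.sin(4 * np.pi * t)
        motion = Motion(q=q, duration=1.0, speed=0.0, params=model75)
        trunk = gyro_signal(motion, SensorSpec("trunk", (0.0, 0.1)))
        thigh = gyro_signal(motion, SensorSpec("thigh_r", (0.0, -0.2)))
        hip_rate = 0.2 * 4 * np.pi * np.cos(4 * np.pi * t)
        np.testing.assert_allclose(thigh, trunk + hip_rate, atol=1e-6)


class TestAccelOracle:
    def test_centripetal_term_on_swinging_thigh(self, model75):
        """Sensor at radius r on a hip-pinned pendulum: specific force includes
        the omega^2 r centripetal term (checked at peak angular velocity)."""
        t = np.arange(N_POINTS) / N_POINTS
        A, T = 0.4, 1.0
        q = np.zeros((N_POINTS, 9))
        q[:, 1] = 1.0
        q[:, 3] = A * np.sin(2 * np.pi * t)
        motion = Motion(q=q, duration=T, speed=0.0, params=model75)
        r = 0.25
        acc = accel_signal(motion, SensorSpec("thigh_r", (0.0, -r)))
        # at t = 0: angle 0, omega = A*2*pi/T (peak), alpha = 0
        omega = A * 2 * np.pi / T
        # longitudinal axis points up the thigh: centripetal (omega^2 r, toward
        # the hip) adds to gravity
        assert acc[0, 1] == pytest.approx(model75.gravity + omega**2 * r, rel=1e-3)

    @pytest.mark.parametrize("gait,speed", [("walk", 1.3), ("run", 4.0)])
    def test_against_refined_grid_finite_differences(self, model75, gait, speed):
        """Independent numeric oracle: central second differences of the
        sensor-point trajectory on a 20x refined grid agree within 1% of peak."""
        from gaitaug.msk.kinematics import CHAIN, rot_apply

        motion = _gait_motion(model75, gait, speed)
        T = motion.duration
        t = np.arange(N_POINTS) / N_POINTS * T
        kin = BodyKinematics(motion.q, params=model75)
        for sensor in default_sensors(model75):
            pos, _, _ = kin.point_on(sensor.segment, np.asarray(sensor.offset))
            pos = pos.copy()
            pos[:, 0] -= motion.speed * t
            f_fd = _fd_oracle(pos, T) - np.array([0.0, -model75.gravity])
            phi = motion.q[:, list(CHAIN[sensor.segment])].sum(axis=1)
            ap = rot_apply(phi, np.asarray(sensor.ap_axis))
            lo = rot_apply(phi, np.asarray(sensor.long_axis))
            oracle = np.stack(
                [np.einsum("ki,ki->k", f_fd, ap), np.einsum("ki,ki->k", f_fd, lo)], axis=1
            )
            got = accel_signal(motion, sensor)
            peak = np.abs(oracle).max()
            assert np.abs(got - oracle).max() < 0.01 * peak


class TestAssembly:
    def test_output_shape_and_role_order(self, model75):
        motion = _gait_motion(model75)
        sensors = default_sensors(model75)
        a = simulate_imu_cycle(motion, sensors)
        b = simulate_imu_cycle(motion, sensors[::-1])  # input order must not matter
        assert a.shape == (100, 12)
        np.testing.assert_array_equal(a, b)

    def test_wrong_sensor_count_rejected(self, model75):
        motion = _static_motion(model75)
        with pytest.raises(ValueError):
            simulate_imu_cycle(motion, default_sensors(model75)[:3])
        with pytest.raises(ValueError):
            simulate_imu_cycle(motion, default_sensors(model75) + [SensorSpec("trunk", (0, 0))])

    def test_unknown_segment_rejected(self):
        with pytest.raises(ValueError):
            SensorSpec("pelvis", (0.0, 0.0))

    def test_static_assembly_gravity_only(self, model75):
        imu = simulate_imu_cycle(_static_motion(model75), default_sensors(model75))
        np.testing.assert_allclose(imu[:, 0::3], 0.0, atol=1e-9)  # A-P accs
        np.testing.assert_allclose(imu[:, 1::3], model75.gravity, atol=1e-9)
        np.testing.assert_allclose(imu[:, 2::3], 0.0, atol=1e-12)  # gyros
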