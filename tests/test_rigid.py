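"""Virtual-IMU simulator against analytic motions and matrix oracles."""

import numpy as np
import pytest

from imugait import quat, rigid
from imugait.rigid import (
    IMUSignal,
    PoseSequence,
    SensorPlacement,
    angular_rate,
    augment,
    cardan_angles,
    cardan_to_quat,
    relative_orientation,
    sensor_pose,
    simulate_accel,
    simulate_imu,
)

from conftest import random_smooth_pose


def spin_z(rate=100.0, omega=1.0, duration=2.0, radius=0.0):
    """Constant-rate rotation about global z, optional circular origin."""
    t = np.arange(0, duration, 1.0 / rate)
    q = np.column_stack(
        [np.cos(omega * t / 2), 0 * t, 0 * t, np.sin(omega * t / 2)]
    )
    p = radius * np.column_stack([np.cos(omega * t), np.sin(omega * t), 0 * t])
    return PoseSequence(rate=rate, orientations=q, origins=p)


class TestAngularRate:
    def test_static_pose_zero_rate(self):
        pose = PoseSequence(100.0, quat.identity(50), np.zeros((50, 3)))
        assert np.allclose(angular_rate(pose), 0.0, atol=1e-12)

    def test_constant_rate_rotation(self):
        w = angular_rate(spin_z(rate=100.0, omega=1.0))
        assert np.allclose(w, [0.0, 0.0, 1.0], atol=1e-4)

    def test_matches_rotation_matrix_oracle(self):
        pose = random_smooth_pose(rate=5000.0, duration=0.5, amp=0.2, seed=42)
        w = angular_rate(pose)
        # oracle: body-frame angular velocity from the skew part of Rᵀ·Ṙ,
        # with rotation-matrix central finite differences
        R = quat.to_matrix(pose.orientations)
        dR = np.empty_like(R)
        dt = pose.dt
        dR[1:-1] = (R[2:] - R[:-2]) / (2 * dt)
        dR[0] = (-3 * R[0] + 4 * R[1] - R[2]) / (2 * dt)
        dR[-1] = (3 * R[-1] - 4 * R[-2] + R[-3]) / (2 * dt)
        S = np.einsum("nji,njk->nik", R, dR)  # Rᵀ Ṙ
        w_oracle = np.stack([S[:, 2, 1], S[:, 0, 2], S[:, 1, 0]], axis=1)
        assert np.abs(w - w_oracle).max() < 1e-6

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            PoseSequence(100.0, quat.identity(2), np.zeros((2, 3)))

    def test_nonunit_quaternions_normalized_with_warning(self):
        q = 2.0 * quat.identity(10)
        with pytest.warns(UserWarning):
            pose = PoseSequence(100.0, q, np.zeros((10, 3)))
        assert np.allclose(np.linalg.norm(pose.orientations, axis=1), 1.0)


class TestSensorPose:
    def test_identity_placement_is_noop(self):
        pose = spin_z()
        out = sensor_pose(pose, SensorPlacement("pelvis"))
        assert np.allclose(out.orientations, pose.orientations)
        assert np.allclose(out.origins, pose.origins)

    def test_pure_translation(self):
        pose = PoseSequence(100.0, quat.identity(10), np.zeros((10, 3)))
        out = sensor_pose(pose, SensorPlacement("pelvis", offset_t=[0.1, 0, 0]))
        assert np.allclose(out.origins, [0.1, 0, 0])

    def test_spinning_offset_traces_circle(self):
        r = 0.1
        pose = spin_z(omega=2.0)
        out = sensor_pose(pose, SensorPlacement("pelvis", offset_t=[r, 0, 0]))
        radii = np.linalg.norm(out.origins[:, :2], axis=1)
        assert np.allclose(radii, r, atol=1e-12)
        # downstream accelerometer sees the centripetal magnitude r·ω²
        acc = simulate_accel(out)
        horiz = np.linalg.norm(acc[5:-5, :2], axis=1)
        assert np.allclose(horiz, r * 4.0, rtol=1e-3)


class TestSimulateAccel:
    def test_static_gravity_reaction(self):
        pose = PoseSequence(100.0, quat.identity(20), np.zeros((20, 3)))
        assert np.allclose(simulate_accel(pose), [0, 0, 9.81], atol=1e-9)

    def test_free_fall_zero_specific_force(self):
        t = np.arange(0, 0.5, 0.01)[:, None]
        p = np.array([1.0, 2.0, 3.0]) + 0.5 * rigid.GRAVITY * t**2
        q = np.tile(quat.from_axis_angle([1, 1, 0], 0.7), (len(t), 1))
        pose = PoseSequence(100.0, q, p)
        assert np.allclose(simulate_accel(pose), 0.0, atol=1e-8)

    def test_horizontal_circle_centripetal(self):
        t = np.arange(0, 3.0, 0.01)
        p = 0.5 * np.column_stack([np.cos(2 * t), np.sin(2 * t), 0 * t])
        pose = PoseSequence(100.0, quat.identity(len(t)), p)
        f = simulate_accel(pose)[5:-5]
        assert np.allclose(np.linalg.norm(f[:, :2], axis=1), 2.0, rtol=1e-3)
        assert np.allclose(f[:, 2], 9.81, atol=1e-9)

    def test_second_order_convergence(self):
        # halving dt reduces the error vs the analytic circular case ~4×
        errs = []
        for rate in (100.0, 200.0):
            t = np.arange(0, 2.0, 1.0 / rate)
            p = 0.5 * np.column_stack([np.cos(2 * t), np.sin(2 * t), 0 * t])
            pose = PoseSequence(rate, quat.identity(len(t)), p)
            f = simulate_accel(pose)[10:-10]
            errs.append(np.abs(np.linalg.norm(f[:, :2], axis=1) - 2.0).max())
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)
        w_errs = []
        for rate in (100.0, 200.0):
            w = angular_rate(spin_z(rate=rate, omega=2.0))[10:-10]
            w_errs.append(np.abs(w[:, 2] - 2.0).max())
        assert w_errs[0] / w_errs[1] == pytest.approx(4.0, rel=0.15)


class TestSimulateIMU:
    def test_static_any_placement(self, rng):
        pose = PoseSequence(100.0, quat.identity(30), np.ones((30, 3)))
        pl = SensorPlacement(
            "shank_L", offset_t=rng.uniform(-0.1, 0.1, 3),
            offset_q=quat.from_axis_angle(rng.normal(size=3), 0.5),
        )
        sig = simulate_imu(pose, pl)
        assert np.allclose(sig.gyro, 0.0, atol=1e-10)
        assert np.allclose(np.linalg.norm(sig.accel, axis=1), 9.81, atol=1e-8)

    def test_rotated_placements_related_by_frame_change(self, rng):
        pose = random_smooth_pose(rate=200.0, seed=5)
        q_extra = quat.from_axis_angle(rng.normal(size=3), 0.8)
        a = simulate_imu(pose, SensorPlacement("thigh_L"))
        b = simulate_imu(
            pose, SensorPlacement("thigh_L", offset_q=q_extra)
        )
        # signals of b expressed back in a's frame must match a
        back = quat.qrotate(q_extra, b.gyro)
        assert np.allclose(back, a.gyro, atol=1e-9)
        back_acc = quat.qrotate(q_extra, b.accel)
        assert np.allclose(back_acc, a.accel, atol=1e-9)

    def test_global_rotation_equivariance(self, rng):
        # body-frame outputs are unchanged when all poses rotate globally
        pose = random_smooth_pose(rate=200.0, seed=6)
        pl = SensorPlacement("pelvis", offset_t=[0.05, 0.02, -0.01],
                             offset_q=quat.from_axis_angle([0, 1, 0], 0.3))
        g_rot = quat.from_axis_angle(rng.normal(size=3), 1.1)
        rotated = PoseSequence(
            pose.rate,
            quat.qmult(np.tile(g_rot, (len(pose), 1)), pose.orientations),
            quat.qrotate(g_rot, pose.origins),
        )
        a = simulate_imu(pose, pl)
        b = simulate_imu(rotated, pl, g_vec=quat.qrotate(g_rot, rigid.GRAVITY))
        assert np.abs(a.gyro - b.gyro).max() < 1e-9
        assert np.abs(a.accel - b.accel).max() < 1e-7


class TestJointDecomposition:
    def test_identical_poses_identity_relative(self):
        pose = spin_z()
        q_rel = relative_orientation(pose, pose)
        assert np.allclose(q_rel, [1, 0, 0, 0], atol=1e-12)

    def test_child_rotated_about_x(self):
        n = 10
        parent = PoseSequence(100.0, quat.identity(n), np.zeros((n, 3)))
        alpha = 0.6
        child_q = np.tile(quat.from_axis_angle([1, 0, 0], alpha), (n, 1))
        child = PoseSequence(100.0, child_q, np.zeros((n, 3)))
        q_rel = relative_orientation(parent, child)
        assert np.allclose(q_rel[0], quat.from_axis_angle([1, 0, 0], alpha),
                           atol=1e-12)

    def test_relative_matches_matrix_oracle(self, rng):
        a = random_smooth_pose(rate=100.0, duration=0.1, seed=1)
        b = random_smooth_pose(rate=100.0, duration=0.1, seed=2)
        q_rel = relative_orientation(a, b)
        R = quat.to_matrix(q_rel)
        oracle = np.einsum(
            "nji,njk->nik",
            quat.to_matrix(a.orientations),
            quat.to_matrix(b.orientations),
        )
        assert np.abs(R - oracle).max() < 1e-9

    def test_length_mismatch_rejected(self):
        a = spin_z(duration=1.0)
        b = spin_z(duration=2.0)
        with pytest.raises(ValueError):
            relative_orientation(a, b)

    def test_cardan_identity_and_single_axis(self):
        ang, flags = cardan_angles(np.array([[1.0, 0, 0, 0]]))
        assert np.allclose(ang, 0.0) and not flags.any()
        q = cardan_to_quat(np.array([[30.0, 0.0, 0.0]]))
        ang, _ = cardan_angles(q)
        assert np.allclose(ang, [[30.0, 0.0, 0.0]], atol=1e-9)

    def test_cardan_round_trip_random(self, rng):
        angles = rng.uniform(-60, 60, (50, 3))
        angles[:, 1] = rng.uniform(-45, 45, 50)  # stay clear of gimbal lock
        q = cardan_to_quat(angles)
        R1 = quat.to_matrix(q)
        back, flags = cardan_angles(q)
        R2 = quat.to_matrix(cardan_to_quat(back))
        assert np.abs(R1 - R2).max() < 1e-9
        assert not flags.any()
        assert np.allclose(back, angles, atol=1e-6)

    def test_gimbal_proximity_flagged(self):
        q = cardan_to_quat(np.array([[10.0, 89.5, 5.0]]))
        _, flags = cardan_angles(q)
        assert flags.all()


class TestAugment:
    def _segments(self):
        pose = spin_z()
        return {seg: pose for seg in rigid.SEGMENTS}

    def _library(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [
            {
                seg: SensorPlacement(seg, offset_t=rng.uniform(-0.03, 0.03, 3))
                for seg in rigid.SEGMENTS
            }
            for _ in range(n)
        ]

    def test_library_of_23_yields_23_trials(self):
        out = augment(self._segments(), self._library(23))
        assert len(out) == 23
        assert all(set(t) == set(rigid.SEGMENTS) for t in out)

    def test_identity_library_equals_direct_simulation(self):
        segs = self._segments()
        out = augment(segs, [{s: SensorPlacement(s) for s in rigid.SEGMENTS}])
        direct = simulate_imu(segs["pelvis"], SensorPlacement("pelvis"))
        assert np.array_equal(out[0]["pelvis"].accel, direct.accel)
        assert np.array_equal(out[0]["pelvis"].gyro, direct.gyro)

    def test_duplicate_entries_bitwise_identical(self):
        lib = self._library(1)
        out = augment(self._segments(), lib + lib)
        assert np.array_equal(out[0]["shank_R"].accel, out[1]["shank_R"].accel)

    def test_missing_segment_rejected(self):
        lib = self._library(1)
        del lib[0]["pelvis"]
        with pytest.raises(ValueError, match="missing"):
            augment(self._segments(), lib)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            augment(self._segments(), [])


def test_imusignal_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        IMUSignal(100.0, np.zeros((5, 3)), np.zeros((4, 3)))


def test_placement_offset_bound():
    with pytest.raises(ValueError):
        SensorPlacement("pelvis", offset_t=[0.6, 0, 0])
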