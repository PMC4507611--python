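"""Quaternion algebra, Euler conversions and the fusion filter."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trunklab import synth
from trunklab.orientation import (FilterConfig, ImuSample,
                                  InvalidQuaternionError, EmptyStreamError,
                                  euler_to_quaternion, fusion_update,
                                  normalize_quaternion, quaternion_conjugate,
                                  quaternion_multiply, quaternion_to_euler,
                                  rotate_vector, trunk_angle_stream)

DT = 1.0 / 51.2

unit_angles = st.floats(-179.0, 179.0)


def axis_quaternion(angle_deg: float, axis: int) -> np.ndarray:
    """Closed-form unit quaternion for a rotation about one cardinal axis."""
    half = np.radians(angle_deg) / 2.0
    q = np.zeros(4)
    q[0] = np.cos(half)
    q[1 + axis] = np.sin(half)
    return q


class TestQuaternionAlgebra:
    @pytest.mark.parametrize("q,expected", [
        ((2, 0, 0, 0), (1, 0, 0, 0)),
        ((0, 3, 4, 0), (0, 0.6, 0.8, 0)),
    ])
    def test_normalize(self, q, expected):
        assert np.allclose(normalize_quaternion(q), expected)

    def test_normalize_zero_raises(self):
        with pytest.raises(InvalidQuaternionError):
            normalize_quaternion((0, 0, 0, 0))

    def test_identity_is_neutral(self):
        q = normalize_quaternion((0.3, -0.5, 0.7, 0.1))
        assert np.allclose(quaternion_multiply([1, 0, 0, 0], q), q)
        assert np.allclose(quaternion_multiply(q, [1, 0, 0, 0]), q)

    def test_conjugate_inverts_unit_quaternion(self):
        q = normalize_quaternion((0.3, -0.5, 0.7, 0.1))
        assert np.allclose(quaternion_multiply(q, quaternion_conjugate(q)),
                           [1, 0, 0, 0], atol=1e-12)

    def test_two_half_turns_compose(self):
        # two 45-degree Z rotations equal one 90-degree Z rotation
        q45 = axis_quaternion(45.0, axis=2)
        q90 = axis_quaternion(90.0, axis=2)
        assert np.allclose(quaternion_multiply(q45, q45), q90, atol=1e-12)

    @given(st.lists(st.floats(-5, 5), min_size=8, max_size=8))
    def test_norm_multiplicativity(self, vals):
        a, b = np.array(vals[:4]), np.array(vals[4:])
        prod = quaternion_multiply(a, b)
        assert np.isclose(np.linalg.norm(prod),
                          np.linalg.norm(a) * np.linalg.norm(b), atol=1e-9)


class TestEulerConversion:
    def test_identity(self):
        e = quaternion_to_euler((1, 0, 0, 0))
        assert e.as_tuple() == (0.0, 0.0, 0.0)

    def test_pure_roll_rotation(self):
        e = quaternion_to_euler(axis_quaternion(90.0, axis=0))
        assert np.allclose(e.as_tuple(), (0.0, 0.0, 90.0), atol=1e-9)

    def test_zero_angles_to_identity(self):
        assert np.allclose(euler_to_quaternion((0, 0, 0)), [1, 0, 0, 0])

    def test_antipodal_roll_equivalence(self):
        qa = euler_to_quaternion((0, 0, 180.0))
        qb = euler_to_quaternion((0, 0, -180.0))
        assert np.allclose(qa, qb, atol=1e-12) or np.allclose(qa, -qb, atol=1e-12)

    @given(yaw=unit_angles, pitch=st.floats(-89.0, 89.0), roll=unit_angles)
    def test_round_trip(self, yaw, pitch, roll):
        e = quaternion_to_euler(euler_to_quaternion((yaw, pitch, roll)))
        assert np.allclose(e.as_tuple(), (yaw, pitch, roll), atol=1e-6)

    def test_gimbal_lock_clamps(self):
        e = quaternion_to_euler(euler_to_quaternion((0, 90.0, 0)))
        assert abs(e.pitch - 90.0) < 1e-6


class TestFusionUpdate:
    def test_gravity_aligned_identity_is_fixed_point(self):
        cfg = FilterConfig(gain=0.1)
        s = ImuSample(0.0, [0, 0, 9.80665], [0, 0, 0], [0, 0, 0])
        q = fusion_update([1, 0, 0, 0], s, cfg, DT)
        assert np.allclose(q, [1, 0, 0, 0], atol=1e-9)

    def test_zero_gain_matches_closed_form_integration(self):
        # constant rate pi/2 rad/s about Z for 1 s in 512 steps
        cfg = FilterConfig(gain=0.0)
        omega = np.pi / 2
        q = np.array([1.0, 0, 0, 0])
        s = ImuSample(0.0, [0, 0, 9.80665], [0, 0, omega], [0, 0, 0])
        for _ in range(512):
            q = fusion_update(q, s, cfg, 1.0 / 512)
        oracle = axis_quaternion(np.degrees(omega), axis=2)
        angle_err = np.degrees(2 * np.arccos(np.clip(abs(np.dot(q, oracle)), 0, 1)))
        assert angle_err <= 0.1
        assert abs(quaternion_to_euler(q).yaw - 90.0) <= 0.1

    @pytest.mark.parametrize("use_mag", [False, True])
    def test_static_convergence_to_accelerometer_tilt(self, use_mag):
        tilt = 30.0  # degrees about X; arctan oracle: roll = tilt
        cfg = FilterConfig(gain=0.1, use_magnetometer=use_mag)
        q_true = euler_to_quaternion((0, 0, tilt))
        accel = rotate_vector(q_true, [0, 0, 9.80665])
        mag = rotate_vector(q_true, synth.MAG_REFERENCE)
        s = ImuSample(0.0, accel, [0, 0, 0], mag)
        q = np.array([1.0, 0, 0, 0])
        for _ in range(2000):
            q = fusion_update(q, s, cfg, DT)
        assert abs(quaternion_to_euler(q).roll - tilt) <= 0.5

    def test_unit_norm_invariant(self, rng):
        cfg = FilterConfig(gain=0.2)
        q = np.array([1.0, 0, 0, 0])
        for i in range(200):
            s = ImuSample(i * DT, rng.normal(0, 3, 3) + [0, 0, 9.8],
                          rng.normal(0, 1, 3), rng.normal(0, 1, 3))
            q = fusion_update(q, s, cfg, DT)
            assert abs(np.linalg.norm(q) - 1.0) < 1e-9

    def test_zero_accel_skips_correction(self):
        cfg = FilterConfig(gain=0.5)
        s = ImuSample(0.0, [0, 0, 0], [0, 0, 0], [0, 0, 0])
        q0 = normalize_quaternion((0.9, 0.1, 0.2, 0.3))
        assert np.allclose(fusion_update(q0, s, cfg, DT), q0, atol=1e-12)


class TestTrunkAngleStream:
    def test_static_gravity_aligned_stream(self):
        samples = [ImuSample(i * DT, [0, 0, 9.80665], [0, 0, 0], [0, 0, 0])
                   for i in range(100)]
        angles = trunk_angle_stream(samples)
        assert all(abs(roll) < 1e-6 for _, roll in angles)

    def test_empty_stream_raises(self):
        with pytest.raises(EmptyStreamError):
            trunk_angle_stream([])

    def test_roll_invariant_to_accel_rescaling(self):
        sc = synth.PostureScenario(initial_roll=20.0, hold_duration=2.0,
                                   droop_rate=5.0, tremor_sd=0.0, seed=7)
        traj = synth.simulate_trajectory(sc, 4.0)
        imu = synth.synthesize_imu(traj)
        scaled = [ImuSample(s.t, s.accel * 3.7, s.gyro, s.mag) for s in imu]
        a1 = trunk_angle_stream(imu)
        a2 = trunk_angle_stream(scaled)
        assert np.allclose([r for _, r in a1], [r for _, r in a2], atol=1e-9)

    def test_tracks_hold_then_ramp_trajectory(self):
        # hold 30 degrees then ramp toward 45; roll must track within 1 degree
        sc = synth.PostureScenario(initial_roll=30.0, hold_duration=4.0,
                                   droop_rate=5.0, tremor_sd=0.0, seed=3)
        traj = synth.simulate_trajectory(sc, 7.0)
        angles = trunk_angle_stream(synth.synthesize_imu(traj))
        skip = int(1.0 / DT)  # convergence window
        err = np.abs(np.array([r for _, r in angles])[skip:] - traj[skip:, 3])
        assert err.max() <= 1.0

    def test_nan_accel_sample_preserves_length(self):
        samples = [ImuSample(i * DT, [0, 0, 9.80665], [0, 0, 0], [0, 0, 0])
                   for i in range(50)]
        samples[25] = ImuSample(25 * DT, [np.nan, 0, 9.8], [0, 0, 0], [0, 0, 0])
        angles = trunk_angle_stream(samples)
        assert len(angles) == 50
        assert all(np.isfinite(roll) for _, roll in angles)
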