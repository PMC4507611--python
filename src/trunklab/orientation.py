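"""Attitude estimation from inertial/magnetic sensor streams.

The trunk angle used by the endurance-test timer is the roll component of the
sensor attitude.  Attitude is estimated by a gradient-descent complementary
filter: angular rate is integrated through quaternion kinematics and, at each
step, the estimate is nudged toward the orientation that best explains the
measured gravity direction (and, optionally, the magnetic field direction).
This is the quaternion gradient-descent scheme widely used for small wearable
IMU/MARG units; it avoids Euler-angle singularities and needs no trigonometric
evaluation inside the update loop.

Conventions
-----------
* Quaternions are scalar-first unit 4-vectors ``(q1, q2, q3, q4)`` with
  ``q1`` the scalar part, representing the rotation from the Earth frame to
  the sensor frame.
* Earth frame: Z up, gravity along -Z; a resting accelerometer reads ``+g``
  along its body Z axis when level.
* Euler angles follow the aerospace Z-Y-X sequence: yaw about Z, then pitch
  about Y, then roll about X, reported in degrees.  Roll is the trunk angle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ImuSample",
    "EulerAngles",
    "FilterConfig",
    "InvalidQuaternionError",
    "EmptyStreamError",
    "normalize_quaternion",
    "quaternion_multiply",
    "quaternion_conjugate",
    "rotate_vector",
    "fusion_update",
    "quaternion_to_euler",
    "euler_to_quaternion",
    "tilt_quaternion_from_accel",
    "trunk_angle_stream",
]

logger = logging.getLogger(__name__)

GRAVITY = 9.80665  # m/s^2, standard gravity

IDENTITY_QUATERNION = np.array([1.0, 0.0, 0.0, 0.0])


class InvalidQuaternionError(ValueError):
    """Raised for zero-norm or non-finite quaternion input."""


class EmptyStreamError(ValueError):
    """Raised when an operation receives an empty sample stream."""


@dataclass(frozen=True)
class ImuSample:
    """One timestamped inertial/magnetic reading.

    Parameters
    ----------
    t : float
        Seconds since stream start; strictly increasing within a stream.
    accel : array-like of 3 floats
        Specific force, m/s^2 (reads +g on body Z at rest, level).
    gyro : array-like of 3 floats
        Angular rate, rad/s, body frame.
    mag : array-like of 3 floats
        Magnetic field in consistent arbitrary units (only its direction is
        used).
    """

    t: float
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "accel", np.asarray(self.accel, dtype=float))
        object.__setattr__(self, "gyro", np.asarray(self.gyro, dtype=float))
        object.__setattr__(self, "mag", np.asarray(self.mag, dtype=float))


@dataclass(frozen=True)
class EulerAngles:
    """Aerospace Z-Y-X Euler angles in degrees.

    yaw, roll in (-180, 180]; pitch in [-90, 90].
    """

    yaw: float
    pitch: float
    roll: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.yaw, self.pitch, self.roll)


@dataclass(frozen=True)
class FilterConfig:
    """Fusion filter settings.

    ``gain`` (beta) scales the gradient-descent correction toward the field
    observations, in rad/s of correction authority; 0 reduces the filter to
    pure gyro integration.  ``sample_rate`` is the nominal stream rate used
    when timestamps are unavailable.
    """

    gain: float = 0.1
    sample_rate: float = 51.2
    use_magnetometer: bool = True

    def __post_init__(self):
        if self.gain < 0:
            raise ValueError("filter gain must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


# ---------------------------------------------------------------------------
# Quaternion algebra
# ---------------------------------------------------------------------------

def normalize_quaternion(q: Sequence[float]) -> np.ndarray:
    """Scale a quaternion to unit norm, preserving direction.

    Raises
    ------
    InvalidQuaternionError
        If the input has zero norm or non-finite components.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise InvalidQuaternionError(f"expected 4 components, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise InvalidQuaternionError("quaternion has non-finite components")
    n = np.linalg.norm(q)
    if n == 0.0:
        raise InvalidQuaternionError("cannot normalize zero quaternion")
    return q / n


def quaternion_multiply(a: Sequence[float], b: Sequence[float]) -> np.ndarray:
    """Hamilton product a ⊗ b (scalar-first)."""
    a1, a2, a3, a4 = np.asarray(a, dtype=float)
    b1, b2, b3, b4 = np.asarray(b, dtype=float)
    return np.array([
        a1 * b1 - a2 * b2 - a3 * b3 - a4 * b4,
        a1 * b2 + a2 * b1 + a3 * b4 - a4 * b3,
        a1 * b3 - a2 * b4 + a3 * b1 + a4 * b2,
        a1 * b4 + a2 * b3 - a3 * b2 + a4 * b1,
    ])


def quaternion_conjugate(q: Sequence[float]) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def rotate_vector(q: Sequence[float], v: Sequence[float]) -> np.ndarray:
    """Rotate Earth-frame vector ``v`` into the sensor frame of ``q``.

    ``q`` encodes Earth->sensor, so the sensor-frame view of an Earth-fixed
    vector is q* ⊗ (0, v) ⊗ q.
    """
    vq = np.concatenate(([0.0], np.asarray(v, dtype=float)))
    out = quaternion_multiply(quaternion_multiply(quaternion_conjugate(q), vq), q)
    return out[1:]


# ---------------------------------------------------------------------------
# Euler conversions (aerospace Z-Y-X, scalar-first)
# ---------------------------------------------------------------------------

def quaternion_to_euler(q: Sequence[float]) -> EulerAngles:
    """Convert a unit quaternion to Z-Y-X Euler angles in degrees.

    The arcsin argument for pitch is clamped to [-1, 1], so gimbal-lock
    configurations degrade gracefully instead of raising.
    """
    q1, q2, q3, q4 = normalize_quaternion(q)
    yaw = np.degrees(np.arctan2(2.0 * (q1 * q4 + q2 * q3),
                                1.0 - 2.0 * (q3 * q3 + q4 * q4)))
    pitch = np.degrees(np.arcsin(np.clip(2.0 * (q1 * q3 - q4 * q2), -1.0, 1.0)))
    roll = np.degrees(np.arctan2(2.0 * (q1 * q2 + q3 * q4),
                                 1.0 - 2.0 * (q2 * q2 + q3 * q3)))
    return EulerAngles(yaw=float(yaw), pitch=float(pitch), roll=float(roll))


def euler_to_quaternion(e: EulerAngles | Sequence[float]) -> np.ndarray:
    """Inverse of :func:`quaternion_to_euler` away from gimbal lock.

    Accepts an :class:`EulerAngles` or a (yaw, pitch, roll) triple in degrees.
    """
    if isinstance(e, EulerAngles):
        yaw, pitch, roll = e.as_tuple()
    else:
        yaw, pitch, roll = e
    hy, hp, hr = (np.radians(a) / 2.0 for a in (yaw, pitch, roll))
    cy, sy = np.cos(hy), np.sin(hy)
    cp, sp = np.cos(hp), np.sin(hp)
    cr, sr = np.cos(hr), np.sin(hr)
    return np.array([
        cy * cp * cr + sy * sp * sr,
        cy * cp * sr - sy * sp * cr,
        cy * sp * cr + sy * cp * sr,
        sy * cp * cr - cy * sp * sr,
    ])


def tilt_quaternion_from_accel(accel: Sequence[float]) -> np.ndarray:
    """Roll/pitch attitude consistent with a static accelerometer reading.

    Yaw is set to zero (gravity carries no heading information).  Returns the
    identity if the reading has zero norm.
    """
    a = np.asarray(accel, dtype=float)
    n = np.linalg.norm(a)
    if n == 0.0 or not np.all(np.isfinite(a)):
        return IDENTITY_QUATERNION.copy()
    ax, ay, az = a / n
    roll = np.degrees(np.arctan2(ay, az))
    pitch = np.degrees(np.arctan2(-ax, np.hypot(ay, az)))
    return euler_to_quaternion((0.0, pitch, roll))


# ---------------------------------------------------------------------------
# Fusion filter
# ---------------------------------------------------------------------------

def _gradient_step(q: np.ndarray, accel: np.ndarray, mag: np.ndarray | None) -> np.ndarray | None:
    """Normalized gradient of the field-alignment objective, or None if the
    accelerometer gives no usable direction."""
    a_norm = np.linalg.norm(accel)
    if a_norm == 0.0 or not np.all(np.isfinite(accel)):
        return None
    ax, ay, az = accel / a_norm
    q1, q2, q3, q4 = q

    # Gravity objective: sensor-frame view of Earth +Z must match accel.
    f_g = np.array([
        2.0 * (q2 * q4 - q1 * q3) - ax,
        2.0 * (q1 * q2 + q3 * q4) - ay,
        2.0 * (0.5 - q2 * q2 - q3 * q3) - az,
    ])
    j_g = np.array([
        [-2.0 * q3, 2.0 * q4, -2.0 * q1, 2.0 * q2],
        [2.0 * q2, 2.0 * q1, 2.0 * q4, 2.0 * q3],
        [0.0, -4.0 * q2, -4.0 * q3, 0.0],
    ])
    grad = j_g.T @ f_g

    if mag is not None:
        m_norm = np.linalg.norm(mag)
        if m_norm > 0.0 and np.all(np.isfinite(mag)):
            mx, my, mz = mag / m_norm
            # Earth-frame field from the current estimate, flattened to the
            # XZ plane so magnetic disturbance only affects heading.
            h = rotate_vector(quaternion_conjugate(q), [mx, my, mz])
            bx = float(np.hypot(h[0], h[1]))
            bz = float(h[2])
            f_b = np.array([
                2.0 * bx * (0.5 - q3 * q3 - q4 * q4)
                + 2.0 * bz * (q2 * q4 - q1 * q3) - mx,
                2.0 * bx * (q2 * q3 - q1 * q4)
                + 2.0 * bz * (q1 * q2 + q3 * q4) - my,
                2.0 * bx * (q1 * q3 + q2 * q4)
                + 2.0 * bz * (0.5 - q2 * q2 - q3 * q3) - mz,
            ])
            j_b = np.array([
                [-2.0 * bz * q3,
                 2.0 * bz * q4,
                 -4.0 * bx * q3 - 2.0 * bz * q1,
                 -4.0 * bx * q4 + 2.0 * bz * q2],
                [-2.0 * bx * q4 + 2.0 * bz * q2,
                 2.0 * bx * q3 + 2.0 * bz * q1,
                 2.0 * bx * q2 + 2.0 * bz * q4,
                 -2.0 * bx * q1 + 2.0 * bz * q3],
                [2.0 * bx * q3,
                 2.0 * bx * q4 - 4.0 * bz * q2,
                 2.0 * bx * q1 - 4.0 * bz * q3,
                 2.0 * bx * q2],
            ])
            grad = grad + j_b.T @ f_b

    g_norm = np.linalg.norm(grad)
    if g_norm == 0.0:
        return np.zeros(4)
    return grad / g_norm


def fusion_update(state: Sequence[float], s: ImuSample, cfg: FilterConfig,
                  dt: float) -> np.ndarray:
    """Advance the attitude estimate by one sample.

    Integrates the gyroscope through quaternion kinematics and applies a
    gradient-descent correction of magnitude ``cfg.gain * dt`` toward the
    attitude implied by the accelerometer (and magnetometer when enabled).
    A zero-norm or non-finite accelerometer reading skips the correction for
    that sample rather than failing.

    Returns a unit quaternion.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    q = normalize_quaternion(state)

    omega = np.asarray(s.gyro, dtype=float)
    q_dot = 0.5 * quaternion_multiply(q, np.concatenate(([0.0], omega)))

    if cfg.gain > 0.0:
        mag = s.mag if cfg.use_magnetometer else None
        step = _gradient_step(q, np.asarray(s.accel, dtype=float), mag)
        if step is None:
            logger.debug("unusable accelerometer sample at t=%.4f; "
                         "correction skipped", s.t)
        else:
            q_dot = q_dot - cfg.gain * step

    return normalize_quaternion(q + q_dot * dt)


def trunk_angle_stream(samples: Iterable[ImuSample],
                       cfg: FilterConfig | None = None,
                       initial_state: Sequence[float] | None = None,
                       ) -> list[tuple[float, float]]:
    """Run the fusion filter over a stream and emit ``(t, roll_deg)`` pairs.

    The filter state is threaded through the stream; ``dt`` comes from
    consecutive timestamps with ``1/cfg.sample_rate`` as fallback for the
    first sample (or non-increasing timestamps).  Unless ``initial_state`` is
    given, the state is initialized from the accelerometer tilt of the first
    sample, which removes most of the static convergence transient.

    Raises
    ------
    EmptyStreamError
        If the stream contains no samples.
    """
    cfg = cfg or FilterConfig()
    samples = list(samples)
    if not samples:
        raise EmptyStreamError("trunk_angle_stream requires at least one sample")

    if initial_state is not None:
        q = normalize_quaternion(initial_state)
    else:
        q = tilt_quaternion_from_accel(samples[0].accel)

    fallback_dt = 1.0 / cfg.sample_rate
    out: list[tuple[float, float]] = []
    prev_t: float | None = None
    for s in samples:
        dt = fallback_dt
        if prev_t is not None and s.t > prev_t:
            dt = s.t - prev_t
        q = fusion_update(q, s, cfg, dt)
        out.append((float(s.t), quaternion_to_euler(q).roll))
        prev_t = s.t
    return out
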