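"""Synthetic posture, inertial, EMG and paired-study generators.

Every other module is testable against known ground truth through these
generators, without hardware:

* a posture trajectory that holds an initial trunk roll (with optional
  physiological tremor) and then droops at a constant rate — the kinematics
  of a subject failing an isometric endurance hold;
* an inverse sensor model turning that trajectory into accelerometer,
  gyroscope and magnetometer streams (gravity and a fixed magnetic field
  rotated into the sensor frame, finite-difference body rates, additive
  Gaussian noise);
* a zero-mean EMG amplitude process whose instantaneous RMS grows linearly
  with time, mimicking the amplitude increase of a fatiguing isometric
  contraction;
* a one-way random-effects paired study with known true ICC, for
  parameter-recovery experiments.

All generators are bit-reproducible given (scenario, seed): randomness comes
from a ``numpy.random.default_rng`` (PCG64) seeded per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orientation import (GRAVITY, ImuSample, euler_to_quaternion,
                          quaternion_conjugate, quaternion_multiply,
                          rotate_vector)
from .reliability import PairedMeasurements

__all__ = [
    "PostureScenario",
    "EmgScenario",
    "MAG_REFERENCE",
    "simulate_trajectory",
    "synthesize_imu",
    "simulate_emg",
    "simulate_paired_study",
    "true_icc_oneway",
]

# Earth magnetic field direction: unit vector with 50 degree inclination
# (pointing north and down, Z-up frame).
MAG_REFERENCE = np.array([np.cos(np.radians(50.0)), 0.0, -np.sin(np.radians(50.0))])


@dataclass(frozen=True)
class PostureScenario:
    """A hold-then-droop posture: roll stays near ``initial_roll`` degrees
    for ``hold_duration`` s, then drifts at ``droop_rate`` deg/s.  ``tremor_sd``
    adds zero-mean Gaussian jitter to the held angle."""

    initial_roll: float = 0.0
    hold_duration: float = 60.0
    droop_rate: float = 15.0
    tremor_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.hold_duration < 0:
            raise ValueError("hold_duration must be >= 0")
        if self.droop_rate < 0:
            raise ValueError("droop_rate must be >= 0")

    def crossing_time(self, tolerance: float) -> float:
        """Time at which the noise-free roll first exceeds the reference by
        more than ``tolerance`` degrees (inf if it never droops)."""
        if self.droop_rate == 0:
            return np.inf
        return self.hold_duration + tolerance / self.droop_rate


@dataclass(frozen=True)
class EmgScenario:
    """Zero-mean EMG process with RMS = baseline + slope * t (mV, mV/s)."""

    baseline_rms: float = 0.05
    fatigue_slope: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_rms <= 0:
            raise ValueError("baseline_rms must be > 0")


def simulate_trajectory(sc: PostureScenario, duration: float,
                        sample_rate: float = 51.2) -> np.ndarray:
    """Ground-truth Euler trajectory, array of (t, yaw, pitch, roll) rows.

    Roll holds at ``initial_roll`` (plus tremor) for ``hold_duration`` and
    then ramps at ``droop_rate`` deg/s; yaw and pitch carry a tenth of the
    tremor so the orientation problem stays genuinely three-dimensional.
    Deterministic per scenario seed.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    rng = np.random.default_rng(sc.seed)
    n = max(1, int(round(duration * sample_rate)))
    t = np.arange(n) / sample_rate
    roll = np.full(n, float(sc.initial_roll))
    drooping = t > sc.hold_duration
    roll[drooping] += sc.droop_rate * (t[drooping] - sc.hold_duration)
    if sc.tremor_sd > 0:
        roll += rng.normal(0.0, sc.tremor_sd, n)
    small = sc.tremor_sd / 10.0
    yaw = rng.normal(0.0, small, n) if small > 0 else np.zeros(n)
    pitch = rng.normal(0.0, small, n) if small > 0 else np.zeros(n)
    return np.column_stack([t, yaw, pitch, roll])


def synthesize_imu(trajectory: np.ndarray, sample_rate: float = 51.2,
                   accel_noise_sd: float = 0.0, gyro_noise_sd: float = 0.0,
                   mag_noise_sd: float = 0.0, seed: int = 0,
                   ) -> list[ImuSample]:
    """Inverse sensor model: attitude trajectory -> IMU sample stream.

    Accelerometer reads the attitude-rotated gravity reaction (+g on body Z
    when level), the gyroscope the finite-difference body angular rate, and
    the magnetometer the attitude-rotated reference field, each plus
    independent Gaussian noise.  With all noise SDs zero the output is
    independent of the seed.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.size == 0:
        raise ValueError("trajectory must be non-empty")
    rng = np.random.default_rng(seed)
    t = trajectory[:, 0]
    quats = [euler_to_quaternion(row[1:4]) for row in trajectory]

    samples: list[ImuSample] = []
    for i, (ti, q) in enumerate(zip(t, quats)):
        accel = rotate_vector(q, [0.0, 0.0, GRAVITY])
        mag = rotate_vector(q, MAG_REFERENCE)
        if i + 1 < len(quats):
            dt = t[i + 1] - ti if t[i + 1] > ti else 1.0 / sample_rate
            dq = (quats[i + 1] - q) / dt
        elif i > 0:
            dt = ti - t[i - 1] if ti > t[i - 1] else 1.0 / sample_rate
            dq = (q - quats[i - 1]) / dt
        else:
            dq = np.zeros(4)
        # body rate from kinematics: q_dot = 0.5 q (0, omega)
        omega = 2.0 * quaternion_multiply(quaternion_conjugate(q), dq)[1:]
        if accel_noise_sd > 0:
            accel = accel + rng.normal(0.0, accel_noise_sd, 3)
        if gyro_noise_sd > 0:
            omega = omega + rng.normal(0.0, gyro_noise_sd, 3)
        if mag_noise_sd > 0:
            mag = mag + rng.normal(0.0, mag_noise_sd, 3)
        samples.append(ImuSample(t=float(ti), accel=accel, gyro=omega, mag=mag))
    return samples


def simulate_emg(sc: EmgScenario, duration: float,
                 sample_rate: float = 51.2) -> np.ndarray:
    """EMG trace as (t, mV) rows with RMS(t) = baseline + slope * t."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(sc.seed)
    n = max(1, int(round(duration * sample_rate)))
    t = np.arange(n) / sample_rate
    sd = np.maximum(sc.baseline_rms + sc.fatigue_slope * t, 0.0)
    return np.column_stack([t, rng.normal(0.0, 1.0, n) * sd])


def true_icc_oneway(sigma_between: float, sigma_within: float,
                    k: int = 2) -> tuple[float, float]:
    """Population (single, average) ICC of the one-way random model."""
    sb2, sw2 = sigma_between ** 2, sigma_within ** 2
    if sb2 + sw2 == 0:
        raise ValueError("at least one variance must be positive")
    single = sb2 / (sb2 + sw2)
    average = k * single / (1.0 + (k - 1) * single)
    return single, average


def simulate_paired_study(n: int, sigma_between: float, sigma_within: float,
                          mean: float = 80.0, seed: int = 0,
                          ) -> tuple[PairedMeasurements, float, float]:
    """Draw a paired study from the one-way random-effects model.

    Subject true values are Normal(mean, sigma_between^2); each method
    observes truth + Normal(0, sigma_within^2) independently.  Returns the
    measurements together with the population single- and average-measures
    ICC implied by the variance components.
    """
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    if sigma_between < 0 or sigma_within < 0:
        raise ValueError("variances must be >= 0")
    rng = np.random.default_rng(seed)
    truth = rng.normal(mean, sigma_between, n)
    a = truth + rng.normal(0.0, sigma_within, n)
    b = truth + rng.normal(0.0, sigma_within, n)
    pm = PairedMeasurements.from_arrays(a, b, label=f"simulated(n={n})")
    single, average = true_icc_oneway(sigma_between, sigma_within)
    return pm, single, average
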