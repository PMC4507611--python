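"""Endurance-test timing: reference capture, termination checks, attempts.

A test runs over a trunk-angle stream, ``(t, roll_deg)`` pairs from the
orientation filter.  When the examiner signals the start, the angle at that
moment becomes the reference; the attempt then runs until the trunk deviates
from the reference by strictly more than the protocol tolerance (10 degrees
for the Sorensen and side-bridge holds, 30 degrees for the trunk curl), the
hold exceeds 240 s, or the examiner stops it manually.  Reason priority when
simultaneous: manual > angle > max-duration.

The Sorensen protocol (STEET) allows a second attempt; its total duration is
the sum over attempts.  All timing uses stream timestamps, never wall clock,
so results are reproducible offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import emg as emg_mod
from .norms import CategoryBins, DEFAULT_BINS, MAX_DURATION_S

__all__ = [
    "TestProtocol",
    "AttemptResult",
    "TestResult",
    "PROTOCOLS",
    "TruncatedStreamError",
    "capture_reference",
    "check_termination",
    "run_attempt",
    "run_test",
]

AngleStream = Sequence[tuple[float, float]]


class TruncatedStreamError(RuntimeError):
    """The angle stream ended before any termination criterion fired."""

    def __init__(self, message: str, partial_duration: float):
        super().__init__(message)
        self.partial_duration = partial_duration


@dataclass(frozen=True)
class TestProtocol:
    """Protocol constants for one endurance test."""

    __test__ = False  # keep pytest from collecting this dataclass

    name: str
    angle_tolerance: float  # degrees, strict threshold
    max_duration: float = MAX_DURATION_S  # seconds, strict threshold
    attempts: int = 1
    plane: str = "coronal"

    def __post_init__(self):
        if self.angle_tolerance <= 0:
            raise ValueError("angle_tolerance must be > 0")


PROTOCOLS: dict[str, TestProtocol] = {
    "STEET": TestProtocol("STEET", angle_tolerance=10.0, attempts=2, plane="coronal"),
    "TCSET": TestProtocol("TCSET", angle_tolerance=30.0, attempts=1, plane="coronal"),
    "SBET_RIGHT": TestProtocol("SBET_RIGHT", angle_tolerance=10.0, attempts=1, plane="sagittal"),
    "SBET_LEFT": TestProtocol("SBET_LEFT", angle_tolerance=10.0, attempts=1, plane="sagittal"),
}


@dataclass(frozen=True)
class AttemptResult:
    reference_angle: float
    duration: float
    termination_reason: str  # angle_exceeded | max_duration | manual_stop


@dataclass
class TestResult:
    __test__ = False  # keep pytest from collecting this dataclass

    protocol: str
    attempts: list[AttemptResult]
    total_duration: float
    category: str | None = None
    fatigue: emg_mod.FatigueMetrics | None = None
    epoch_fatigue: list[tuple[float, emg_mod.FatigueMetrics]] = field(default_factory=list)


def _angle_deviation(current: float, reference: float) -> float:
    """Absolute roll deviation, wrap-aware across the +/-180 seam."""
    d = abs(current - reference) % 360.0
    return min(d, 360.0 - d)


def capture_reference(angle_stream: AngleStream, start_event_time: float) -> float:
    """Angle at (or nearest preceding sample to) the start event.

    Raises ``ValueError`` if the event precedes the first sample or follows
    the last.
    """
    if not angle_stream:
        raise ValueError("empty angle stream")
    if start_event_time < angle_stream[0][0] or start_event_time > angle_stream[-1][0]:
        raise ValueError(
            f"start event t={start_event_time} outside stream span "
            f"[{angle_stream[0][0]}, {angle_stream[-1][0]}]")
    ref = angle_stream[0][1]
    for t, angle in angle_stream:
        if t > start_event_time:
            break
        ref = angle
    return ref


def check_termination(protocol: TestProtocol, reference: float, current: float,
                      elapsed: float, manual_stop: bool = False,
                      ) -> tuple[bool, str | None]:
    """Evaluate the termination criteria at one instant.

    Returns ``(terminate, reason)``; both angle and time thresholds are
    strict ("more than"), and manual stop wins over simultaneous criteria.
    """
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    if manual_stop:
        return True, "manual_stop"
    if _angle_deviation(current, reference) > protocol.angle_tolerance:
        return True, "angle_exceeded"
    if elapsed > protocol.max_duration:
        return True, "max_duration"
    return False, None


def run_attempt(angle_stream: AngleStream, protocol: TestProtocol,
                start_time: float, manual_stop_time: float | None = None,
                ) -> AttemptResult:
    """Time one attempt: scan the stream from the start event to termination.

    Duration is the time of the first terminating sample minus the start
    time, capped at the protocol maximum.  Deterministic for fixed input.

    Raises
    ------
    TruncatedStreamError
        If the stream ends before any criterion fires; carries the partial
        duration observed so far.
    """
    reference = capture_reference(angle_stream, start_time)
    last_elapsed = 0.0
    for t, angle in angle_stream:
        if t < start_time:
            continue
        elapsed = t - start_time
        manual = manual_stop_time is not None and t >= manual_stop_time
        terminate, reason = check_termination(protocol, reference, angle,
                                              elapsed, manual_stop=manual)
        if terminate:
            return AttemptResult(reference_angle=reference,
                                 duration=min(elapsed, protocol.max_duration),
                                 termination_reason=reason)
        last_elapsed = elapsed
    raise TruncatedStreamError(
        f"angle stream ended after {last_elapsed:.2f} s without meeting a "
        f"termination criterion for {protocol.name}", last_elapsed)


def run_test(angle_streams: AngleStream | Sequence[AngleStream],
             protocol: TestProtocol | str,
             start_times: float | Sequence[float],
             emg_signal: Sequence[float] | None = None,
             emg_sample_rate: float = 51.2,
             epoch_len: float = 1.0,
             bins: CategoryBins = DEFAULT_BINS,
             manual_stop_times: Sequence[float | None] | None = None,
             ) -> TestResult:
    """Run a full test: one attempt per start event, protocol total rule.

    For the Sorensen test up to two attempts are accepted and the total is
    their sum (the second attempt is optional); other protocols take a single
    attempt.  EMG fatigue, when a signal is supplied, is summarized over the
    union of attempt windows.  The category lookup clips the total at the
    240 s scale maximum (a two-attempt Sorensen sum can exceed it).
    """
    if isinstance(protocol, str):
        protocol = PROTOCOLS[protocol.upper()]

    if isinstance(start_times, (int, float)):
        start_times = [float(start_times)]
    start_times = list(start_times)
    if len(start_times) > protocol.attempts:
        raise ValueError(
            f"{protocol.name} accepts at most {protocol.attempts} attempt(s), "
            f"got {len(start_times)} start events")

    # One shared stream, or one stream per attempt.
    if angle_streams and isinstance(angle_streams[0][0], (int, float)):
        streams = [angle_streams] * len(start_times)
    else:
        streams = list(angle_streams)
    if manual_stop_times is None:
        manual_stop_times = [None] * len(start_times)

    attempts = [run_attempt(stream, protocol, t0, manual_stop_time=ms)
                for stream, t0, ms in zip(streams, start_times, manual_stop_times)]
    total = sum(a.duration for a in attempts)

    result = TestResult(protocol=protocol.name, attempts=attempts,
                        total_duration=total)
    result.category = bins.lookup(protocol.name,
                                  min(total, protocol.max_duration))

    if emg_signal is not None and len(emg_signal) > 0:
        import numpy as np
        sig = np.asarray(emg_signal, dtype=float)
        windows = []
        for stream, t0, a in zip(streams, start_times, attempts):
            stream_t0 = stream[0][0]
            i0 = int(round((t0 - stream_t0) * emg_sample_rate))
            i1 = int(round((t0 - stream_t0 + a.duration) * emg_sample_rate))
            windows.append(sig[max(i0, 0):max(i1, 0)])
        joined = np.concatenate([w for w in windows if w.size]) if windows else sig
        if joined.size:
            result.fatigue = emg_mod.summarize(joined)
            result.epoch_fatigue = emg_mod.epoch_metrics(
                joined, epoch_len=epoch_len, sample_rate=emg_sample_rate)
    return result
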