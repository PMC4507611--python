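"""Surface-EMG amplitude metrics used as muscle-fatigue indices.

Three time-domain amplitude measures are computed per epoch of the recorded
signal: the root mean square (RMS), the average rectified value (ARV) and the
maximum contraction amplitude (MVC).  By the power-mean inequality the three
always satisfy ARV <= RMS <= MVC on the rectified signal, which the test
suite exploits as an invariant.

MVC is taken over the rectified signal by default, so a strongly
negative-going burst counts as a contraction peak; the raw (signed) maximum
is available via ``rectify_mvc=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EmgEpoch",
    "FatigueMetrics",
    "EmptyEpochError",
    "rms",
    "arv",
    "mvc",
    "epoch_metrics",
    "summarize",
]


class EmptyEpochError(ValueError):
    """Raised when a metric is requested on an empty epoch."""


@dataclass(frozen=True)
class EmgEpoch:
    """A contiguous window of EMG samples in mV starting at ``t_start`` s."""

    samples: np.ndarray
    t_start: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class FatigueMetrics:
    """Amplitude summary of one epoch: RMS, ARV and MVC, all in mV."""

    rms: float
    arv: float
    mvc: float


def _as_epoch(epoch: EmgEpoch | Sequence[float]) -> np.ndarray:
    x = epoch.samples if isinstance(epoch, EmgEpoch) else np.asarray(epoch, dtype=float)
    if x.size == 0:
        raise EmptyEpochError("EMG epoch contains no samples")
    return x


def rms(epoch: EmgEpoch | Sequence[float]) -> float:
    """Root mean square amplitude: sqrt(sum(EMG(k)^2)/N)."""
    x = _as_epoch(epoch)
    return float(np.sqrt(np.mean(np.square(x))))


def arv(epoch: EmgEpoch | Sequence[float]) -> float:
    """Average rectified value: sum(|EMG(k)|)/N."""
    x = _as_epoch(epoch)
    return float(np.mean(np.abs(x)))


def mvc(epoch: EmgEpoch | Sequence[float], rectify: bool = True) -> float:
    """Maximum contraction amplitude: max over the (rectified) epoch."""
    x = _as_epoch(epoch)
    return float(np.max(np.abs(x) if rectify else x))


def metrics(epoch: EmgEpoch | Sequence[float], rectify_mvc: bool = True) -> FatigueMetrics:
    """All three amplitude metrics of one epoch."""
    return FatigueMetrics(rms=rms(epoch), arv=arv(epoch),
                          mvc=mvc(epoch, rectify=rectify_mvc))


def epoch_metrics(signal: Sequence[float], epoch_len: float = 1.0,
                  sample_rate: float = 51.2, t0: float = 0.0,
                  rectify_mvc: bool = True,
                  demean: bool = False,
                  ) -> list[tuple[float, FatigueMetrics]]:
    """Metrics over consecutive non-overlapping epochs of a signal.

    The final partial epoch is kept only if it is at least half full.  A
    ``demean`` toggle subtracts the whole-signal mean first (off by default:
    the raw amplitudes are the clinical quantities).

    Returns a list of ``(t_start, FatigueMetrics)`` rows.
    """
    if epoch_len <= 0:
        raise ValueError("epoch_len must be > 0")
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise EmptyEpochError("signal contains no samples")
    if demean:
        x = x - x.mean()

    per_epoch = max(1, int(round(epoch_len * sample_rate)))
    rows: list[tuple[float, FatigueMetrics]] = []
    for start in range(0, x.size, per_epoch):
        chunk = x[start:start + per_epoch]
        if chunk.size < per_epoch and chunk.size < 0.5 * per_epoch:
            break
        rows.append((t0 + start / sample_rate,
                     metrics(chunk, rectify_mvc=rectify_mvc)))
    return rows


def summarize(signal: Sequence[float], rectify_mvc: bool = True,
              demean: bool = False) -> FatigueMetrics:
    """Whole-test amplitude summary over every sample of the signal."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise EmptyEpochError("signal contains no samples")
    if demean:
        x = x - x.mean()
    return metrics(x, rectify_mvc=rectify_mvc)
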