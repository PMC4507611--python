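"""Normative scoring of trunk endurance durations.

Published normal endurance times for young healthy adults anchor the
categories: the extensor (Sorensen) hold normally lasts 62-131 s, the trunk
curl averages 134 s, and the side bridge averages 84 s (SD 24.5 s).  From
these, each test maps a duration in [0, 240] s to a ``bad`` / ``good`` /
``perfect`` label, and two balance ratios are derived:

* flexor/extensor ratio (curl time over Sorensen time), normally 0.77;
* right/left side-bridge ratio, normally 0.96, with deviations beyond 0.05
  flagged as side-to-side imbalance.

The trunk-curl scale as published lists only two labels whose printed edges
overlap; the bins here close that overlap (bad up to 131 s, good from 132 s)
and remain configurable so clinics can substitute their own cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "ReferenceNorms",
    "CategoryBins",
    "UndefinedRatioError",
    "DEFAULT_BINS",
    "DEFAULT_NORMS",
    "load_config",
    "categorize",
    "flexor_extensor_ratio",
    "side_ratio",
]

MAX_DURATION_S = 240.0


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a ratio denominator is zero."""


@dataclass(frozen=True)
class ReferenceNorms:
    """Published normal endurance times and balance ratios (seconds)."""

    steet_range: tuple[float, float] = (62.0, 131.0)
    tcset_mean: float = 134.0
    sbet_mean: float = 84.0
    sbet_sd: float = 24.5
    flexor_extensor_ref: float = 0.77
    right_left_ref: float = 0.96
    side_imbalance_threshold: float = 0.05


@dataclass(frozen=True)
class CategoryBins:
    """Per-test ordered ``(label, lower_s, upper_s)`` bins covering [0, 240].

    Boundaries are inclusive at the printed integer edges; a non-integer
    duration belongs to the bin whose lower edge is the largest not
    exceeding it, so the continuum is covered without gaps.
    """

    bins: dict[str, tuple[tuple[str, float, float], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_BIN_TABLE))

    def labels(self, test: str) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.bins[self._key(test)])

    def _key(self, test: str) -> str:
        key = test.upper()
        if key.startswith("SBET"):
            key = "SBET"
        if key not in self.bins:
            raise KeyError(f"no category bins for test {test!r}")
        return key

    def lookup(self, test: str, duration_s: float) -> str:
        if not 0.0 <= duration_s <= MAX_DURATION_S:
            raise ValueError(
                f"duration {duration_s} s outside [0, {MAX_DURATION_S:g}]")
        table = self.bins[self._key(test)]
        label = table[0][0]
        for lbl, lower, _upper in table:
            if duration_s >= lower:
                label = lbl
        return label


_DEFAULT_BIN_TABLE = {
    "STEET": (("bad", 0.0, 61.0), ("good", 62.0, 131.0), ("perfect", 132.0, 240.0)),
    "TCSET": (("bad", 0.0, 131.0), ("good", 132.0, 240.0)),
    "SBET": (("bad", 0.0, 60.0), ("good", 61.0, 108.0), ("perfect", 109.0, 240.0)),
}

DEFAULT_BINS = CategoryBins()
DEFAULT_NORMS = ReferenceNorms()


def load_config(path: str | Path | None = None) -> tuple[ReferenceNorms, CategoryBins]:
    """Load norms and bins from a YAML config (default: the packaged file).

    The file carries a ``norms`` mapping of reference values and a ``bins``
    mapping of per-test ``[label, lower, upper]`` triples, so clinics can
    override the published cut-offs.
    """
    import yaml
    if path is None:
        text = resources.files("trunklab.data").joinpath("norms.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    raw = dict(cfg.get("norms", {}))
    if "steet_range" in raw:
        raw["steet_range"] = tuple(float(v) for v in raw["steet_range"])
    norms = ReferenceNorms(**raw)
    bins = CategoryBins({
        test: tuple((str(lbl), float(lo), float(hi)) for lbl, lo, hi in rows)
        for test, rows in cfg.get("bins", {}).items()
    })
    return norms, bins


def categorize(test: str, total_duration_s: float,
               bins: CategoryBins = DEFAULT_BINS) -> str:
    """Label a test duration as bad / good / perfect against its bins."""
    return bins.lookup(test, total_duration_s)


def flexor_extensor_ratio(tcset_s: float, steet_s: float) -> float:
    """Trunk flexor to extensor endurance ratio (curl / Sorensen)."""
    if steet_s == 0:
        raise UndefinedRatioError("extensor duration is zero")
    return tcset_s / steet_s


def side_ratio(right_s: float, left_s: float,
               norms: ReferenceNorms = DEFAULT_NORMS,
               reference: str = "norm") -> tuple[float, bool]:
    """Right/left side-bridge ratio and an imbalance flag.

    ``reference='norm'`` flags imbalance when the ratio deviates from the
    published 0.96 norm by more than the threshold; ``reference='unity'``
    measures the deviation from 1.0 instead.
    """
    if left_s == 0:
        raise UndefinedRatioError("left-side duration is zero")
    ratio = right_s / left_s
    ref = norms.right_left_ref if reference == "norm" else 1.0
    imbalanced = abs(ratio - ref) > norms.side_imbalance_threshold
    return ratio, imbalanced
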