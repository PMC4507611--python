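"""Inter-method agreement statistics for paired endurance durations.

Given each subject's test duration measured by two methods (a stopwatch-timed
traditional assessment and the sensor-based system), agreement is quantified
with three standard clinical statistics:

* the intraclass correlation coefficient (ICC) under the one-way random
  effects model, in both single-measures ICC(1,1) and average-measures
  ICC(1,k) forms, with exact F-based confidence intervals;
* Cronbach's alpha over the two methods treated as items;
* Bland-Altman limits of agreement, mean difference +/- 1.96 SD.

For the one-way model with n subjects and k measurements each, the ANOVA
mean squares are MSB (between subjects, n-1 df) and MSW (within subjects,
n(k-1) df), and

    ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW)
    ICC(1,k) = (MSB - MSW) / MSB

The exact confidence interval follows from F0 = MSB/MSW: with
FL = F0 / F(1-a/2; n-1, n(k-1)) and FU = F0 * F(1-a/2; n(k-1), n-1), the
single-measures bounds are (FL-1)/(FL+k-1) and (FU-1)/(FU+k-1) and the
average-measures bounds are 1 - 1/FL and 1 - 1/FU.

The average-measures form is the default: it is the form under which the
bundled ten-subject validation dataset reproduces its published reliability
table, and ICC(1,k) >= ICC(1,1) whenever the latter is positive.

Conventional qualitative labels are attached for reporting: ICC below 0.4 is
poor, 0.4-0.75 fair-to-good, above 0.75 excellent; alpha below 0.5
unacceptable, then poor / questionable / acceptable / good in 0.1 steps, and
excellent above 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "ReliabilityReport",
    "BlandAltmanReport",
    "DegenerateDataError",
    "icc_oneway",
    "icc_ci",
    "cronbach_alpha",
    "bland_altman",
    "reliability_report",
    "reliability_table",
    "icc_label",
    "alpha_label",
    "load_paired",
    "load_validation_study",
    "round_half_up",
]


class DegenerateDataError(ValueError):
    """Raised when the data carry no variance to decompose."""


@dataclass(frozen=True)
class PairedMeasurements:
    """Durations of n subjects measured by two methods, in seconds."""

    subjects: tuple
    method_a: np.ndarray
    method_b: np.ndarray
    label: str = ""

    def __post_init__(self):
        a = np.asarray(self.method_a, dtype=float)
        b = np.asarray(self.method_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("method_a and method_b must be 1-D of equal length")
        if len(self.subjects) != a.size:
            raise ValueError("subject ids must match the number of rows")
        if a.size < 2:
            raise ValueError("need at least two subjects")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("measurements must be finite")
        object.__setattr__(self, "method_a", a)
        object.__setattr__(self, "method_b", b)
        object.__setattr__(self, "subjects", tuple(self.subjects))

    @classmethod
    def from_arrays(cls, method_a, method_b, label: str = "") -> "PairedMeasurements":
        a = np.asarray(method_a, dtype=float)
        return cls(subjects=tuple(range(1, a.size + 1)),
                   method_a=a, method_b=method_b, label=label)

    @property
    def n(self) -> int:
        return self.method_a.size

    @property
    def k(self) -> int:
        return 2

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.method_a, self.method_b])


@dataclass(frozen=True)
class ReliabilityReport:
    label: str
    icc: float
    ci_low: float
    ci_high: float
    alpha: float
    form: str  # "single" | "average"
    icc_quality: str
    alpha_quality: str


@dataclass(frozen=True)
class BlandAltmanReport:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    averages: np.ndarray
    differences: np.ndarray


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), for display and comparisons."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _anova_mean_squares(pm: PairedMeasurements) -> tuple[float, float]:
    """One-way ANOVA decomposition over subjects: (MSB, MSW)."""
    x = pm.as_matrix()
    n, k = x.shape
    row_means = x.mean(axis=1)
    msb = k * float(np.sum((row_means - x.mean()) ** 2)) / (n - 1)
    msw = float(np.sum((x - row_means[:, None]) ** 2)) / (n * (k - 1))
    if msb == 0.0 and msw == 0.0:
        raise DegenerateDataError("all measurements identical; ICC undefined")
    return msb, msw


def icc_oneway(pm: PairedMeasurements, form: str = "average") -> float:
    """One-way random-effects ICC, single or average measures."""
    msb, msw = _anova_mean_squares(pm)
    if form == "average":
        if msb == 0.0:
            raise DegenerateDataError("no between-subject variance")
        return (msb - msw) / msb
    if form == "single":
        return (msb - msw) / (msb + (pm.k - 1) * msw)
    raise ValueError(f"unknown ICC form {form!r}")


def icc_ci(pm: PairedMeasurements, form: str = "average",
           level: float = 0.95) -> tuple[float, float]:
    """Exact F-based confidence interval for the one-way ICC."""
    msb, msw = _anova_mean_squares(pm)
    if msw == 0.0:
        return (1.0, 1.0)  # limiting behavior: perfect within-subject agreement
    n, k = pm.n, pm.k
    df1, df2 = n - 1, n * (k - 1)
    f0 = msb / msw
    alpha = 1.0 - level
    fl = f0 / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f0 * stats.f.ppf(1 - alpha / 2, df2, df1)
    if form == "average":
        return (1.0 - 1.0 / fl, 1.0 - 1.0 / fu)
    if form == "single":
        return ((fl - 1.0) / (fl + k - 1.0), (fu - 1.0) / (fu + k - 1.0))
    raise ValueError(f"unknown ICC form {form!r}")


def cronbach_alpha(pm: PairedMeasurements) -> float:
    """Cronbach's alpha over the two methods as items (n-1 variances)."""
    x = pm.as_matrix()
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise DegenerateDataError("zero variance of item sums; alpha undefined")
    k = pm.k
    return (k / (k - 1)) * (1.0 - float(item_vars.sum()) / float(total_var))


def bland_altman(pm: PairedMeasurements, z: float = 1.96) -> BlandAltmanReport:
    """Limits of agreement of method_a - method_b differences."""
    diffs = pm.method_a - pm.method_b
    avgs = (pm.method_a + pm.method_b) / 2.0
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanReport(mean_diff=mean, sd_diff=sd,
                             loa_low=mean - z * sd, loa_high=mean + z * sd,
                             averages=avgs, differences=diffs)


def icc_label(icc: float) -> str:
    if icc < 0.4:
        return "poor"
    if icc <= 0.75:
        return "fair to good"
    return "excellent"


def alpha_label(alpha: float) -> str:
    for bound, name in [(0.5, "unacceptable"), (0.6, "poor"),
                        (0.7, "questionable"), (0.8, "acceptable"),
                        (0.9, "good")]:
        if alpha < bound:
            return name
    return "excellent"


def reliability_report(pm: PairedMeasurements, form: str = "average",
                       level: float = 0.95) -> ReliabilityReport:
    icc = icc_oneway(pm, form=form)
    lo, hi = icc_ci(pm, form=form, level=level)
    alpha = cronbach_alpha(pm)
    return ReliabilityReport(label=pm.label, icc=icc, ci_low=lo, ci_high=hi,
                             alpha=alpha, form=form,
                             icc_quality=icc_label(icc),
                             alpha_quality=alpha_label(alpha))


def reliability_table(datasets: Mapping[str, PairedMeasurements] | Iterable[PairedMeasurements],
                      form: str = "average", level: float = 0.95,
                      ) -> pd.DataFrame:
    """One reliability row per test; display values rounded half-up to 2 dp,
    full precision retained in ``*_exact`` columns."""
    if isinstance(datasets, Mapping):
        items = [(name, pm) for name, pm in datasets.items()]
    else:
        items = [(pm.label, pm) for pm in datasets]
    rows = []
    for name, pm in items:
        r = reliability_report(pm, form=form, level=level)
        rows.append({
            "test": name,
            "icc": round_half_up(r.icc),
            "ci_low": round_half_up(r.ci_low),
            "ci_high": round_half_up(r.ci_high),
            "alpha": round_half_up(r.alpha),
            "icc_exact": r.icc, "ci_low_exact": r.ci_low,
            "ci_high_exact": r.ci_high, "alpha_exact": r.alpha,
            "icc_quality": r.icc_quality, "alpha_quality": r.alpha_quality,
        })
    return pd.DataFrame(rows).set_index("test")


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------

def load_paired(path: str | Path, label: str = "") -> PairedMeasurements:
    """Read a ``subject,method_a,method_b`` delimited-text file."""
    df = pd.read_csv(path)
    required = {"subject", "method_a", "method_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    return PairedMeasurements(subjects=tuple(df["subject"]),
                              method_a=df["method_a"].to_numpy(float),
                              method_b=df["method_b"].to_numpy(float),
                              label=label or Path(path).stem)


def load_validation_study() -> dict[str, PairedMeasurements]:
    """The bundled ten-subject validation dataset.

    Ten volunteers performed all four holds (Sorensen, trunk curl, side
    bridge right and left) timed both by a stopwatch-based traditional
    assessment (method_a) and by the sensor system (method_b).  Returns one
    :class:`PairedMeasurements` per test, keyed by test name.
    """
    with resources.files("trunklab.data").joinpath("paired_durations.csv").open() as fh:
        df = pd.read_csv(fh)
    out: dict[str, PairedMeasurements] = {}
    for test, grp in df.groupby("test", sort=False):
        out[test] = PairedMeasurements(subjects=tuple(grp["subject"]),
                                       method_a=grp["traditional_s"].to_numpy(float),
                                       method_b=grp["sensor_s"].to_numpy(float),
                                       label=test)
    return out


def bland_altman_plot(pm: PairedMeasurements, ax=None, z: float = 1.96):
    """Scatter of per-subject differences vs averages with the mean line and
    +/-1.96 SD limits; returns the matplotlib Axes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    report = bland_altman(pm, z=z)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.averages, report.differences, color="k", zorder=3)
    ax.axhline(report.mean_diff, color="tab:blue", label="mean difference")
    for y in (report.loa_low, report.loa_high):
        ax.axhline(y, color="tab:red", linestyle="--")
    ax.set_xlabel("average of methods (s)")
    ax.set_ylabel("difference between methods (s)")
    if pm.label:
        ax.set_title(pm.label)
    return ax
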