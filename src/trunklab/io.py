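"""File formats, session records, pipeline composition and persistence.

Units are fixed across all files: time in seconds, angles in degrees, EMG in
mV.  Streams are delimited text with a header row:

* IMU stream: ``t,ax,ay,az,gx,gy,gz,mx,my,mz`` (m/s^2, rad/s, arbitrary
  field units);
* EMG stream: ``t,emg_mV``;
* angle trace: ``t,roll_deg``;
* paired durations: ``subject,method_a,method_b``.

Sessions persist as one JSON file per session in a store directory —
reproducible and diff-able, with a lossless round trip for every record
type.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import emg as emg_mod
from .emg import FatigueMetrics
from .norms import CategoryBins, DEFAULT_NORMS, flexor_extensor_ratio, side_ratio
from .orientation import FilterConfig, ImuSample, trunk_angle_stream
from .session import PROTOCOLS, AttemptResult, TestResult, run_test

__all__ = [
    "StreamFormatError",
    "PatientRecord",
    "SessionRecord",
    "SessionStore",
    "IMU_COLUMNS",
    "EMG_COLUMNS",
    "read_stream",
    "write_imu_stream",
    "write_emg_stream",
    "write_angle_stream",
    "read_angle_stream",
    "run_pipeline",
    "history_report",
]

logger = logging.getLogger(__name__)

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]
EMG_COLUMNS = ["t", "emg_mV"]
ANGLE_COLUMNS = ["t", "roll_deg"]


class StreamFormatError(ValueError):
    """Malformed stream file: wrong header, bad rows or broken time base."""


@dataclass(frozen=True)
class PatientRecord:
    id: str
    age: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    gender: str | None = None
    conditions: str = ""


@dataclass
class SessionRecord:
    patient_id: str
    date: str
    tests: list[TestResult] = field(default_factory=list)
    ratios: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def test_dict(tr: TestResult) -> dict:
            d = {
                "protocol": tr.protocol,
                "total_duration": tr.total_duration,
                "category": tr.category,
                "attempts": [dataclasses.asdict(a) for a in tr.attempts],
                "fatigue": dataclasses.asdict(tr.fatigue) if tr.fatigue else None,
                "epoch_fatigue": [
                    {"t_start": t, **dataclasses.asdict(m)}
                    for t, m in tr.epoch_fatigue
                ],
            }
            return d
        return {
            "patient_id": self.patient_id,
            "date": self.date,
            "tests": [test_dict(t) for t in self.tests],
            "ratios": self.ratios,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionRecord":
        tests = []
        for td in d.get("tests", []):
            fat = FatigueMetrics(**td["fatigue"]) if td.get("fatigue") else None
            epochs = [(e["t_start"], FatigueMetrics(rms=e["rms"], arv=e["arv"],
                                                    mvc=e["mvc"]))
                      for e in td.get("epoch_fatigue", [])]
            tests.append(TestResult(
                protocol=td["protocol"],
                attempts=[AttemptResult(**a) for a in td["attempts"]],
                total_duration=td["total_duration"],
                category=td.get("category"),
                fatigue=fat, epoch_fatigue=epochs))
        return cls(patient_id=d["patient_id"], date=d["date"], tests=tests,
                   ratios=d.get("ratios", {}))


# ---------------------------------------------------------------------------
# Stream files
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if list(df.columns) != columns:
        raise StreamFormatError(
            f"{path}: expected header {','.join(columns)}, "
            f"got {','.join(map(str, df.columns))}")
    bad = df.index[df.isna().any(axis=1) | ~np.isfinite(df.to_numpy(float)).all(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise StreamFormatError(f"{path}: malformed rows at lines {lines}")
    if not df["t"].is_monotonic_increasing:
        warnings.warn(f"{path}: timestamps out of order; sorting", stacklevel=2)
        df = df.sort_values("t", kind="stable").reset_index(drop=True)
    if df["t"].duplicated().any():
        raise StreamFormatError(f"{path}: duplicate timestamps")
    return df


def read_stream(path: str | Path, kind: str):
    """Read a validated, time-sorted IMU or EMG stream.

    Returns a list of :class:`ImuSample` for ``kind='imu'`` or an (n, 2)
    array of (t, mV) rows for ``kind='emg'``.
    """
    if kind == "imu":
        df = _read_table(path, IMU_COLUMNS)
        arr = df.to_numpy(float)
        return [ImuSample(t=row[0], accel=row[1:4], gyro=row[4:7], mag=row[7:10])
                for row in arr]
    if kind == "emg":
        df = _read_table(path, EMG_COLUMNS)
        return df.to_numpy(float)
    raise ValueError(f"unknown stream kind {kind!r}")


def write_imu_stream(path: str | Path, samples: Sequence[ImuSample]) -> None:
    rows = [[s.t, *s.accel, *s.gyro, *s.mag] for s in samples]
    pd.DataFrame(rows, columns=IMU_COLUMNS).to_csv(path, index=False)


def write_emg_stream(path: str | Path, trace: np.ndarray) -> None:
    pd.DataFrame(np.asarray(trace, float), columns=EMG_COLUMNS).to_csv(path, index=False)


def write_angle_stream(path: str | Path, angles: Sequence[tuple[float, float]]) -> None:
    pd.DataFrame(list(angles), columns=ANGLE_COLUMNS).to_csv(path, index=False)


def read_angle_stream(path: str | Path) -> list[tuple[float, float]]:
    df = _read_table(path, ANGLE_COLUMNS)
    return [tuple(row) for row in df.to_numpy(float)]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str | Path) -> SessionRecord:
    """Execute a full session from a config mapping or YAML/JSON file.

    Config schema::

        patient_id: str
        date: str (ISO)
        tests:
          - protocol: STEET | TCSET | SBET_RIGHT | SBET_LEFT
            imu: path           # or `angles: path` for a precomputed trace
            emg: path           # optional; durations still scored without it
            start_times: [s, ...]
            manual_stop_times: [s|null, ...]   # optional
        filter: {gain: float, sample_rate: float, use_magnetometer: bool}

    Each stage failure aborts with a message tagged by the failing stage.
    Endurance ratios (flexor/extensor, right/left) are added when the needed
    tests are present.
    """
    if not isinstance(config, dict):
        path = Path(config)
        text = path.read_text()
        config = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)

    fcfg = FilterConfig(**config.get("filter", {}))
    record = SessionRecord(patient_id=str(config["patient_id"]),
                           date=str(config.get("date", "")))

    for tcfg in config["tests"]:
        proto = tcfg["protocol"].upper()
        if proto not in PROTOCOLS:
            raise ValueError(f"[session] unknown protocol {proto!r}")
        try:
            if "angles" in tcfg:
                angles = read_angle_stream(tcfg["angles"])
            else:
                imu = read_stream(tcfg["imu"], "imu")
                angles = trunk_angle_stream(imu, fcfg)
        except Exception as exc:
            raise RuntimeError(f"[orientation] {proto}: {exc}") from exc

        emg_signal = None
        if tcfg.get("emg"):
            emg_path = Path(tcfg["emg"])
            if emg_path.exists():
                emg_signal = read_stream(emg_path, "emg")[:, 1]
            else:
                logger.warning("EMG file %s missing; fatigue marked absent",
                               emg_path)
        try:
            result = run_test(angles, proto, tcfg["start_times"],
                              emg_signal=emg_signal,
                              emg_sample_rate=fcfg.sample_rate,
                              manual_stop_times=tcfg.get("manual_stop_times"))
        except Exception as exc:
            raise RuntimeError(f"[session] {proto}: {exc}") from exc
        record.tests.append(result)

    record.ratios = _session_ratios(record)
    for t in record.tests:
        logger.info("%s: reference %.2f deg, %.2f s, %s (%s)", t.protocol,
                    t.attempts[0].reference_angle if t.attempts else float("nan"),
                    t.total_duration, t.attempts[-1].termination_reason
                    if t.attempts else "?", t.category)
    return record


def _session_ratios(record: SessionRecord) -> dict[str, Any]:
    by_proto = {t.protocol: t.total_duration for t in record.tests}
    ratios: dict[str, Any] = {}
    if "TCSET" in by_proto and "STEET" in by_proto and by_proto["STEET"] > 0:
        ratios["flexor_extensor"] = flexor_extensor_ratio(
            by_proto["TCSET"], by_proto["STEET"])
    if ("SBET_RIGHT" in by_proto and "SBET_LEFT" in by_proto
            and by_proto["SBET_LEFT"] > 0):
        ratio, imbalanced = side_ratio(by_proto["SBET_RIGHT"],
                                       by_proto["SBET_LEFT"], DEFAULT_NORMS)
        ratios["right_left"] = ratio
        ratios["side_imbalanced"] = bool(imbalanced)
    return ratios


# ---------------------------------------------------------------------------
# Session store & history
# ---------------------------------------------------------------------------

class SessionStore:
    """Directory of one JSON file per session."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def save(self, record: SessionRecord) -> Path:
        existing = list(self.root.glob(f"{record.patient_id}_*.json"))
        path = self.root / f"{record.patient_id}_{record.date or 'undated'}_{len(existing)}.json"
        path.write_text(json.dumps(record.to_dict(), indent=2, sort_keys=True))
        return path

    def sessions_for(self, patient_id: str) -> list[SessionRecord]:
        records = []
        for path in sorted(self.root.glob(f"{patient_id}_*.json")):
            records.append(SessionRecord.from_dict(json.loads(path.read_text())))
        return sorted(records, key=lambda r: r.date)

    def patients(self) -> list[str]:
        return sorted({p.name.split("_")[0] for p in self.root.glob("*.json")})


class PatientNotFoundError(KeyError):
    pass


def history_report(store: SessionStore, patient_id: str) -> pd.DataFrame:
    """Chronological per-test series of durations and fatigue metrics."""
    sessions = store.sessions_for(patient_id)
    if not sessions:
        raise PatientNotFoundError(f"no sessions stored for patient {patient_id!r}")
    rows = []
    for s in sessions:
        for t in s.tests:
            rows.append({
                "date": s.date, "protocol": t.protocol,
                "duration_s": t.total_duration, "category": t.category,
                "rms_mV": t.fatigue.rms if t.fatigue else np.nan,
                "arv_mV": t.fatigue.arv if t.fatigue else np.nan,
                "mvc_mV": t.fatigue.mvc if t.fatigue else np.nan,
            })
    return (pd.DataFrame(rows)
            .sort_values(["protocol", "date"], kind="stable")
            .reset_index(drop=True))
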