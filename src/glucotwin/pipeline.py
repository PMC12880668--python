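"""Ingest CGM / event / heart-rate streams and prepare 24 h samples.

Raw streams are timezone-naive local-time CSVs:

- ``cgm.csv``: patient_id, timestamp, glucose_mgdl
- ``events.csv``: patient_id, timestamp, type (meal|bolus|basal|exercise),
  value (carb g / insulin U / insulin U / duration min), fat_g, protein_g
- ``hr.csv``: patient_id, timestamp, bpm

Candidate 24 h windows are placed greedily left to right with a minimum
stride, then screened by five quality rules: CGM gaps, CGM discontinuities,
meal count, fast-acting bolus count, and heart-rate coverage.  Surviving
windows become :class:`Sample24h` objects: window-relative minute traces, a
constant basal rate from the most recent long-acting injection in the
preceding 24 h, and the initial glucose taken from the first CGM reading.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecords",
    "RawRecords",
    "Window",
    "FilterReport",
    "Sample24h",
    "extract_windows",
    "materialize_window",
    "apply_filters",
    "prepare_sample",
    "build_dataset",
]

log = logging.getLogger(__name__)

WINDOW_MIN = 1440.0
GAP_LIMIT_MIN = 12.0        # rule 1: any CGM inter-reading interval > 12 min fails
JUMP_LIMIT_MGDL = 45.0      # rule 2: any |dCGM| >= 45 mg/dL fails
MIN_MEALS = 2               # rule 3
MIN_BOLUSES = 1             # rule 4
HR_COVERAGE = 0.30          # rule 5: fraction of 5-min bins with a reading
HR_BIN_MIN = 5.0


@dataclass
class PatientRecords:
    """One patient's raw streams, timestamps strictly increasing."""

    cgm: pd.DataFrame       # timestamp, glucose_mgdl
    events: pd.DataFrame    # timestamp, type, value, fat_g, protein_g
    hr: pd.DataFrame        # timestamp, bpm

    def __post_init__(self) -> None:
        for name in ("cgm", "events", "hr"):
            df = getattr(self, name)
            ts = pd.to_datetime(df["timestamp"])
            if not ts.is_monotonic_increasing:
                raise ValueError(f"{name} timestamps must be increasing")
            df = df.assign(timestamp=ts).reset_index(drop=True)
            setattr(self, name, df)
        g = self.cgm["glucose_mgdl"]
        if len(g) and ((g <= 20) | (g >= 600)).any():
            raise ValueError("CGM values outside the (20, 600) mg/dL plausibility band")


@dataclass
class RawRecords:
    patients: dict[str, PatientRecords] = field(default_factory=dict)

    @classmethod
    def read_dir(cls, path) -> "RawRecords":
        path = Path(path)
        cgm = pd.read_csv(path / "cgm.csv", parse_dates=["timestamp"])
        events = pd.read_csv(path / "events.csv", parse_dates=["timestamp"])
        hr = pd.read_csv(path / "hr.csv", parse_dates=["timestamp"])
        out = {}
        for pid in sorted(cgm["patient_id"].unique(), key=str):
            out[str(pid)] = PatientRecords(
                cgm=cgm[cgm.patient_id == pid].drop(columns="patient_id"),
                events=events[events.patient_id == pid].drop(columns="patient_id"),
                hr=hr[hr.patient_id == pid].drop(columns="patient_id"),
            )
        return cls(out)

    def write_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in ("cgm", "events", "hr"):
            frames = []
            for pid, pr in self.patients.items():
                frames.append(getattr(pr, name).assign(patient_id=pid))
            df = pd.concat(frames, ignore_index=True)
            cols = ["patient_id"] + [c for c in df.columns if c != "patient_id"]
            df[cols].to_csv(path / f"{name}.csv", index=False)


@dataclass
class Window:
    """A materialised 24 h candidate window of one patient."""

    patient_id: str
    start: pd.Timestamp
    cgm_t: np.ndarray       # min from start
    cgm: np.ndarray
    hr_t: np.ndarray
    hr_bpm: np.ndarray
    events: pd.DataFrame    # rows inside [start, start+24h), t_min column added


@dataclass
class FilterReport:
    window_id: str
    start: pd.Timestamp
    rules: dict             # rule name -> bool (True = pass)
    max_gap_min: float
    max_jump_mgdl: float
    n_meals: int
    n_boluses: int
    hr_coverage: float

    @property
    def passed(self) -> bool:
        return all(self.rules.values())

    def to_row(self) -> dict:
        return {"window_id": self.window_id, "start": self.start, **{f"pass_{k}": v for k, v in self.rules.items()},
                "max_gap_min": self.max_gap_min, "max_jump_mgdl": self.max_jump_mgdl,
                "n_meals": self.n_meals, "n_boluses": self.n_boluses,
                "hr_coverage": self.hr_coverage, "passed": self.passed}


@dataclass
class Sample24h:
    """One quality-screened 24 h sample, everything in window-relative minutes."""

    patient_id: str
    start: pd.Timestamp
    cgm_t: np.ndarray
    cgm: np.ndarray
    hr_t: np.ndarray
    hr_bpm: np.ndarray
    meals: list             # dicts: t_report, carbs, fat, protein
    boluses: list           # dicts: t_report, dose
    exercises: list         # dicts: t_report, duration
    basal_rate: float       # U/min
    g0: float               # mg/dL, first CGM reading
    day_frac0: float        # window-start time of day, fraction of a day
    hr_rest: float = 65.0   # resting heart rate for this patient

    def write_csv(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"t_min": self.cgm_t, "glucose_mgdl": self.cgm}).to_csv(
            path / "cgm.csv", index=False, float_format="%.17e")
        pd.DataFrame({"t_min": self.hr_t, "bpm": self.hr_bpm}).to_csv(
            path / "hr.csv", index=False, float_format="%.17e")
        rows = [{"t_min": m["t_report"], "type": "meal", "value": m["carbs"],
                 "fat_g": m.get("fat", 0.0), "protein_g": m.get("protein", 0.0)} for m in self.meals]
        rows += [{"t_min": b["t_report"], "type": "bolus", "value": b["dose"], "fat_g": "", "protein_g": ""}
                 for b in self.boluses]
        rows += [{"t_min": e["t_report"], "type": "exercise", "value": e.get("duration", 0.0),
                  "fat_g": "", "protein_g": ""} for e in self.exercises]
        pd.DataFrame(rows, columns=["t_min", "type", "value", "fat_g", "protein_g"]).to_csv(
            path / "events.csv", index=False)
        meta = pd.DataFrame([{"patient_id": self.patient_id, "start": self.start,
                              "basal_rate": self.basal_rate, "g0": self.g0,
                              "day_frac0": self.day_frac0, "hr_rest": self.hr_rest}])
        meta.to_csv(path / "meta.csv", index=False)

    @classmethod
    def read_csv(cls, path) -> "Sample24h":
        path = Path(path)
        cgm = pd.read_csv(path / "cgm.csv", float_precision="round_trip")
        hr = pd.read_csv(path / "hr.csv", float_precision="round_trip")
        ev = pd.read_csv(path / "events.csv", float_precision="round_trip")
        meta = pd.read_csv(path / "meta.csv", float_precision="round_trip").iloc[0]
        meals, boluses, exercises = [], [], []
        for _, r in ev.iterrows():
            if r["type"] == "meal":
                meals.append({"t_report": float(r.t_min), "carbs": float(r.value),
                              "fat": float(r.fat_g) if pd.notna(r.fat_g) else 0.0,
                              "protein": float(r.protein_g) if pd.notna(r.protein_g) else 0.0})
            elif r["type"] == "bolus":
                boluses.append({"t_report": float(r.t_min), "dose": float(r.value)})
            elif r["type"] == "exercise":
                exercises.append({"t_report": float(r.t_min), "duration": float(r.value)})
        return cls(patient_id=str(meta.patient_id), start=pd.Timestamp(meta.start),
                   cgm_t=cgm["t_min"].to_numpy(float), cgm=cgm["glucose_mgdl"].to_numpy(float),
                   hr_t=hr["t_min"].to_numpy(float), hr_bpm=hr["bpm"].to_numpy(float),
                   meals=meals, boluses=boluses, exercises=exercises,
                   basal_rate=float(meta.basal_rate), g0=float(meta.g0),
                   day_frac0=float(meta.day_frac0), hr_rest=float(meta.hr_rest))


def _minutes(ts: pd.Series, start: pd.Timestamp) -> np.ndarray:
    return (pd.to_datetime(ts) - start).dt.total_seconds().to_numpy() / 60.0


def extract_windows(records: PatientRecords, length: float = WINDOW_MIN,
                    min_stride: float = 300.0) -> list[pd.Timestamp]:
    """Greedy left-to-right candidate window starts, fully inside the CGM span."""
    if len(records.cgm) == 0:
        return []
    t0 = records.cgm["timestamp"].iloc[0]
    t_end = records.cgm["timestamp"].iloc[-1]
    starts = []
    start = t0
    while start + pd.Timedelta(minutes=length) <= t_end:
        starts.append(start)
        start = start + pd.Timedelta(minutes=min_stride)
    return starts


def materialize_window(records: PatientRecords, start: pd.Timestamp,
                       patient_id: str = "", length: float = WINDOW_MIN) -> Window:
    """Slice the streams to the half-open window [start, start + length)."""
    end = start + pd.Timedelta(minutes=length)
    cgm = records.cgm[(records.cgm.timestamp >= start) & (records.cgm.timestamp < end)]
    hr = records.hr[(records.hr.timestamp >= start) & (records.hr.timestamp < end)]
    ev = records.events[(records.events.timestamp >= start) & (records.events.timestamp < end)].copy()
    ev["t_min"] = _minutes(ev["timestamp"], start) if len(ev) else []
    return Window(patient_id=patient_id, start=start,
                  cgm_t=_minutes(cgm["timestamp"], start), cgm=cgm["glucose_mgdl"].to_numpy(float),
                  hr_t=_minutes(hr["timestamp"], start), hr_bpm=hr["bpm"].to_numpy(float), events=ev)


def apply_filters(window: Window) -> FilterReport:
    """Screen one window with the five quality rules (order-independent)."""
    gaps = np.diff(window.cgm_t) if window.cgm_t.size > 1 else np.array([np.inf])
    max_gap = float(gaps.max()) if gaps.size else np.inf
    jumps = np.abs(np.diff(window.cgm)) if window.cgm.size > 1 else np.array([0.0])
    max_jump = float(jumps.max()) if jumps.size else 0.0
    ev = window.events
    n_meals = int((ev["type"] == "meal").sum()) if len(ev) else 0
    n_boluses = int((ev["type"] == "bolus").sum()) if len(ev) else 0
    n_bins = int(WINDOW_MIN / HR_BIN_MIN)
    if window.hr_t.size:
        bins = np.unique((window.hr_t // HR_BIN_MIN).astype(int))
        coverage = bins.size / n_bins
    else:
        coverage = 0.0
    rules = {
        "cgm_gap": max_gap <= GAP_LIMIT_MIN,
        "cgm_jump": max_jump < JUMP_LIMIT_MGDL,
        "meal_count": n_meals >= MIN_MEALS,
        "bolus_count": n_boluses >= MIN_BOLUSES,
        "hr_coverage": coverage >= HR_COVERAGE,
    }
    wid = f"{window.patient_id}@{window.start.isoformat()}"
    return FilterReport(window_id=wid, start=window.start, rules=rules, max_gap_min=max_gap,
                        max_jump_mgdl=max_jump, n_meals=n_meals, n_boluses=n_boluses,
                        hr_coverage=coverage)


def prepare_sample(records: PatientRecords, window: Window, hr_rest: float | None = None) -> Sample24h:
    """Turn a filtered window into a Sample24h.

    The most recent long-acting ('basal') injection within the preceding
    24 h becomes a constant infusion dose/1440 U/min; none found means zero
    basal with a warning.  Initial glucose is the first CGM reading.
    """
    lookback = window.start - pd.Timedelta(minutes=WINDOW_MIN)
    basal_ev = records.events[(records.events["type"] == "basal")
                              & (records.events.timestamp > lookback)
                              & (records.events.timestamp <= window.start)]
    if len(basal_ev):
        basal_rate = float(basal_ev["value"].iloc[-1]) / WINDOW_MIN
    else:
        basal_rate = 0.0
        warnings.warn(f"no long-acting dose in the 24 h before {window.start}; basal set to 0",
                      stacklevel=2)
    if window.cgm.size == 0:
        raise ValueError("window has no CGM readings")
    ev = window.events
    meals = [{"t_report": float(r.t_min), "carbs": float(r.value),
              "fat": float(r.fat_g) if pd.notna(r.fat_g) else 0.0,
              "protein": float(r.protein_g) if pd.notna(r.protein_g) else 0.0}
             for r in ev[ev["type"] == "meal"].itertuples()]
    boluses = [{"t_report": float(r.t_min), "dose": float(r.value)}
               for r in ev[ev["type"] == "bolus"].itertuples()]
    exercises = [{"t_report": float(r.t_min), "duration": float(r.value)}
                 for r in ev[ev["type"] == "exercise"].itertuples()]
    if hr_rest is None:
        hr_rest = float(np.percentile(records.hr["bpm"], 5)) if len(records.hr) else 65.0
    midnight = window.start.normalize()
    day_frac0 = (window.start - midnight).total_seconds() / 86400.0
    return Sample24h(patient_id=window.patient_id, start=window.start,
                     cgm_t=window.cgm_t, cgm=window.cgm, hr_t=window.hr_t, hr_bpm=window.hr_bpm,
                     meals=meals, boluses=boluses, exercises=exercises, basal_rate=basal_rate,
                     g0=float(window.cgm[0]), day_frac0=day_frac0, hr_rest=float(hr_rest))


def build_dataset(raw: RawRecords, min_stride: float = 300.0,
                  report_path=None) -> tuple[list[list[Sample24h]], pd.DataFrame]:
    """Extract, filter and prepare all windows; returns (patients, report table)."""
    patients: list[list[Sample24h]] = []
    rows = []
    for pid in sorted(raw.patients, key=str):
        pr = raw.patients[pid]
        hr_rest = float(np.percentile(pr.hr["bpm"], 5)) if len(pr.hr) else 65.0
        samples = []
        for start in extract_windows(pr, min_stride=min_stride):
            w = materialize_window(pr, start, patient_id=pid)
            rep = apply_filters(w)
            rows.append(rep.to_row())
            if rep.passed:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    samples.append(prepare_sample(pr, w, hr_rest=hr_rest))
        patients.append(samples)
    report = pd.DataFrame(rows)
    if report_path is not None:
        report.to_csv(report_path, index=False)
    return patients, report
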