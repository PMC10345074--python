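"""Reading, validation and exclusion logic for beat-annotation data.

The raw unit of data is a *beat series*: for one patient, the monitor's
beat-to-beat (RR) intervals in milliseconds, each stamped with an absolute
clock time and a beat label (``N`` normal/sinus, ``P`` paced, ``E`` ectopic,
``O`` other).  Clinical covariates ride alongside in a one-row-per-patient
table.  This module applies the cohort-selection cascade: trim each record
to the first 48 h after admission, keep only normal (sinus) beats, and drop
patients with too few normal beats, missing required covariates, or an
atrial-fibrillation diagnosis.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LABELS = ("N", "P", "E", "O")

#: Covariates that must be present for a patient to enter the analysis.
DEFAULT_REQUIRED_FIELDS = (
    "age",
    "sex",
    "nihss",
    "gfr",
    "mrs_discharge",
    "troponin_ng_l",
)

#: Default threshold for "insufficient numbers of normal heart beats" over
#: the 48 h window (~10% duty cycle at 60 bpm); site rules vary, so this is
#: configuration, not a constant of the method.
DEFAULT_MIN_NORMAL_BEATS = 5000


class BeatSeriesError(ValueError):
    """Raised when a beat series violates its invariants."""


@dataclass
class BeatSeries:
    """Ordered beat-to-beat intervals with per-beat labels for one patient.

    Parameters
    ----------
    patient_id : str
    time : np.ndarray of datetime64[ns]
        Absolute beat times, strictly increasing.  Times are time-zone-naive
        local clock times: the circadian analysis is clock-relative.
    rr_ms : np.ndarray of float
        Beat-to-beat interval ending at the corresponding beat, ms; positive
        and finite.
    label : np.ndarray of str
        One of ``N``, ``P``, ``E``, ``O`` per beat.
    """

    patient_id: str
    time: np.ndarray
    rr_ms: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype="datetime64[ns]")
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.label = np.asarray(self.label, dtype="U1")
        n = len(self.time)
        if len(self.rr_ms) != n or len(self.label) != n:
            raise BeatSeriesError("time, rr_ms and label must have equal length")
        if n:
            if not np.all(np.isfinite(self.rr_ms)):
                bad = np.flatnonzero(~np.isfinite(self.rr_ms))
                raise BeatSeriesError(f"non-finite rr_ms at positions {bad[:5].tolist()}")
            if np.any(self.rr_ms <= 0):
                bad = np.flatnonzero(self.rr_ms <= 0)
                raise BeatSeriesError(f"non-positive rr_ms at positions {bad[:5].tolist()}")
            if np.any(np.diff(self.time.astype("int64")) <= 0):
                bad = np.flatnonzero(np.diff(self.time.astype("int64")) <= 0)
                raise BeatSeriesError(
                    f"beat times not strictly increasing at positions {bad[:5].tolist()}"
                )
        unknown = set(np.unique(self.label)) - set(LABELS)
        if unknown:
            raise BeatSeriesError(f"unknown beat labels {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_normal(self) -> int:
        return int(np.sum(self.label == "N"))

    def equals(self, other: "BeatSeries") -> bool:
        return (
            self.patient_id == other.patient_id
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.rr_ms, other.rr_ms)
            and np.array_equal(self.label, other.label)
        )


@dataclass
class PatientRecord:
    """One subject: beat series plus clinical covariates.

    Any covariate may be missing; missing numerics are NaN and missing
    categoricals/lists are ``None``.  ``troponin_ng_l`` holds serial
    high-sensitivity troponin measurements in ng/l, in sampling order.
    """

    patient_id: str
    admission_time: pd.Timestamp
    series: BeatSeries
    age: float = math.nan
    sex: str | None = None  # "female" | "male"
    nihss: float = math.nan
    hypertension: float = math.nan
    diabetes: float = math.nan
    prior_mi: float = math.nan
    cad: float = math.nan
    pneumonia: float = math.nan
    stroke_type: str | None = None  # "ischemic" | "hemorrhagic"
    af_diagnosis: bool = False
    troponin_ng_l: list[float] | None = None
    gfr: float = math.nan
    mrs_discharge: float = math.nan

    def replace(self, **kw) -> "PatientRecord":
        return dataclasses.replace(self, **kw)


@dataclass
class FlowReport:
    """Patient counts through the exclusion cascade (flow-chart accounting).

    Each excluded patient is counted once, under the first criterion it
    fails, in the fixed order insufficient-beats -> missing-fields -> AF ->
    paced; conservation ``initial == analyzable + sum(exclusions)`` always
    holds.
    """

    initial: int = 0
    excluded_insufficient_beats: int = 0
    excluded_missing_fields: int = 0
    excluded_af: int = 0
    excluded_paced: int = 0
    analyzable: int = 0

    def total_excluded(self) -> int:
        return (
            self.excluded_insufficient_beats
            + self.excluded_missing_fields
            + self.excluded_af
            + self.excluded_paced
        )

    def check(self) -> None:
        if self.initial != self.analyzable + self.total_excluded():
            raise AssertionError(f"flow report does not conserve patients: {self}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(dataclasses.asdict(self)), "count": list(dataclasses.asdict(self).values())}
        )


# ---------------------------------------------------------------------------
# beat-annotation CSV  (columns: patient_id,time_iso8601,rr_ms,label)
# ---------------------------------------------------------------------------

def _series_from_frame(pid: str, g: pd.DataFrame) -> BeatSeries:
    times = pd.to_datetime(g["time_iso8601"], format="ISO8601").to_numpy()
    rr = pd.to_numeric(g["rr_ms"], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(rr) | (rr <= 0))
    if bad.size:
        rows = (g.index.to_numpy()[bad] + 2).tolist()  # +2: header + 1-based
        raise BeatSeriesError(f"invalid rr_ms in rows {rows[:10]} of patient {pid}")
    labels = g["label"].to_numpy(dtype="U1")
    return BeatSeries(pid, times, rr, labels)


def read_beat_csv_multi(path) -> dict[str, BeatSeries]:
    """Read a beat-annotation CSV holding one or more patients."""
    df = pd.read_csv(path, dtype={"patient_id": str, "label": str})
    expected = ["patient_id", "time_iso8601", "rr_ms", "label"]
    if list(df.columns) != expected:
        raise BeatSeriesError(f"expected columns {expected}, found {list(df.columns)}")
    return {pid: _series_from_frame(pid, g) for pid, g in df.groupby("patient_id", sort=True)}


def read_beat_csv(path, patient_id: str | None = None) -> BeatSeries:
    """Read a single patient's beat series from a beat-annotation CSV."""
    series = read_beat_csv_multi(path)
    if patient_id is not None:
        try:
            return series[patient_id]
        except KeyError:
            raise BeatSeriesError(f"patient {patient_id!r} not in {path}") from None
    if len(series) != 1:
        raise BeatSeriesError(
            f"{path} holds {len(series)} patients; pass patient_id to pick one"
        )
    return next(iter(series.values()))


def write_beat_csv(series: BeatSeries | Iterable[BeatSeries], path) -> None:
    many = [series] if isinstance(series, BeatSeries) else list(series)
    frames = [
        pd.DataFrame(
            {
                "patient_id": s.patient_id,
                "time_iso8601": np.datetime_as_string(s.time, unit="ns"),
                "rr_ms": s.rr_ms,
                "label": s.label,
            }
        )
        for s in many
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# covariate CSV  (one row per patient; troponin serialized ';'-joined)
# ---------------------------------------------------------------------------

COVARIATE_COLUMNS = [
    "patient_id",
    "admission_time",
    "age",
    "sex",
    "nihss",
    "hypertension",
    "diabetes",
    "prior_mi",
    "cad",
    "pneumonia",
    "stroke_type",
    "af_diagnosis",
    "troponin_ng_l",
    "gfr",
    "mrs_discharge",
]


def write_covariates_csv(records: Sequence[PatientRecord], path) -> None:
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in COVARIATE_COLUMNS if c != "troponin_ng_l"}
        d["admission_time"] = pd.Timestamp(r.admission_time).strftime("%Y-%m-%dT%H:%M:%S")
        d["troponin_ng_l"] = (
            ";".join(f"{v:.3f}" for v in r.troponin_ng_l) if r.troponin_ng_l else ""
        )
        rows.append(d)
    pd.DataFrame(rows, columns=COVARIATE_COLUMNS).to_csv(path, index=False, float_format="%.6f")


def read_covariates_csv(path) -> pd.DataFrame:
    """Read the covariate table; troponin cells become lists of floats."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["admission_time"] = pd.to_datetime(df["admission_time"], format="ISO8601")
    df["troponin_ng_l"] = [
        [float(x) for x in str(cell).split(";")] if isinstance(cell, str) and cell else None
        for cell in df["troponin_ng_l"]
    ]
    return df


def records_from_tables(beats: dict[str, BeatSeries], covariates: pd.DataFrame) -> list[PatientRecord]:
    """Join beat series and covariate rows into PatientRecords."""
    out = []
    for _, row in covariates.iterrows():
        pid = row["patient_id"]
        series = beats.get(pid)
        if series is None:
            series = BeatSeries(pid, np.array([], "datetime64[ns]"), np.array([]), np.array([], "U1"))
        out.append(
            PatientRecord(
                patient_id=pid,
                admission_time=pd.Timestamp(row["admission_time"]),
                series=series,
                age=float(row["age"]) if pd.notna(row["age"]) else math.nan,
                sex=row["sex"] if isinstance(row["sex"], str) else None,
                nihss=float(row["nihss"]) if pd.notna(row["nihss"]) else math.nan,
                hypertension=_maybe_float(row["hypertension"]),
                diabetes=_maybe_float(row["diabetes"]),
                prior_mi=_maybe_float(row["prior_mi"]),
                cad=_maybe_float(row["cad"]),
                pneumonia=_maybe_float(row["pneumonia"]),
                stroke_type=row["stroke_type"] if isinstance(row["stroke_type"], str) else None,
                af_diagnosis=bool(row["af_diagnosis"]),
                troponin_ng_l=row["troponin_ng_l"],
                gfr=float(row["gfr"]) if pd.notna(row["gfr"]) else math.nan,
                mrs_discharge=float(row["mrs_discharge"]) if pd.notna(row["mrs_discharge"]) else math.nan,
            )
        )
    return out


def _maybe_float(v) -> float:
    return float(v) if pd.notna(v) else math.nan


# ---------------------------------------------------------------------------
# filtering operations
# ---------------------------------------------------------------------------

def trim_to_window(record: PatientRecord, hours: float = 48.0) -> PatientRecord:
    """Keep beats in ``[admission, admission + hours)`` (half-open)."""
    if pd.isna(record.admission_time):
        raise ValueError(f"patient {record.patient_id}: admission_time missing")
    t0 = np.datetime64(pd.Timestamp(record.admission_time), "ns")
    t1 = t0 + np.timedelta64(int(round(hours * 3600 * 1e9)), "ns")
    s = record.series
    keep = (s.time >= t0) & (s.time < t1)
    return record.replace(
        series=BeatSeries(s.patient_id, s.time[keep], s.rr_ms[keep], s.label[keep])
    )


def select_normal_beats(series: BeatSeries) -> BeatSeries:
    """Keep only beats labeled normal (sinus).

    Stored rr_ms values are used as annotated; intervals are never re-derived
    across the holes left by removed beats.  Successive-difference statistics
    downstream detect those holes from time jumps.
    """
    keep = series.label == "N"
    return BeatSeries(series.patient_id, series.time[keep], series.rr_ms[keep], series.label[keep])


def categorize_troponin(samples: Sequence[float] | None) -> int | None:
    """Code serial troponin (ng/l) as 0/1/2; ``None`` when unmeasured.

    0: all samples below the 14 ng/l upper reference limit.
    1: at least one sample above 14 ng/l.
    2: acute elevation — some sample above 14 ng/l plus a second sample
       differing from it by at least 20% of the elevated value (rise or fall).
    """
    if samples is None or len(samples) == 0:
        return None
    vals = [float(v) for v in samples]
    if any((not math.isfinite(v)) or v < 0 for v in vals):
        raise ValueError(f"troponin samples must be finite and >= 0, got {vals}")
    elevated = [v for v in vals if v > 14.0]
    if not elevated:
        return 0
    if len(vals) >= 2:
        for e in elevated:
            others = list(vals)
            others.remove(e)
            if any(abs(o - e) >= 0.2 * e for o in others):
                return 2
    return 1


def dichotomize_outcome(mrs: int | float) -> str:
    """Modified Rankin Scale 0-2 -> ``good`` (independent living); 3-6 ->
    ``unfavorable`` (dependency, including death)."""
    if pd.isna(mrs) or mrs != int(mrs) or not 0 <= int(mrs) <= 6:
        raise ValueError(f"mRS must be an integer in 0..6, got {mrs!r}")
    return "good" if mrs <= 2 else "unfavorable"


def _missing_fields(record: PatientRecord, required: Sequence[str]) -> list[str]:
    out = []
    for f in required:
        v = getattr(record, f)
        if v is None:
            out.append(f)
        elif isinstance(v, (list, tuple)) and len(v) == 0:
            out.append(f)
        elif isinstance(v, float) and math.isnan(v):
            out.append(f)
    return out


def apply_exclusions(
    cohort: Sequence[PatientRecord],
    min_normal_beats: int = DEFAULT_MIN_NORMAL_BEATS,
    required_fields: Sequence[str] = DEFAULT_REQUIRED_FIELDS,
    exclude_af: bool = True,
    max_paced_fraction: float = 0.5,
) -> tuple[list[PatientRecord], FlowReport]:
    """Apply the cohort-selection cascade with first-failure accounting.

    Order: insufficient normal beats -> missing required covariates -> AF
    diagnosis -> majority-paced rhythm.  ``exclude_af=False`` disables the AF
    criterion (robustness analyses re-admit AF patients).  Each patient is
    counted under the first criterion it fails, so flow counts are well
    defined and conserve the initial cohort size.
    """
    report = FlowReport(initial=len(cohort))
    analyzable: list[PatientRecord] = []
    for rec in cohort:
        n_beats = len(rec.series)
        if rec.series.n_normal < min_normal_beats:
            report.excluded_insufficient_beats += 1
        elif _missing_fields(rec, required_fields):
            report.excluded_missing_fields += 1
        elif exclude_af and rec.af_diagnosis:
            report.excluded_af += 1
        elif n_beats and np.mean(rec.series.label == "P") > max_paced_fraction:
            report.excluded_paced += 1
        else:
            analyzable.append(rec)
    report.analyzable = len(analyzable)
    report.check()
    return analyzable, report
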