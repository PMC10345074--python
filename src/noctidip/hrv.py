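"""Segment-wise HR/HRV metrics and hour-of-day circadian profiles.

The normal-beat series is binned into wall-clock 5-min segments
([hh:00, hh:05), ...).  Within each segment we compute:

* ``hr_bpm``   — median instantaneous HR, median over beats of 60000/RR;
* ``sdnn_ms``  — population standard deviation of the RR intervals;
* ``rmssd_ms`` — root mean square of successive RR differences, skipping
  pairs that straddle a removed beat or recording gap (detected as a time
  jump greater than twice the segment's median RR);
* ``lf_ms2``/``hf_ms2`` — band power of the RR tachogram in 0.04-0.15 Hz
  and 0.15-0.4 Hz: cubic smoothing-spline interpolation of the tachogram,
  uniform resampling at 4 Hz, mean removal, periodogram PSD, rectangle-rule
  integration over the band.

Hourly circadian values aggregate the segment values of each clock hour
(median across segments); an hour is reported only when at least 3 of its
possible 24 five-minute segments (over a 48 h window) are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.signal import periodogram

from .ingest import BeatSeries
from .synthetic import LF_BAND, HF_BAND

SEGMENT_SECONDS = 300
#: minimum beats per segment for HR/SDNN/RMSSD (~10% duty cycle at 60 bpm)
MIN_SEGMENT_BEATS = 30
#: spectral preconditions: enough span to resolve 0.04 Hz, enough beats
MIN_SPECTRAL_SPAN_S = 150.0
MIN_SPECTRAL_BEATS = 16
RESAMPLE_HZ = 4.0
HOURLY_QUORUM = 3

ALL_METRICS = ("hr", "sdnn", "rmssd", "lf", "hf")

_METRIC_COLUMNS = {
    "hr": "hr_bpm",
    "sdnn": "sdnn_ms",
    "rmssd": "rmssd_ms",
    "lf": "lf_ms2",
    "hf": "hf_ms2",
    "lf_hf": "lf_hf_ratio",
}


@dataclass
class CircadianProfile:
    """Hour-of-day profile of one metric for one patient.

    ``hour_values[h]`` is the hourly value for clock hour ``h`` (NaN when
    fewer than ``quorum`` segments contributed); ``hour_segment_counts[h]``
    counts contributing segments.
    """

    patient_id: str
    metric: str
    hour_values: np.ndarray  # shape (24,), float with NaN
    hour_segment_counts: np.ndarray  # shape (24,), int

    def available_hours(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.hour_values))


def segment_series(series: BeatSeries) -> list[tuple[pd.Timestamp, np.ndarray, np.ndarray]]:
    """Bin beats into wall-clock 5-min segments (half-open grid bins).

    Returns ``(segment_start, time_s, rr_ms)`` triples for non-empty
    segments, where ``time_s`` is beat time in seconds relative to the
    segment start.
    """
    if len(series) == 0:
        return []
    epoch_s = series.time.astype("int64") / 1e9
    seg_idx = np.floor(epoch_s / SEGMENT_SECONDS).astype(np.int64)
    out = []
    order = np.argsort(seg_idx, kind="stable")  # already sorted, cheap
    boundaries = np.flatnonzero(np.diff(seg_idx[order])) + 1
    groups = np.split(order, boundaries)
    for g in groups:
        s0 = seg_idx[g[0]] * SEGMENT_SECONDS
        start = pd.Timestamp(int(s0 * 1e9))
        out.append((start, epoch_s[g] - s0, series.rr_ms[g]))
    return out


def segment_hr(rr_ms: np.ndarray) -> float:
    """Median instantaneous heart rate of a segment, bpm (midpoint median)."""
    return float(np.median(60000.0 / np.asarray(rr_ms, dtype=float)))


def segment_time_domain(
    time_s: np.ndarray, rr_ms: np.ndarray
) -> tuple[float, float]:
    """(SDNN, RMSSD) in ms for one segment's beats.

    SDNN is the population standard deviation of the RR intervals.  RMSSD
    uses only successive pairs whose inter-beat time jump is at most twice
    the segment's median RR, which skips pairs straddling removed non-normal
    beats or gaps; NaN when fewer than 2 valid pairs exist.
    """
    rr = np.asarray(rr_ms, dtype=float)
    t = np.asarray(time_s, dtype=float)
    sdnn = float(np.std(rr)) if rr.size >= 2 else math.nan
    if rr.size < 3:
        return sdnn, math.nan
    dt = np.diff(t)
    med_rr_s = np.median(rr) / 1000.0
    valid = dt <= 2.0 * med_rr_s
    diffs = np.diff(rr)[valid]
    rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size >= 2 else math.nan
    return sdnn, rmssd


def segment_spectral(
    time_s: np.ndarray,
    rr_ms: np.ndarray,
    resample_hz: float = RESAMPLE_HZ,
    spline_smoothing: float = 0.0,
) -> tuple[float, float]:
    """(LF, HF) band power in ms² from the segment tachogram.

    Tachogram (beat time -> RR) is interpolated with a cubic smoothing
    spline (``spline_smoothing=0`` interpolates through the data), sampled
    on a uniform grid at ``resample_hz``, mean-removed, and fed to a
    periodogram; band powers integrate the PSD over [0.04, 0.15) and
    [0.15, 0.4) Hz with the rectangle rule.  NaN when the segment spans
    less than 150 s or has fewer than 16 beats.
    """
    t = np.asarray(time_s, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if t.size < MIN_SPECTRAL_BEATS or (t[-1] - t[0]) < MIN_SPECTRAL_SPAN_S:
        return math.nan, math.nan
    spline = UnivariateSpline(t, rr, k=3, s=spline_smoothing)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    x = spline(grid)
    x = x - x.mean()
    freqs, psd = periodogram(x, fs=resample_hz)
    df = freqs[1] - freqs[0]
    lf = float(np.sum(psd[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])]) * df)
    hf = float(np.sum(psd[(freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])]) * df)
    return lf, hf


def compute_segment_metrics(
    series: BeatSeries,
    metrics: Sequence[str] = ALL_METRICS,
    min_beats: int = MIN_SEGMENT_BEATS,
    spline_smoothing: float = 0.0,
) -> pd.DataFrame:
    """Per-segment metrics for one patient as a tidy DataFrame.

    Columns: patient_id, segment_start, n_beats, plus the requested metric
    columns (hr_bpm, sdnn_ms, rmssd_ms, lf_ms2, hf_ms2, lf_hf_ratio).
    Metrics are NaN for segments below the per-segment beat minimum.
    Restricting ``metrics`` (e.g. to ``("hr",)``) skips the expensive
    spectral step for HR-only studies.
    """
    want = set(metrics)
    rows = []
    for start, t_s, rr in segment_series(series):
        row: dict = {
            "patient_id": series.patient_id,
            "segment_start": start,
            "n_beats": len(rr),
        }
        ok = len(rr) >= min_beats
        if "hr" in want:
            row["hr_bpm"] = segment_hr(rr) if ok else math.nan
        if "sdnn" in want or "rmssd" in want:
            sdnn, rmssd = segment_time_domain(t_s, rr) if ok else (math.nan, math.nan)
            if "sdnn" in want:
                row["sdnn_ms"] = sdnn
            if "rmssd" in want:
                row["rmssd_ms"] = rmssd
        if "lf" in want or "hf" in want:
            lf, hf = (
                segment_spectral(t_s, rr, spline_smoothing=spline_smoothing)
                if ok
                else (math.nan, math.nan)
            )
            row["lf_ms2"] = lf
            row["hf_ms2"] = hf
            row["lf_hf_ratio"] = lf / hf if (not math.isnan(hf)) and hf > 0 else math.nan
        rows.append(row)
    cols = ["patient_id", "segment_start", "n_beats"] + [
        _METRIC_COLUMNS[m] for m in ALL_METRICS if m in want
    ]
    if ("lf" in want or "hf" in want) and "lf_hf_ratio" not in cols:
        cols.append("lf_hf_ratio")
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def build_profile(
    segments: pd.DataFrame, metric: str, quorum: int = HOURLY_QUORUM
) -> CircadianProfile:
    """Aggregate one patient's segment metrics into a 24-hour profile.

    Slot ``h`` pools all segments whose start falls in clock hour ``h``
    across both recording days; the hourly value is the median of the
    contributing (non-NaN) segment values, reported only when at least
    ``quorum`` segments contribute.
    """
    col = _METRIC_COLUMNS[metric]
    if len(segments) == 0:
        return CircadianProfile("unknown", metric, np.full(24, math.nan), np.zeros(24, dtype=int))
    pids = segments["patient_id"].unique()
    if len(pids) > 1:
        raise ValueError(f"segments span multiple patients: {pids.tolist()}")
    pid = pids[0] if len(pids) else "unknown"
    values = np.full(24, math.nan)
    counts = np.zeros(24, dtype=int)
    if len(segments):
        hours = pd.DatetimeIndex(segments["segment_start"]).hour.to_numpy()
        vals = segments[col].to_numpy(dtype=float)
        present = ~np.isnan(vals)
        for h in range(24):
            sel = (hours == h) & present
            counts[h] = int(sel.sum())
            if counts[h] >= quorum:
                values[h] = float(np.median(vals[sel]))
    return CircadianProfile(pid, metric, values, counts)


def cohort_profiles(
    segment_frames: Iterable[pd.DataFrame],
    metrics: Sequence[str] = ALL_METRICS,
    quorum: int = HOURLY_QUORUM,
) -> dict[str, dict[str, CircadianProfile]]:
    """Profiles for every patient: ``{patient_id: {metric: profile}}``."""
    out: dict[str, dict[str, CircadianProfile]] = {}
    for seg in segment_frames:
        if not len(seg):
            continue
        pid = seg["patient_id"].iloc[0]
        out[pid] = {
            m: build_profile(seg, m, quorum=quorum)
            for m in metrics
            if _METRIC_COLUMNS[m] in seg.columns
        }
    return out


def hour_value_matrix(profiles: Iterable[CircadianProfile]) -> pd.DataFrame:
    """Patients x 24 clock hours matrix of hourly values (NaN = missing)."""
    profiles = list(profiles)
    return pd.DataFrame(
        [p.hour_values for p in profiles],
        index=pd.Index([p.patient_id for p in profiles], name="patient_id"),
        columns=range(24),
    )


def cohort_profile_summary(
    values: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per-hour group mean, SD and patient count over available slots.

    ``values`` is a patients x 24 matrix (see :func:`hour_value_matrix`);
    ``groups`` maps patient_id to group label.
    """
    rows = []
    for g in pd.unique(groups):
        sub = values.loc[groups[groups == g].index.intersection(values.index)]
        for h in range(24):
            col = sub[h].dropna()
            rows.append(
                {
                    "group": g,
                    "hour": h,
                    "mean": col.mean() if len(col) else math.nan,
                    "sd": col.std(ddof=1) if len(col) >= 2 else math.nan,
                    "n": len(col),
                }
            )
    return pd.DataFrame(rows)


def profiles_to_frame(
    profiles: dict[str, dict[str, CircadianProfile]]
) -> pd.DataFrame:
    """Tidy (patient, metric, hour) long table of hourly values and counts."""
    rows = []
    for pid, by_metric in profiles.items():
        for m, prof in by_metric.items():
            for h in range(24):
                rows.append(
                    {
                        "patient_id": pid,
                        "metric": m,
                        "hour": h,
                        "value": prof.hour_values[h],
                        "n_segments": int(prof.hour_segment_counts[h]),
                    }
                )
    return pd.DataFrame(rows)
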