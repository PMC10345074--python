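"""Synthetic stroke-unit cohort generator.

Emulates the statistical structure the downstream analysis assumes, without
claiming to reproduce any real population: circadian heart-rate modulation
with a controllable nocturnal dip, LF-band (0.04-0.15 Hz) and HF-band
(0.15-0.4 Hz) RR oscillations, additive Gaussian RR noise, beat-label
artifacts (ectopic beats, paced patients), recording gaps, AF-like
irregularly irregular series, outcome-imbalanced covariates, and a logistic
link from covariates and nocturnal physiology to the discharge mRS.

The RR recurrence is sequential (each beat's time is the cumulative sum of
all previous intervals, and the target HR depends on that time), so the
core loop is compiled with numba.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import lfilter

from .ingest import BeatSeries, PatientRecord

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

#: RR floor/cap applied after noise addition, ms (physiological plausibility;
#: also guarantees positive intervals).
RR_FLOOR_MS = 300.0
RR_CAP_MS = 2000.0


class SpecError(ValueError):
    """A generator spec field is non-finite or out of range."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise SpecError(f"{name}: {msg}")


@dataclass(frozen=True)
class CircadianHRSpec:
    """Target circadian HR trajectory plus RR-level oscillations.

    The instantaneous target heart rate is
    ``h(t) = baseline_day_hr * (1 - dip_fraction * w(t))`` where ``w``
    ramps 0->1 around the start of the night window and 1->0 around its end
    (piecewise-cosine ramp of ``transition_minutes``, centred on the window
    boundary).  Each RR interval is ``60000/h(t)`` plus LF and HF sinusoids
    and Gaussian noise, floored at 300 ms and capped at 2000 ms.
    """

    baseline_day_hr: float = 75.0
    dip_fraction: float = 0.10
    night_window: tuple[int, int] = (22, 5)
    transition_minutes: float = 60.0
    lf_amplitude_ms: float = 20.0
    lf_freq_hz: float = 0.10
    hf_amplitude_ms: float = 15.0
    hf_freq_hz: float = 0.25
    noise_sd_ms: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "baseline_day_hr",
            "dip_fraction",
            "transition_minutes",
            "lf_amplitude_ms",
            "lf_freq_hz",
            "hf_amplitude_ms",
            "hf_freq_hz",
            "noise_sd_ms",
        ):
            _check(math.isfinite(getattr(self, name)), name, "must be finite")
        _check(self.baseline_day_hr > 0, "baseline_day_hr", "must be > 0")
        _check(0 <= self.dip_fraction < 1, "dip_fraction", "must be in [0, 1)")
        _check(self.transition_minutes >= 0, "transition_minutes", "must be >= 0")
        for name in ("lf_amplitude_ms", "hf_amplitude_ms", "noise_sd_ms"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        _check(
            LF_BAND[0] < self.lf_freq_hz < LF_BAND[1],
            "lf_freq_hz",
            f"must lie strictly inside the LF band {LF_BAND}",
        )
        _check(
            HF_BAND[0] < self.hf_freq_hz < HF_BAND[1],
            "hf_freq_hz",
            f"must lie strictly inside the HF band {HF_BAND}",
        )
        nw = self.night_window
        _check(
            len(nw) == 2 and all(isinstance(h, int) and 0 <= h < 24 for h in nw),
            "night_window",
            "must be a pair of clock hours in 0..23",
        )


@njit(cache=False)
def _rr_kernel(
    start_sec_of_day: float,
    duration_s: float,
    baseline_hr: float,
    dip: float,
    night_start_s: float,
    night_end_s: float,
    ramp_s: float,
    lf_amp: float,
    lf_f: float,
    hf_amp: float,
    hf_f: float,
    noise: np.ndarray,
    rr_out: np.ndarray,
    t_out: np.ndarray,
) -> int:
    """Sequential RR generation; returns the number of beats produced.

    ``t`` is seconds since recording start; the clock position drives the
    dip weight w.  Ramps are centred on the night-window boundaries.
    """
    two_pi = 2.0 * math.pi
    t = 0.0
    n = 0
    nmax = rr_out.shape[0]
    day_s = 86400.0
    while n < nmax:
        c = (start_sec_of_day + t) % day_s
        # signed distance into the night window handles midnight wrap
        if ramp_s > 0.0:
            d_start = c - night_start_s
            if d_start > day_s / 2:
                d_start -= day_s
            elif d_start < -day_s / 2:
                d_start += day_s
            d_end = c - night_end_s
            if d_end > day_s / 2:
                d_end -= day_s
            elif d_end < -day_s / 2:
                d_end += day_s
            half = ramp_s / 2.0
            if -half <= d_start <= half:
                w = 0.5 - 0.5 * math.cos(math.pi * (d_start + half) / ramp_s)
            elif -half <= d_end <= half:
                w = 0.5 + 0.5 * math.cos(math.pi * (d_end + half) / ramp_s)
            else:
                if night_start_s < night_end_s:
                    in_night = night_start_s <= c < night_end_s
                else:
                    in_night = c >= night_start_s or c < night_end_s
                w = 1.0 if in_night else 0.0
        else:
            if night_start_s < night_end_s:
                in_night = night_start_s <= c < night_end_s
            else:
                in_night = c >= night_start_s or c < night_end_s
            w = 1.0 if in_night else 0.0
        h = baseline_hr * (1.0 - dip * w)
        rr = 60000.0 / h
        if lf_amp > 0.0:
            rr += lf_amp * math.sin(two_pi * lf_f * t)
        if hf_amp > 0.0:
            rr += hf_amp * math.sin(two_pi * hf_f * t)
        rr += noise[n]
        if rr < RR_FLOOR_MS:
            rr = RR_FLOOR_MS
        elif rr > RR_CAP_MS:
            rr = RR_CAP_MS
        t += rr / 1000.0
        if t > duration_s:
            break
        rr_out[n] = rr
        t_out[n] = t
        n += 1
    return n


def generate_rr_series(
    spec: CircadianHRSpec,
    start_clock_time,
    duration_hours: float,
    seed: int,
    patient_id: str = "sim",
) -> BeatSeries:
    """Generate a beat series following the spec's circadian HR trajectory.

    Beat times are the cumulative sum of the RR intervals, offset from
    ``start_clock_time``; all beats are labeled normal.  Identical arguments
    (including seed) give an identical series.
    """
    if not (math.isfinite(duration_hours) and duration_hours > 0):
        raise SpecError("duration_hours: must be finite and > 0")
    start = pd.Timestamp(start_clock_time)
    duration_s = duration_hours * 3600.0
    nmax = int(duration_s / (RR_FLOOR_MS / 1000.0)) + 2
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, spec.noise_sd_ms, size=nmax)
        if spec.noise_sd_ms > 0
        else np.zeros(nmax)
    )
    rr = np.empty(nmax)
    t = np.empty(nmax)
    sod = (start - start.normalize()).total_seconds()
    n = _rr_kernel(
        sod,
        duration_s,
        spec.baseline_day_hr,
        spec.dip_fraction,
        spec.night_window[0] * 3600.0,
        spec.night_window[1] * 3600.0,
        spec.transition_minutes * 60.0,
        spec.lf_amplitude_ms,
        spec.lf_freq_hz,
        spec.hf_amplitude_ms,
        spec.hf_freq_hz,
        noise,
        rr,
        t,
    )
    times = np.datetime64(start, "ns") + np.round(t[:n] * 1e9).astype("timedelta64[ns]")
    return BeatSeries(patient_id, times, rr[:n].copy(), np.full(n, "N", dtype="U1"))


def generate_af_series(
    mean_rr_ms: float,
    start_clock_time,
    duration_hours: float,
    seed: int,
    patient_id: str = "sim-af",
    ar_coef: float = 0.9,
    log_sd: float = 0.2,
) -> BeatSeries:
    """AF-like series: RR = exp(Gaussian AR(1)), rescaled to the target mean.

    Irregularly irregular, serially correlated, no circadian structure —
    the rhythm that makes standard HRV comparison invalid.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_hours * 3600.0 * 1000.0 / mean_rr_ms * 1.3) + 10
    eps = rng.normal(0.0, log_sd * math.sqrt(1 - ar_coef**2), size=n)
    z = lfilter([1.0], [1.0, -ar_coef], eps)
    rr = np.exp(z)
    rr *= mean_rr_ms / rr.mean()
    rr = np.clip(rr, RR_FLOOR_MS, RR_CAP_MS)
    t = np.cumsum(rr) / 1000.0
    keep = t <= duration_hours * 3600.0
    start = pd.Timestamp(start_clock_time)
    times = np.datetime64(start, "ns") + np.round(t[keep] * 1e9).astype("timedelta64[ns]")
    return BeatSeries(patient_id, times, rr[keep], np.full(int(keep.sum()), "N", dtype="U1"))


def inject_artifacts(
    series: BeatSeries,
    ectopic_fraction: float = 0.0,
    gaps: Sequence[tuple] = (),
    seed: int = 0,
) -> BeatSeries:
    """Relabel a random fraction of beats as ectopic and cut recording gaps.

    Each beat is independently relabeled ectopic with probability
    ``ectopic_fraction``; an ectopic beat's RR is shortened to 0.6x and the
    following beat's RR lengthened to 1.4x (premature beat + compensatory
    pause).  Beats whose time falls inside any ``(start, duration)`` gap are
    removed.  Beat times are left untouched, so gaps appear as time jumps.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    if not 0 <= ectopic_fraction <= 1:
        raise SpecError("ectopic_fraction: must be in [0, 1]")
    gap_bounds = []
    for start, dur in gaps:
        g0 = np.datetime64(pd.Timestamp(start), "ns")
        g1 = g0 + np.timedelta64(int(round(pd.Timedelta(dur).total_seconds() * 1e9)), "ns")
        if g1 <= g0:
            raise SpecError(f"gap ({start}, {dur}): non-positive duration")
        gap_bounds.append((g0, g1))
    gap_bounds.sort()
    for (a0, a1), (b0, b1) in zip(gap_bounds, gap_bounds[1:]):
        if b0 < a1:
            raise SpecError(f"overlapping gaps at {a1} / {b0}")

    rr = series.rr_ms.copy()
    label = series.label.copy()
    rng = np.random.default_rng(seed)
    if ectopic_fraction > 0:
        hit = rng.random(len(series)) < ectopic_fraction
        idx = np.flatnonzero(hit)
        label[idx] = "E"
        rr[idx] *= 0.6
        nxt = idx + 1
        nxt = nxt[nxt < len(series)]
        rr[nxt] *= 1.4
    keep = np.ones(len(series), dtype=bool)
    for g0, g1 in gap_bounds:
        keep &= ~((series.time >= g0) & (series.time < g1))
    return BeatSeries(series.patient_id, series.time[keep], rr[keep], label[keep])


# ---------------------------------------------------------------------------
# cohort-level specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateParams:
    """Distribution parameters for the clinical covariates.

    Defaults are loosely calibrated to a typical elderly stroke-unit
    population (mean age ~74.5 y, median NIHSS ~5, hypertension ~84%,
    diabetes ~29%) without claiming to reproduce any specific cohort.
    """

    age_mean: float = 74.5
    age_sd: float = 10.0
    nihss_mean: float = 5.5  # negative binomial, overdispersed
    nihss_dispersion: float = 3.0
    female_fraction: float = 0.456
    prevalence: dict = field(
        default_factory=lambda: {
            "hypertension": 0.84,
            "diabetes": 0.29,
            "prior_mi": 0.01,
            "cad": 0.09,
            "pneumonia": 0.05,
        }
    )
    hemorrhagic_fraction: float = 0.111
    gfr_mean: float = 74.0
    gfr_sd: float = 20.0
    troponin_log_median: float = math.log(10.0)
    troponin_log_sd: float = 0.7
    troponin_serial_sd: float = 0.25
    #: additive shifts applied to the unfavorable group's draws, creating the
    #: covariate imbalance that motivates propensity matching
    unfavorable_age_shift: float = 4.8
    unfavorable_nihss_shift: float = 2.0


@dataclass(frozen=True)
class OutcomeCoefficients:
    """Logistic coefficients for P(unfavorable outcome, i.e. mRS > 2).

    Inputs enter on internal standardized scales (see ``_linear_predictor``);
    a negative ``dip_fraction`` coefficient means deeper nocturnal dipping
    lowers the odds of an unfavorable outcome.
    """

    intercept: float = 0.0
    age: float = 0.35
    nihss: float = 0.9
    dip_fraction: float = -0.9
    nocturnal_hr: float = 0.8
    comorbidity: float = 0.3


@dataclass(frozen=True)
class ArtifactRates:
    ectopic_fraction: float = 0.02
    paced_patient_fraction: float = 0.03
    af_patient_fraction: float = 0.267
    #: expected number of recording gaps per patient (Poisson); each gap
    #: lasts 15-90 min, uniformly placed
    gaps_per_patient: float = 1.0
    gap_min_minutes: float = 15.0
    gap_max_minutes: float = 90.0


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort.

    ``n_good``/``n_unfavorable`` fix the two physiological groups (dipper
    vs blunted-dipper HR specs); the discharge mRS is then drawn from the
    logistic outcome link, so downstream outcome labels come from the mRS
    dichotomy, not the group index.  Identical specs (including seed) give
    bit-identical cohorts.
    """

    n_good: int = 100
    n_unfavorable: int = 100
    hr_spec_good: CircadianHRSpec = field(
        default_factory=lambda: CircadianHRSpec(baseline_day_hr=76.3, dip_fraction=0.105)
    )
    hr_spec_unfavorable: CircadianHRSpec = field(
        default_factory=lambda: CircadianHRSpec(baseline_day_hr=78.4, dip_fraction=0.063)
    )
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    outcome_coefficients: OutcomeCoefficients = field(default_factory=OutcomeCoefficients)
    missingness_rates: dict = field(
        default_factory=lambda: {"nihss": 0.02, "gfr": 0.02, "troponin_ng_l": 0.03, "mrs_discharge": 0.01}
    )
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    duration_hours: float = 48.0
    #: between-patient variability of the circadian parameters
    dip_sd: float = 0.02
    baseline_hr_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_good >= 0 and self.n_unfavorable >= 0, "n_good/n_unfavorable", "must be >= 0")
        for k, v in {**self.missingness_rates}.items():
            _check(0 <= v <= 1, f"missingness_rates[{k}]", "must be in [0, 1]")
        a = self.artifact_rates
        for name in ("ectopic_fraction", "paced_patient_fraction", "af_patient_fraction"):
            _check(0 <= getattr(a, name) <= 1, name, "must be in [0, 1]")
        _check(self.duration_hours > 0, "duration_hours", "must be > 0")


# standardization anchors for the outcome link (fixed so that coefficients
# have a stable meaning across cohort specs)
_Z_ANCHORS = {
    "age": (74.5, 10.0),
    "nihss": (5.5, 4.0),
    "dip_fraction": (0.084, 0.03),
    "nocturnal_hr": (71.0, 6.0),
    "comorbidity": (1.2, 1.0),
}


def _linear_predictor(co: OutcomeCoefficients, age, nihss, dip, noct_hr, n_comorb):
    def z(name, x):
        m, s = _Z_ANCHORS[name]
        return (x - m) / s

    return (
        co.intercept
        + co.age * z("age", age)
        + co.nihss * z("nihss", nihss)
        + co.dip_fraction * z("dip_fraction", dip)
        + co.nocturnal_hr * z("nocturnal_hr", noct_hr)
        + co.comorbidity * z("comorbidity", n_comorb)
    )


def generate_covariates(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-patient covariates, circadian parameters and outcomes.

    Returns one row per patient with clinical covariates, the realized
    per-patient ``dip_fraction`` / ``baseline_day_hr`` / nocturnal target HR,
    group index, outcome probability, drawn mRS, and artifact assignments.
    Missingness is applied afterwards by :func:`generate_cohort` so this
    frame stays complete for parameter-recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    cp = spec.covariate_params
    n = spec.n_good + spec.n_unfavorable
    group = np.array(["good"] * spec.n_good + ["unfavorable"] * spec.n_unfavorable)
    is_unfav = group == "unfavorable"

    age = rng.normal(cp.age_mean, cp.age_sd, n) + cp.unfavorable_age_shift * is_unfav
    age = np.clip(np.round(age), 18, 100)
    p_nb = cp.nihss_dispersion / (cp.nihss_dispersion + cp.nihss_mean)
    nihss = rng.negative_binomial(cp.nihss_dispersion, p_nb, n) + np.round(
        cp.unfavorable_nihss_shift * is_unfav * rng.random(n) * 2
    ).astype(int)
    nihss = np.clip(nihss, 0, 42)
    sex = np.where(rng.random(n) < cp.female_fraction, "female", "male")
    comorb = {k: (rng.random(n) < p).astype(float) for k, p in cp.prevalence.items()}
    stroke_type = np.where(rng.random(n) < cp.hemorrhagic_fraction, "hemorrhagic", "ischemic")
    gfr = np.clip(rng.normal(cp.gfr_mean, cp.gfr_sd, n), 5, 150).round(1)

    spec_by_group = {"good": spec.hr_spec_good, "unfavorable": spec.hr_spec_unfavorable}
    dip = np.array(
        [spec_by_group[g].dip_fraction for g in group]
    ) + rng.normal(0, spec.dip_sd, n)
    dip = np.clip(dip, 0.0, 0.95)
    base = np.array(
        [spec_by_group[g].baseline_day_hr for g in group]
    ) + rng.normal(0, spec.baseline_hr_sd, n)
    base = np.clip(base, 40.0, 160.0)
    noct_hr = base * (1 - dip)

    n_comorb = np.sum(list(comorb.values()), axis=0)
    eta = _linear_predictor(spec.outcome_coefficients, age, nihss, dip, noct_hr, n_comorb)
    p_unfav = 1.0 / (1.0 + np.exp(-eta))
    if np.all(p_unfav > 1 - 1e-9) or np.all(p_unfav < 1e-9):
        warnings.warn("degenerate logistic outcome specification: all-one or all-zero probability")
    unfav_draw = rng.random(n) < p_unfav
    mrs = np.where(
        unfav_draw,
        rng.choice([3, 4, 5, 6], size=n, p=[0.35, 0.3, 0.15, 0.2]),
        rng.choice([0, 1, 2], size=n, p=[0.3, 0.4, 0.3]),
    )

    ar = spec.artifact_rates
    af = rng.random(n) < ar.af_patient_fraction
    paced = (~af) & (rng.random(n) < ar.paced_patient_fraction)

    # admissions spread across the clock (circadian analysis is clock-relative)
    base_day = pd.Timestamp("2021-03-01")
    admit = base_day + pd.to_timedelta(rng.integers(0, 14 * 24 * 60, n), unit="m")

    # serial troponin: 1-3 samples, lognormal with serial correlation
    n_samples = rng.choice([1, 2, 3], size=n, p=[0.2, 0.5, 0.3])
    trop_first = np.exp(rng.normal(cp.troponin_log_median, cp.troponin_log_sd, n))
    troponin = []
    for i in range(n):
        vals = [trop_first[i]]
        for _ in range(int(n_samples[i]) - 1):
            vals.append(vals[-1] * math.exp(rng.normal(0, cp.troponin_serial_sd)))
        troponin.append([round(v, 3) for v in vals])

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "group": group,
            "admission_time": admit,
            "age": age,
            "sex": sex,
            "nihss": nihss.astype(float),
            **comorb,
            "stroke_type": stroke_type,
            "af_diagnosis": af,
            "gfr": gfr,
            "mrs_discharge": mrs.astype(float),
            "dip_fraction": dip,
            "baseline_day_hr": base,
            "nocturnal_hr_target": noct_hr,
            "p_unfavorable": p_unfav,
            "paced_patient": paced,
        }
    )
    df["troponin_ng_l"] = troponin
    return df


def generate_cohort(spec: CohortSpec, include_series: bool = True) -> list[PatientRecord]:
    """Generate the full cohort: covariates plus per-patient beat series.

    AF-flagged patients receive an irregular AR(1) series with no circadian
    structure; paced patients have ~90% of beats labeled paced; everyone
    else follows their personalized :class:`CircadianHRSpec`.  Ectopic beats
    and recording gaps are injected per ``spec.artifact_rates``, and
    missingness per ``spec.missingness_rates``.  With ``include_series=False``
    the records carry empty series (covariate-only studies, e.g. matching).
    """
    cov = generate_covariates(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    ar = spec.artifact_rates
    records: list[PatientRecord] = []
    empty = BeatSeries("empty", np.array([], "datetime64[ns]"), np.array([]), np.array([], "U1"))
    for i, row in cov.iterrows():
        pid = row["patient_id"]
        series = empty
        if include_series:
            pseed = int(rng.integers(0, 2**31 - 1))
            if row["af_diagnosis"]:
                series = generate_af_series(
                    800.0, row["admission_time"], spec.duration_hours, pseed, pid
                )
            else:
                pspec = replace(
                    spec.hr_spec_good,
                    baseline_day_hr=float(row["baseline_day_hr"]),
                    dip_fraction=float(row["dip_fraction"]),
                )
                series = generate_rr_series(
                    pspec, row["admission_time"], spec.duration_hours, pseed, pid
                )
                gaps = []
                n_gaps = rng.poisson(ar.gaps_per_patient)
                for _ in range(n_gaps):
                    g_start = row["admission_time"] + pd.Timedelta(
                        minutes=float(rng.uniform(0, spec.duration_hours * 60))
                    )
                    g_dur = pd.Timedelta(
                        minutes=float(rng.uniform(ar.gap_min_minutes, ar.gap_max_minutes))
                    )
                    gaps.append((g_start, g_dur))
                gaps.sort()
                gaps = _drop_overlaps(gaps)
                series = inject_artifacts(
                    series,
                    ectopic_fraction=ar.ectopic_fraction,
                    gaps=gaps,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                if row["paced_patient"]:
                    lab = series.label.copy()
                    hit = rng.random(len(series)) < 0.9
                    lab[hit] = "P"
                    series = BeatSeries(pid, series.time, series.rr_ms, lab)

        rec = PatientRecord(
            patient_id=pid,
            admission_time=pd.Timestamp(row["admission_time"]),
            series=series if include_series else empty,
            age=float(row["age"]),
            sex=str(row["sex"]),
            nihss=float(row["nihss"]),
            hypertension=float(row["hypertension"]),
            diabetes=float(row["diabetes"]),
            prior_mi=float(row["prior_mi"]),
            cad=float(row["cad"]),
            pneumonia=float(row["pneumonia"]),
            stroke_type=str(row["stroke_type"]),
            af_diagnosis=bool(row["af_diagnosis"]),
            troponin_ng_l=list(row["troponin_ng_l"]),
            gfr=float(row["gfr"]),
            mrs_discharge=float(row["mrs_discharge"]),
        )
        # field-level missingness
        for fname, p in spec.missingness_rates.items():
            if rng.random() < p:
                if fname == "troponin_ng_l":
                    rec = rec.replace(troponin_ng_l=None)
                else:
                    rec = rec.replace(**{fname: math.nan})
        records.append(rec)
    return records


def _drop_overlaps(gaps: list[tuple]) -> list[tuple]:
    out: list[tuple] = []
    last_end = None
    for start, dur in gaps:
        if last_end is None or start >= last_end:
            out.append((start, dur))
            last_end = start + dur
    return out


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a plain (YAML-friendly) mapping."""
    d = dict(d)
    for key, cls in (
        ("hr_spec_good", CircadianHRSpec),
        ("hr_spec_unfavorable", CircadianHRSpec),
        ("covariate_params", CovariateParams),
        ("outcome_coefficients", OutcomeCoefficients),
        ("artifact_rates", ArtifactRates),
    ):
        if key in d and isinstance(d[key], dict):
            sub = dict(d[key])
            if "night_window" in sub:
                sub["night_window"] = tuple(sub["night_window"])
            d[key] = cls(**sub)
    return CohortSpec(**d)
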