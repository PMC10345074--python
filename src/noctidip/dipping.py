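"""Nocturnal HR dipping statistic and per-hour group comparisons.

The dip statistic compares each patient's mean hourly HR over the day
window (10:00-17:00, clock hours 10-16) with the night window
(22:00-05:00, clock hours 22, 23, 0-4):

    percent_decline = 100 * (day_mean - night_mean) / day_mean

Negative values indicate reverse dipping (night HR above day HR).  Group
comparisons per clock hour use a two-sided Mann-Whitney U test on
patient-level hourly values with a fixed Bonferroni factor of 24.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .hrv import CircadianProfile

DAY_HOURS = (10, 11, 12, 13, 14, 15, 16)
NIGHT_HOURS = (22, 23, 0, 1, 2, 3, 4)
BONFERRONI_FACTOR = 24
ALPHA = 0.05


@dataclass
class DipResult:
    patient_id: str
    day_mean_hr: float
    night_mean_hr: float
    percent_decline: float

    @property
    def available(self) -> bool:
        return not math.isnan(self.percent_decline)


def _window_mean(profile: CircadianProfile, hours) -> float:
    vals = profile.hour_values[list(hours)]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else math.nan


def nocturnal_dip(profile: CircadianProfile) -> DipResult:
    """Percent nocturnal HR decline for one patient's HR profile.

    Window means weight available hourly slots equally.  When either window
    has no available slot the result is marked unavailable (NaN fields).
    """
    day = _window_mean(profile, DAY_HOURS)
    night = _window_mean(profile, NIGHT_HOURS)
    if math.isnan(day) or math.isnan(night) or day == 0:
        return DipResult(profile.patient_id, day, night, math.nan)
    return DipResult(profile.patient_id, day, night, 100.0 * (day - night) / day)


def nocturnal_hr_feature(profile: CircadianProfile) -> float:
    """Mean HR over the night window (22:00-05:00); the ML feature.

    NaN when no night slot is available (such patients are dropped from the
    feature table with a logged count).
    """
    return _window_mean(profile, NIGHT_HOURS)


def dips_to_frame(dips: list[DipResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [d.patient_id for d in dips],
            "day_mean_hr": [d.day_mean_hr for d in dips],
            "night_mean_hr": [d.night_mean_hr for d in dips],
            "percent_decline": [d.percent_decline for d in dips],
        }
    )


def group_dip_summary(dips: list[DipResult], groups: pd.Series) -> pd.DataFrame:
    """Group mean +/- standard error of the mean of percent decline.

    ``groups`` maps patient_id to group label.  SEM = SD/sqrt(n) with the
    sample (ddof=1) standard deviation.
    """
    df = dips_to_frame(dips).dropna(subset=["percent_decline"])
    df = df.merge(groups.rename("group"), left_on="patient_id", right_index=True)
    rows = []
    for g, sub in df.groupby("group", sort=True):
        n = len(sub)
        mean = sub["percent_decline"].mean()
        sem = sub["percent_decline"].std(ddof=1) / math.sqrt(n) if n >= 2 else math.nan
        rows.append({"group": g, "mean_percent_decline": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)


def hourly_group_test(
    values: pd.DataFrame,
    groups: pd.Series,
    group_a: str = "good",
    group_b: str = "unfavorable",
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per clock hour, Bonferroni-corrected.

    ``values`` is the patients x 24 hourly-value matrix of one metric.  The
    Bonferroni factor stays fixed at 24 regardless of how many hours were
    testable (conservative).  Hours where either group contributes fewer
    than 2 values are reported untested (NaN statistics).
    """
    ids_a = groups[groups == group_a].index.intersection(values.index)
    ids_b = groups[groups == group_b].index.intersection(values.index)
    rows = []
    for h in range(24):
        a = values.loc[ids_a, h].dropna().to_numpy()
        b = values.loc[ids_b, h].dropna().to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            u, p = mannwhitneyu(a, b, alternative="two-sided")
            p_bonf = min(1.0, BONFERRONI_FACTOR * p)
            rows.append(
                {
                    "hour": h,
                    "tested": True,
                    "u_statistic": float(u),
                    "p_raw": float(p),
                    "p_bonferroni": p_bonf,
                    "significant": p_bonf < ALPHA,
                    "n_a": len(a),
                    "n_b": len(b),
                }
            )
        else:
            rows.append(
                {
                    "hour": h,
                    "tested": False,
                    "u_statistic": math.nan,
                    "p_raw": math.nan,
                    "p_bonferroni": math.nan,
                    "significant": False,
                    "n_a": len(a),
                    "n_b": len(b),
                }
            )
    return pd.DataFrame(rows)
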