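"""Nocturnal dip statistic and per-hour group comparison on a small cohort.

Each patient's percent HR decline compares the day window (10:00-17:00)
with the night window (22:00-05:00); groups are then compared hour by hour
with Mann-Whitney U tests, Bonferroni-corrected for the 24 clock hours.
"""

import pandas as pd

from noctidip import (
    build_profile, dichotomize_outcome, generate_cohort, group_dip_summary,
    hourly_group_test, nocturnal_dip, select_normal_beats, trim_to_window,
)
from noctidip.hrv import compute_segment_metrics, hour_value_matrix
from noctidip.synthetic import ArtifactRates, CohortSpec

spec = CohortSpec(
    n_good=50, n_unfavorable=50, duration_hours=24.0,
    artifact_rates=ArtifactRates(af_patient_fraction=0.0),
    missingness_rates={}, seed=21,
)
profiles, dips, groups = [], [], {}
for rec in generate_cohort(spec):
    rec = trim_to_window(rec, 24.0)
    seg = compute_segment_metrics(select_normal_beats(rec.series), metrics=("hr",))
    prof = build_profile(seg, "hr")
    profiles.append(prof)
    dips.append(nocturnal_dip(prof))
    groups[rec.patient_id] = dichotomize_outcome(rec.mrs_discharge)
groups = pd.Series(groups)

print(group_dip_summary(dips, groups).to_string(index=False))
# mean percent decline +/- SEM per outcome group: dippers (good outcome)
# show the deeper nocturnal HR fall

tests = hourly_group_test(hour_value_matrix(profiles), groups)
sig = tests.loc[tests["significant"], "hour"].tolist()
print(f"\nhours with Bonferroni-significant HR group difference: {sig}")
print("(the unfavorable group runs a higher HR throughout; the gap is widest "
      "at night, where the dippers' HR is down)")
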