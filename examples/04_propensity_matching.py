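"""Propensity-score matching of outcome groups on age and NIHSS.

Outcome groups in stroke cohorts are imbalanced in age and stroke severity;
matching pairs each minority-group patient with the nearest opposite-group
patient on the logit propensity (caliper 0.2 SD, no replacement) and the
balance table shows the standardized mean differences shrinking.
"""

import numpy as np
import pandas as pd

from noctidip import balance_report, estimate_propensity, generate_covariates, match_pairs
from noctidip.synthetic import CohortSpec

cov = generate_covariates(CohortSpec(n_good=150, n_unfavorable=150, seed=5))
cov["group"] = np.where(cov["mrs_discharge"] > 2, "unfavorable", "good")
groups = pd.Series(cov["group"].to_numpy(), index=cov["patient_id"])

propensity = estimate_propensity(cov, covariates=("age", "nihss"))
result = match_pairs(propensity, groups, caliper=0.2, seed=5)
result.balance = balance_report(cov, result)

print(f"{groups.value_counts().to_dict()} -> {len(result.pairs)} matched pairs")
print(result.balance.to_string(index=False))
# |SMD| < 0.1 after matching is the conventional bar for "balanced":
# age and NIHSS no longer confound the HR-outcome comparison.
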