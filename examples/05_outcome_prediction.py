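"""Nested-CV outcome prediction with and without the nocturnal HR feature.

Builds a clinical feature table whose outcome depends on nocturnal HR,
evaluates logistic regression by nested stratified 5-fold cross-validation
(inner grid search over the inverse-regularization grid), and compares the
with-HR vs without-HR configurations by a two-sample t test over shuffles.
"""

import numpy as np
import pandas as pd

from noctidip.ingest import categorize_troponin
from noctidip.model import ModelSpec, compare_feature_sets, nested_cv_evaluate
from noctidip.synthetic import CohortSpec, OutcomeCoefficients, generate_covariates

cov = generate_covariates(
    CohortSpec(
        n_good=120, n_unfavorable=120,
        outcome_coefficients=OutcomeCoefficients(
            age=0.3, nihss=0.5, dip_fraction=0.0, nocturnal_hr=1.5, comorbidity=0.2
        ),
        seed=9,
    )
)
rng = np.random.default_rng(9)
X = pd.DataFrame(
    {
        "age": cov["age"],
        "sex_male": (cov["sex"] == "male").astype(float),
        "nihss": cov["nihss"],
        "hypertension": cov["hypertension"],
        "diabetes": cov["diabetes"],
        "troponin_category": [float(categorize_troponin(t)) for t in cov["troponin_ng_l"]],
        "gfr": cov["gfr"],
        "nocturnal_hr": cov["nocturnal_hr_target"] + rng.normal(0, 1.5, len(cov)),
    }
)
y = (cov["mrs_discharge"] > 2).to_numpy(dtype=int)

spec = ModelSpec.default_logistic()
with_hr = nested_cv_evaluate(X, y, spec, n_shuffles=5, seed=1)
without_hr = nested_cv_evaluate(X.drop(columns=["nocturnal_hr"]), y, spec,
                                n_shuffles=5, seed=1)
cmp = compare_feature_sets(without_hr, with_hr)

print(f"AUC without nocturnal HR: {cmp.mean_a:.3f} +/- {cmp.sd_a:.3f}")
print(f"AUC with nocturnal HR   : {cmp.mean_b:.3f} +/- {cmp.sd_b:.3f}")
print(f"two-sample t over shuffles: t={cmp.t_statistic:.2f}, p={cmp.p_value:.2g}")
print("\nunit-norm feature importances (with HR):")
print(with_hr.mean_importance.sort_values(ascending=False).round(3).to_string())
# With an HR-driven outcome, the nocturnal HR feature tops the importance
# ranking and lifts the held-out AUC, mirroring the role of nocturnal
# non-dipping in outcome prediction.
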