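"""Propensity-score matching of outcome groups on clinical covariates.

A logistic model of group membership (unfavorable = 1) on the matching
covariates (default: age and NIHSS) yields propensity scores; greedy 1:1
nearest-neighbor matching on the logit scale, without replacement, with a
caliper of 0.2 standard deviations of the logit propensity (the
conventional rule), balances the groups.  Standardized mean differences
before/after quantify the achieved balance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

DEFAULT_CALIPER = 0.2
#: ridge penalty used when the unpenalized fit separates perfectly
SEPARATION_RIDGE_PENALTY = 1e-4


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]  # (good id, unfavorable id)
    propensity: pd.Series  # per patient, indexed by patient_id
    caliper_used: float  # absolute threshold on |logit difference|
    balance: pd.DataFrame | None = None

    @property
    def matched_ids(self) -> list[str]:
        return [i for pair in self.pairs for i in pair]


def estimate_propensity(
    df: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "nihss"),
    group_col: str = "group",
    positive_label: str = "unfavorable",
) -> pd.Series:
    """Fitted P(unfavorable | covariates) per patient.

    Covariates are standardized for numerical stability; the model is
    unpenalized logistic regression.  Under perfect separation (divergent
    coefficients) a ridge-penalized fallback fit is used, with a warning.
    """
    X = df[list(covariates)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matching covariates contain missing values")
    y = (df[group_col] == positive_label).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be present to estimate propensities")
    Xz = StandardScaler().fit_transform(X)
    model = LogisticRegression(C=np.inf, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xz, y)
    p = model.predict_proba(Xz)[:, 1]
    # perfect separation: the fitted scores split the classes exactly, so the
    # unpenalized MLE diverges
    separated = p[y == 1].min() > p[y == 0].max() or np.max(np.abs(model.coef_)) > 30
    if separated:
        warnings.warn(
            "propensity model (near-)separated; falling back to ridge-penalized fit"
        )
        model = LogisticRegression(penalty="l2", C=1.0 / SEPARATION_RIDGE_PENALTY, max_iter=2000)
        model.fit(Xz, y)
        p = model.predict_proba(Xz)[:, 1]
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return pd.Series(p, index=df["patient_id"].to_numpy(), name="propensity")


def match_pairs(
    propensity: pd.Series,
    groups: pd.Series,
    caliper: float = DEFAULT_CALIPER,
    caliper_scale: str = "logit_sd",
    seed: int = 0,
    group_a: str = "good",
    group_b: str = "unfavorable",
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching on logit propensity.

    The minority group is processed in seeded random order; each patient is
    paired with the nearest still-unmatched member of the other group, and
    the pair is kept only if the |logit propensity| distance is within the
    caliper.  ``caliper_scale='logit_sd'`` interprets the caliper as a
    multiple of the SD of the logit propensity (the conventional rule);
    ``'probability'`` applies it on the raw probability scale instead.
    Returns an explicit empty result when no pair survives.
    """
    groups = groups.loc[propensity.index]
    logit = np.log(propensity / (1 - propensity))
    if caliper_scale == "logit_sd":
        sd = float(logit.std(ddof=1))
        threshold = caliper * sd if sd > 0 else 0.0
        dist_values = logit
    elif caliper_scale == "probability":
        threshold = caliper
        dist_values = propensity.astype(float)
    else:
        raise ValueError(f"unknown caliper_scale {caliper_scale!r}")

    ids_a = propensity.index[groups == group_a].to_numpy()
    ids_b = propensity.index[groups == group_b].to_numpy()
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError("both groups must be non-empty")
    minority_is_a = len(ids_a) <= len(ids_b)
    minority = ids_a if minority_is_a else ids_b
    majority = ids_b if minority_is_a else ids_a

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(minority))
    maj_vals = dist_values.loc[majority].to_numpy(dtype=float)
    available = np.ones(len(majority), dtype=bool)
    pairs: list[tuple[str, str]] = []
    for i in order:
        mid = minority[i]
        v = float(dist_values.loc[mid])
        cand = np.flatnonzero(available)
        if cand.size == 0:
            break
        d = np.abs(maj_vals[cand] - v)
        j = cand[int(np.argmin(d))]
        if d.min() <= threshold:
            available[j] = False
            other = majority[j]
            pairs.append((mid, other) if minority_is_a else (other, mid))
    pairs.sort()
    return MatchResult(pairs=pairs, propensity=propensity, caliper_used=float(threshold))


def balance_report(
    df: pd.DataFrame,
    matched: MatchResult,
    covariates: tuple[str, ...] = ("age", "nihss"),
    group_col: str = "group",
) -> pd.DataFrame:
    """Standardized mean differences before and after matching.

    SMD = (mean_good - mean_unfavorable) / pooled SD, with pooled SD =
    sqrt((s1^2 + s2^2)/2).  A zero pooled SD (degenerate covariate) gives
    SMD 0 with a flag.
    """
    def smd(sub: pd.DataFrame, cov: str) -> tuple[float, bool]:
        g1 = sub.loc[sub[group_col] == "good", cov].to_numpy(dtype=float)
        g2 = sub.loc[sub[group_col] == "unfavorable", cov].to_numpy(dtype=float)
        s1 = g1.std(ddof=1) if len(g1) >= 2 else 0.0
        s2 = g2.std(ddof=1) if len(g2) >= 2 else 0.0
        pooled = math.sqrt((s1**2 + s2**2) / 2)
        if pooled == 0:
            return 0.0, True
        return float((g1.mean() - g2.mean()) / pooled), False

    matched_df = df[df["patient_id"].isin(matched.matched_ids)]
    rows = []
    for cov in covariates:
        before, deg_b = smd(df, cov)
        after, deg_a = (smd(matched_df, cov) if len(matched_df) else (math.nan, False))
        rows.append(
            {
                "covariate": cov,
                "smd_before": before,
                "smd_after": after,
                "degenerate": deg_b or deg_a,
            }
        )
    return pd.DataFrame(rows)
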