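"""Nested cross-validated outcome prediction with feature importances.

Two model families predict the dichotomized discharge outcome (unfavorable
= mRS 3-6) from clinical features, optionally augmented with the nocturnal
HR feature:

* logistic regression, tuned over a 50-point grid of the inverse
  regularization strength;
* gradient-boosted trees (LightGBM), tuned over tree depth, learning rate,
  bagging fraction and L2 leaf regularization.

Evaluation is a stratified nested five-fold cross-validation: the outer
split (4:1, class proportions preserved) estimates held-out AUC, the inner
five-fold grid search picks hyperparameters, and the whole procedure is
repeated over ``n_shuffles`` random re-shufflings.  Features are
standardized to zero mean / unit variance with outer-training-fold
statistics only.  Global feature importance is the absolute standardized
coefficient (logistic) or the mean absolute per-sample Shapley tree-path
attribution (boosting), scaled to unit Euclidean norm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from scipy.stats import ttest_ind
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .ingest import PatientRecord, categorize_troponin, dichotomize_outcome

#: inverse-regularization-strength grid for logistic regression (50 values,
#: log-spaced 0.1..1000)
LOGISTIC_C_GRID = [
    0.1, 0.12, 0.15, 0.18, 0.21, 0.26, 0.31, 0.37, 0.45, 0.54,
    0.66, 0.79, 0.95, 1.15, 1.39, 1.68, 2.02, 2.44, 2.95, 3.56,
    4.29, 5.18, 6.25, 7.54, 9.1, 10.9, 13.3, 16.0, 19.3, 23.3,
    28.1, 33.9, 40.9, 49.4, 59.6, 72.0, 86.9, 105.0, 126.0, 153.0,
    184.0, 222.0, 268.0, 324.0, 391.0, 471.0, 569.0, 687.0, 829.0, 1000.0,
]

BASE_FEATURES = [
    "age",
    "sex_male",
    "nihss",
    "hypertension",
    "diabetes",
    "prior_mi",
    "cad",
    "pneumonia",
    "troponin_category",
    "gfr",
]
HR_FEATURE = "nocturnal_hr"


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus its hyperparameter grid.

    ``grid`` maps hyperparameter name to the list of candidate values;
    the exhaustive product is searched.  Candidates are visited from the
    least to the most complex model (larger regularization / smaller depth
    first) and ties in inner AUC keep the earlier candidate, which makes
    the search deterministic.
    """

    family: str  # "logistic_regression" | "gradient_boosting"
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("logistic_regression", "gradient_boosting"):
            raise ValueError(f"unknown model family {self.family!r}")
        for k, v in self.grid.items():
            if len(v) == 0:
                raise ValueError(f"empty grid for {k}")

    @staticmethod
    def default_logistic() -> "ModelSpec":
        return ModelSpec("logistic_regression", {"C": list(LOGISTIC_C_GRID)})

    @staticmethod
    def default_boosting() -> "ModelSpec":
        return ModelSpec(
            "gradient_boosting",
            {
                "max_depth": [2, 4, 6],
                "learning_rate": [round(v, 6) for v in np.linspace(0.03, 0.3, 20)],
                "bagging_fraction": [round(v, 6) for v in np.linspace(0.6, 1.0, 3)],
                "reg_lambda": [3.0, 10.0, 100.0, 500.0],
            },
        )

    @staticmethod
    def small_boosting() -> "ModelSpec":
        """Reduced boosting grid for quick runs; same axes, fewer points."""
        return ModelSpec(
            "gradient_boosting",
            {
                "max_depth": [2, 4],
                "learning_rate": [0.05, 0.2],
                "bagging_fraction": [1.0],
                "reg_lambda": [10.0, 100.0],
            },
        )

    def candidates(self) -> list[dict]:
        keys = sorted(self.grid)
        combos = [dict(zip(keys, vals)) for vals in product(*(self.grid[k] for k in keys))]
        if self.family == "logistic_regression":
            combos.sort(key=lambda c: c.get("C", 1.0))
        else:
            combos.sort(
                key=lambda c: (
                    c.get("max_depth", 6),
                    -c.get("reg_lambda", 0.0),
                    c.get("learning_rate", 0.1),
                    -c.get("bagging_fraction", 1.0),
                )
            )
        return combos


def _make_estimator(spec: ModelSpec, params: dict, random_state: int):
    if spec.family == "logistic_regression":
        return LogisticRegression(C=params["C"], max_iter=2000, solver="lbfgs")
    p = dict(params)
    bagging = p.pop("bagging_fraction", 1.0)
    kw = dict(
        n_estimators=100,
        num_leaves=2 ** p.get("max_depth", 6),
        min_child_samples=5,
        random_state=random_state,
        deterministic=True,
        n_jobs=1,
        verbose=-1,
        **p,
    )
    if bagging < 1.0:
        kw.update(subsample=bagging, subsample_freq=1)
    return LGBMClassifier(**kw)


def normalize_importance(raw: np.ndarray) -> np.ndarray:
    """Scale a nonnegative importance vector to unit Euclidean norm.

    An all-zero vector is returned unchanged (the degenerate no-signal
    case is flagged by its zero norm rather than by NaNs).
    """
    raw = np.asarray(raw, dtype=float)
    norm = float(np.linalg.norm(raw))
    return raw / norm if norm > 0 else raw


def feature_importance(model, family: str, X: np.ndarray) -> np.ndarray:
    """Unit-norm global feature importance of a fitted model.

    Logistic: absolute coefficients (features are standardized, so these
    are standardized coefficients).  Boosting: mean absolute per-sample
    additive Shapley attribution from exact tree-path contributions.
    """
    if family == "logistic_regression":
        raw = np.abs(model.coef_[0])
    else:
        contrib = model.predict(np.asarray(X), pred_contrib=True)
        raw = np.abs(contrib[:, :-1]).mean(axis=0)  # last column is the bias term
    return normalize_importance(raw)


@dataclass
class CVResult:
    """Per-shuffle, per-outer-fold nested-CV results for one configuration."""

    feature_names: list[str]
    fold_aucs: np.ndarray  # (n_shuffles, n_outer)
    importances: np.ndarray  # (n_shuffles, n_outer, n_features)
    chosen_params: list[list[dict]]
    seed: int

    @property
    def shuffle_mean_aucs(self) -> np.ndarray:
        return self.fold_aucs.mean(axis=1)

    @property
    def mean_auc(self) -> float:
        return float(self.shuffle_mean_aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.shuffle_mean_aucs.std(ddof=1)) if len(self.fold_aucs) > 1 else 0.0

    @property
    def mean_importance(self) -> pd.Series:
        return pd.Series(
            self.importances.reshape(-1, len(self.feature_names)).mean(axis=0),
            index=self.feature_names,
        )


def nested_cv_evaluate(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
    n_shuffles: int = 50,
    seed: int = 0,
    n_outer: int = 5,
    n_inner: int = 5,
) -> CVResult:
    """Nested stratified cross-validation of one model/feature-set config.

    Per shuffle: a stratified outer ``n_outer``-fold split; per outer fold,
    features are standardized with training-fold statistics, an inner
    stratified ``n_inner``-fold exhaustive grid search maximizes AUC, the
    winning candidate is refit on the full outer-training fold, and AUC is
    measured on the held-out fold.  A shuffle whose split leaves a class
    absent from some fold is retried with an offset seed.
    """
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(Xv).any():
        raise ValueError("feature table contains missing cells")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 10:
        raise ValueError(f"need >= 10 patients per class, have {counts.tolist()}")
    candidates = spec.candidates()
    fold_aucs = np.empty((n_shuffles, n_outer))
    importances = np.empty((n_shuffles, n_outer, Xv.shape[1]))
    chosen: list[list[dict]] = []
    for s in range(n_shuffles):
        for attempt in range(5):
            rs = seed + s + attempt * 7919
            try:
                aucs, imps, params = _one_shuffle(
                    Xv, y, spec, candidates, rs, n_outer, n_inner
                )
                break
            except ValueError:
                if attempt == 4:
                    raise
                warnings.warn(f"shuffle {s}: degenerate split, retrying with offset seed")
        fold_aucs[s] = aucs
        importances[s] = imps
        chosen.append(params)
    return CVResult(list(X.columns), fold_aucs, importances, chosen, seed)


def _one_shuffle(Xv, y, spec, candidates, rs, n_outer, n_inner):
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=rs)
    aucs = np.empty(n_outer)
    imps = np.empty((n_outer, Xv.shape[1]))
    params_used = []
    for k, (tr, te) in enumerate(outer.split(Xv, y)):
        scaler = StandardScaler().fit(Xv[tr])
        Xtr, Xte = scaler.transform(Xv[tr]), scaler.transform(Xv[te])
        ytr, yte = y[tr], y[te]
        inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=rs + 1)
        inner_splits = list(inner.split(Xtr, ytr))
        best_score, best_params = -np.inf, None
        for cand in candidates:
            scores = []
            for itr, ite in inner_splits:
                est = _make_estimator(spec, cand, rs)
                est.fit(Xtr[itr], ytr[itr])
                p = est.predict_proba(Xtr[ite])[:, 1]
                scores.append(roc_auc_score(ytr[ite], p))
            score = float(np.mean(scores))
            if score > best_score:  # strict: ties keep the simpler candidate
                best_score, best_params = score, cand
        model = _make_estimator(spec, best_params, rs)
        model.fit(Xtr, ytr)
        aucs[k] = roc_auc_score(yte, model.predict_proba(Xte)[:, 1])
        imps[k] = feature_importance(model, spec.family, Xtr)
        params_used.append(best_params)
    return aucs, imps, params_used


@dataclass
class ComparisonResult:
    t_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float

    @property
    def delta(self) -> float:
        return self.mean_b - self.mean_a


def compare_feature_sets(result_a: CVResult, result_b: CVResult) -> ComparisonResult:
    """Two-sample t test on the per-shuffle mean AUCs of two configurations.

    Convention: ``result_a`` = without the HR feature, ``result_b`` = with.
    """
    a = result_a.shuffle_mean_aucs
    b = result_b.shuffle_mean_aucs
    if len(a) != len(b):
        raise ValueError(f"shuffle counts differ: {len(a)} vs {len(b)}")
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = ttest_ind(a, b)
        t, p = float(t), float(p)
    return ComparisonResult(
        t, p, float(a.mean()), float(a.std(ddof=1)), float(b.mean()), float(b.std(ddof=1))
    )


def build_feature_table(
    records: list[PatientRecord],
    nocturnal_hr: pd.Series | None = None,
    include_nocturnal_hr: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Assemble the ML feature table; returns ``(table, n_dropped)``.

    One row per patient with the clinical features, the ordinal troponin
    category, optionally the nocturnal HR feature, and the outcome label
    (column ``outcome``: 1 = unfavorable).  Patients with any missing cell
    are dropped and counted in ``n_dropped``.
    """
    rows = []
    for r in records:
        trop = categorize_troponin(r.troponin_ng_l) if r.troponin_ng_l else None
        try:
            outcome = dichotomize_outcome(r.mrs_discharge)
        except ValueError:
            outcome = None
        row = {
            "patient_id": r.patient_id,
            "age": r.age,
            "sex_male": {"male": 1.0, "female": 0.0}.get(r.sex, math.nan),
            "nihss": r.nihss,
            "hypertension": r.hypertension,
            "diabetes": r.diabetes,
            "prior_mi": r.prior_mi,
            "cad": r.cad,
            "pneumonia": r.pneumonia,
            "troponin_category": float(trop) if trop is not None else math.nan,
            "gfr": r.gfr,
            "outcome": 1.0 if outcome == "unfavorable" else (0.0 if outcome == "good" else math.nan),
        }
        if include_nocturnal_hr:
            row[HR_FEATURE] = (
                float(nocturnal_hr.get(r.patient_id, math.nan))
                if nocturnal_hr is not None
                else math.nan
            )
        rows.append(row)
    cols = ["patient_id"] + BASE_FEATURES + ([HR_FEATURE] if include_nocturnal_hr else []) + ["outcome"]
    df = pd.DataFrame(rows)[cols]
    complete = df.dropna()
    return complete.reset_index(drop=True), len(df) - len(complete)
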