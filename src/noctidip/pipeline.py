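"""End-to-end orchestration: ingest -> filter -> profile -> dip -> match -> ML.

``run_pipeline`` executes the full analysis on either a simulated cohort or
beat/covariate CSV files, writing every intermediate artifact (flow report,
segment metrics, circadian profiles, dip statistics, hourly tests, match
result, CV results, figures) into a run directory together with a
machine-readable manifest.  Outputs are byte-reproducible for a fixed
config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dipping, hrv, ingest, matching, model, synthetic
from .ingest import dichotomize_outcome

logger = logging.getLogger("noctidip")

_FLOAT_FMT = "%.10g"

MATCHING_PRESETS = {
    "age_nihss": ("age", "nihss"),
    "age": ("age",),
    "none": None,
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults follow the method's
    stated constants (48 h window, 5-min segments, 3-of-24 hourly quorum,
    night 22:00-05:00 / day 10:00-17:00, caliper 0.2, nested 5-fold CV)."""

    cohort_spec: synthetic.CohortSpec | None = None
    beats_csv: str | None = None
    covariates_csv: str | None = None
    window_hours: float = 48.0
    hourly_quorum: int = hrv.HOURLY_QUORUM
    min_normal_beats: int = ingest.DEFAULT_MIN_NORMAL_BEATS
    exclude_af: bool = True
    matching_preset: str = "age_nihss"
    caliper: float = matching.DEFAULT_CALIPER
    metrics: tuple[str, ...] = hrv.ALL_METRICS
    model_specs: tuple[model.ModelSpec, ...] = field(
        default_factory=lambda: (model.ModelSpec.default_logistic(),)
    )
    n_shuffles: int = 50
    seed: int = 0
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.matching_preset not in MATCHING_PRESETS:
            raise ValueError(f"unknown matching preset {self.matching_preset!r}")
        if self.cohort_spec is None and (self.beats_csv is None or self.covariates_csv is None):
            raise ValueError("provide either cohort_spec or beats_csv + covariates_csv")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage and write artifacts into ``out_dir``.

    Returns the in-memory results: flow report, segment/profiles frames,
    dip results, hourly tests, match result and CV results per model family
    and feature set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- ingest -----------------------------------------------------------
    if config.cohort_spec is not None:
        logger.info("simulating cohort (seed=%d)", config.cohort_spec.seed)
        cohort = synthetic.generate_cohort(config.cohort_spec)
    else:
        logger.info("loading cohort from %s / %s", config.beats_csv, config.covariates_csv)
        beats = ingest.read_beat_csv_multi(config.beats_csv)
        cov = ingest.read_covariates_csv(config.covariates_csv)
        cohort = ingest.records_from_tables(beats, cov)

    # --- trim + exclusions ------------------------------------------------
    cohort = [ingest.trim_to_window(r, config.window_hours) for r in cohort]
    analyzable, flow = ingest.apply_exclusions(
        cohort,
        min_normal_beats=config.min_normal_beats,
        exclude_af=config.exclude_af,
    )
    logger.info("exclusion cascade: %s", flow)
    _write(flow.to_frame(), out / "flow_report.csv")
    results["flow"] = flow

    # --- segment metrics + profiles ---------------------------------------
    seg_frames = []
    for rec in analyzable:
        normal = ingest.select_normal_beats(rec.series)
        seg_frames.append(
            hrv.compute_segment_metrics(normal, metrics=config.metrics)
        )
    segments = (
        pd.concat(seg_frames, ignore_index=True) if seg_frames else pd.DataFrame()
    )
    if len(segments):
        seg_out = segments.copy()
        seg_out["segment_start"] = pd.DatetimeIndex(seg_out["segment_start"]).strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
        _write(seg_out, out / "segment_metrics.csv")
    profiles = hrv.cohort_profiles(
        seg_frames, metrics=config.metrics, quorum=config.hourly_quorum
    )
    _write(hrv.profiles_to_frame(profiles), out / "profiles.csv")
    results["segments"] = segments
    results["profiles"] = profiles

    # --- outcome groups ---------------------------------------------------
    groups = pd.Series(
        {r.patient_id: dichotomize_outcome(r.mrs_discharge) for r in analyzable},
        name="group",
    )

    # --- matching ---------------------------------------------------------
    covariate_cols = MATCHING_PRESETS[config.matching_preset]
    cohort_df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in analyzable],
            "age": [r.age for r in analyzable],
            "nihss": [r.nihss for r in analyzable],
            "group": groups.loc[[r.patient_id for r in analyzable]].to_numpy(),
        }
    )
    if covariate_cols is not None and groups.nunique() == 2:
        propensity = matching.estimate_propensity(cohort_df, covariates=covariate_cols)
        match = matching.match_pairs(
            propensity, groups, caliper=config.caliper, seed=config.seed
        )
        match.balance = matching.balance_report(cohort_df, match, covariates=("age", "nihss"))
        _write(
            pd.DataFrame(match.pairs, columns=["patient_id_good", "patient_id_unfavorable"]),
            out / "match_pairs.csv",
        )
        _write(match.balance, out / "balance.csv")
        selected_ids = set(match.matched_ids)
        logger.info("matched %d pairs (caliper %.4f)", len(match.pairs), match.caliper_used)
    else:
        match = None
        selected_ids = {r.patient_id for r in analyzable}
    results["match"] = match
    selected = [r for r in analyzable if r.patient_id in selected_ids]
    sel_groups = groups.loc[[r.patient_id for r in selected]]
    results["selected_ids"] = sorted(selected_ids)

    # --- dipping + hourly tests -------------------------------------------
    hr_profiles = [
        profiles[r.patient_id]["hr"]
        for r in selected
        if r.patient_id in profiles and "hr" in profiles[r.patient_id]
    ]
    dips = [dipping.nocturnal_dip(p) for p in hr_profiles]
    _write(dipping.dips_to_frame(dips), out / "dip_results.csv")
    dip_summary = dipping.group_dip_summary(dips, sel_groups)
    _write(dip_summary, out / "dip_summary.csv")
    results["dips"], results["dip_summary"] = dips, dip_summary

    hourly_frames = []
    summaries = []
    for m in config.metrics:
        mats = hrv.hour_value_matrix(
            profiles[r.patient_id][m]
            for r in selected
            if r.patient_id in profiles and m in profiles[r.patient_id]
        )
        if sel_groups.nunique() == 2 and len(mats):
            ht = dipping.hourly_group_test(mats, sel_groups)
            ht.insert(0, "metric", m)
            hourly_frames.append(ht)
        summary = hrv.cohort_profile_summary(mats, sel_groups)
        summary.insert(0, "metric", m)
        summaries.append(summary)
    hourly_tests = (
        pd.concat(hourly_frames, ignore_index=True) if hourly_frames else pd.DataFrame()
    )
    if len(hourly_tests):
        _write(hourly_tests, out / "hourly_tests.csv")
    summary_df = pd.concat(summaries, ignore_index=True)
    _write(summary_df, out / "cohort_hourly_summary.csv")
    results["hourly_tests"] = hourly_tests
    results["hourly_summary"] = summary_df

    # --- outcome prediction ------------------------------------------------
    noct_hr = pd.Series(
        {p.patient_id: dipping.nocturnal_hr_feature(p) for p in hr_profiles}
    ).dropna()
    cv_results: dict[str, dict[str, model.CVResult]] = {}
    comparisons = {}
    ml_dropped = {}
    for spec in config.model_specs:
        per_set = {}
        for label, with_hr in (("without_hr", False), ("with_hr", True)):
            table, dropped = model.build_feature_table(
                selected, nocturnal_hr=noct_hr, include_nocturnal_hr=with_hr
            )
            ml_dropped[f"{spec.family}/{label}"] = dropped
            X = table.drop(columns=["patient_id", "outcome"])
            y = table["outcome"].to_numpy(dtype=int)
            logger.info(
                "nested CV: %s %s (n=%d, %d shuffles)", spec.family, label, len(y), config.n_shuffles
            )
            per_set[label] = model.nested_cv_evaluate(
                X, y, spec, n_shuffles=config.n_shuffles, seed=config.seed
            )
        cv_results[spec.family] = per_set
        comparisons[spec.family] = model.compare_feature_sets(
            per_set["without_hr"], per_set["with_hr"]
        )
    results["cv"] = cv_results
    results["comparisons"] = comparisons

    if cv_results:
        auc_rows, imp_rows = [], []
        for fam, per_set in cv_results.items():
            for label, res in per_set.items():
                for s, auc in enumerate(res.shuffle_mean_aucs):
                    auc_rows.append(
                        {"family": fam, "feature_set": label, "shuffle": s, "mean_auc": auc}
                    )
                for fname, v in res.mean_importance.items():
                    imp_rows.append(
                        {"family": fam, "feature_set": label, "feature": fname, "importance": v}
                    )
        _write(pd.DataFrame(auc_rows), out / "auc_per_shuffle.csv")
        _write(pd.DataFrame(imp_rows), out / "feature_importance.csv")
        comp_json = {
            fam: {
                "auc_without_hr": c.mean_a,
                "sd_without_hr": c.sd_a,
                "auc_with_hr": c.mean_b,
                "sd_with_hr": c.sd_b,
                "t_statistic": c.t_statistic,
                "p_value": c.p_value,
            }
            for fam, c in comparisons.items()
        }
        (out / "model_comparison.json").write_text(
            json.dumps(comp_json, indent=2, sort_keys=True) + "\n"
        )

    # --- manifest ----------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": _config_dict(config),
        "n_initial": flow.initial,
        "n_analyzable": flow.analyzable,
        "n_selected": len(selected),
        "ml_dropped": ml_dropped,
        "input_hashes": _input_hashes(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    if config.make_figures:
        from .plots import render_run_figures

        render_run_figures(out)
    return results


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    d = {k: enc(v) for k, v in dataclasses.asdict(config).items()}
    d["model_specs"] = [
        {"family": s.family, "grid": {k: list(map(float, v)) for k, v in s.grid.items()}}
        for s in config.model_specs
    ]
    return d


def _input_hashes(config: RunConfig) -> dict:
    hashes = {}
    for name in ("beats_csv", "covariates_csv"):
        path = getattr(config, name)
        if path and Path(path).exists():
            hashes[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return hashes


def run_config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a plain (YAML-friendly) mapping."""
    d = dict(d)
    if "cohort_spec" in d and isinstance(d["cohort_spec"], dict):
        d["cohort_spec"] = synthetic.cohort_spec_from_dict(d["cohort_spec"])
    if "model_specs" in d:
        specs = []
        for s in d["model_specs"]:
            if isinstance(s, str):
                specs.append(
                    model.ModelSpec.default_logistic()
                    if s == "logistic_regression"
                    else model.ModelSpec.default_boosting()
                )
            else:
                specs.append(model.ModelSpec(**s))
        d["model_specs"] = tuple(specs)
    if "metrics" in d:
        d["metrics"] = tuple(d["metrics"])
    return RunConfig(**d)
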