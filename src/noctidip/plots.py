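"""Figure rendering for pipeline run directories (mean+/-SD circadian
curves with the night window shaded and per-hour significance stars, and
AUC / feature-importance bars for the prediction models)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dipping import NIGHT_HOURS

_GROUP_COLORS = {"good": "tab:blue", "unfavorable": "tab:red"}


def plot_circadian_curves(summary: pd.DataFrame, hourly_tests: pd.DataFrame | None, path) -> None:
    metrics = list(summary["metric"].unique())
    fig, axes = plt.subplots(len(metrics), 1, figsize=(8, 2.4 * len(metrics)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, m in zip(axes, metrics):
        sub = summary[summary["metric"] == m]
        for g, gs in sub.groupby("group"):
            gs = gs.sort_values("hour")
            ax.errorbar(
                gs["hour"], gs["mean"], yerr=gs["sd"], label=g,
                color=_GROUP_COLORS.get(g, "gray"), capsize=2, lw=1.2,
            )
        for h in NIGHT_HOURS:
            ax.axvspan(h - 0.5, h + 0.5, color="0.85", zorder=0)
        if hourly_tests is not None and len(hourly_tests):
            sig = hourly_tests[(hourly_tests["metric"] == m) & hourly_tests["significant"]]
            ymax = sub["mean"].max() + sub["sd"].max()
            for h in sig["hour"]:
                ax.text(h, ymax, "*", ha="center", fontsize=11)
        ax.set_ylabel(m)
        ax.set_xticks(range(0, 24, 2))
    axes[0].legend(loc="upper right", fontsize=8)
    axes[-1].set_xlabel("clock hour")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_prediction(aucs: pd.DataFrame, importances: pd.DataFrame, path) -> None:
    families = list(aucs["family"].unique())
    fig, axes = plt.subplots(2, len(families), figsize=(5 * len(families), 7), squeeze=False)
    for j, fam in enumerate(families):
        ax = axes[0][j]
        sub = aucs[aucs["family"] == fam]
        stats = sub.groupby("feature_set")["mean_auc"].agg(["mean", "std"])
        order = [s for s in ("without_hr", "with_hr") if s in stats.index]
        ax.bar(
            range(len(order)),
            stats.loc[order, "mean"],
            yerr=stats.loc[order, "std"],
            color=["tab:blue", "tab:orange"][: len(order)],
            capsize=4,
        )
        ax.set_xticks(range(len(order)), order)
        ax.set_ylabel("AUC")
        ax.set_title(fam)
        ax = axes[1][j]
        isub = importances[
            (importances["family"] == fam) & (importances["feature_set"] == "with_hr")
        ].sort_values("importance", ascending=True)
        ax.barh(isub["feature"], isub["importance"], color="tab:orange")
        ax.set_xlabel("unit-norm importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_run_figures(run_dir) -> list[Path]:
    """Render figures from the CSV artifacts of a pipeline run directory."""
    run_dir = Path(run_dir)
    made = []
    summary_path = run_dir / "cohort_hourly_summary.csv"
    if summary_path.exists():
        summary = pd.read_csv(summary_path)
        tests_path = run_dir / "hourly_tests.csv"
        tests = pd.read_csv(tests_path) if tests_path.exists() else None
        out = run_dir / "circadian_profiles.png"
        plot_circadian_curves(summary, tests, out)
        made.append(out)
    auc_path = run_dir / "auc_per_shuffle.csv"
    if auc_path.exists():
        out = run_dir / "prediction.png"
        plot_prediction(
            pd.read_csv(auc_path), pd.read_csv(run_dir / "feature_importance.csv"), out
        )
        made.append(out)
    return made
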