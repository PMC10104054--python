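"""Figure regeneration from stored results tables.

Each renderer consumes the tidy CSVs written by the analysis scripts (or
:mod:`beliefrnn.experiments`) and reproduces the corresponding
computational panel: RPE-vs-reward-time curves, before/after-training
metric comparisons, PCA trajectories, distance-from-fixed-point traces,
capacity sweeps, and ESN gain sweeps.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_rpe_by_reward_time",
    "plot_cohort_metric",
    "plot_memory_traces",
    "plot_pca_trajectory",
    "plot_capacity_sweep",
    "plot_esn_sweep",
    "render_all",
]


def _save(fig, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_rpe_by_reward_time(curves: pd.DataFrame, path: Path,
                            title: str = "RPE at reward vs. reward time") -> Path:
    """Mean reward-time RPE per ISI, one line per model label."""
    fig, ax = plt.subplots(figsize=(4, 3))
    for label, sub in curves.groupby("model"):
        style = "--" if label == "beliefs" else "-"
        ax.errorbar(sub["group"], sub["mean"], yerr=sub["sem"],
                    fmt=style + "o", ms=3, label=str(label))
    ax.set_xlabel("reward time (steps after odor)")
    ax.set_ylabel("RPE at reward")
    ax.set_title(title)
    ax.legend(fontsize=7)
    return _save(fig, path)


def plot_cohort_metric(results: pd.DataFrame, metric: str, path: Path,
                       logy: bool = False) -> Path:
    """Per-model values before vs. after training, medians overlaid."""
    sub = results[results["metric"] == metric]
    fig, ax = plt.subplots(figsize=(3.2, 3))
    stages = ["untrained", "trained"]
    for x, stage in enumerate(stages):
        vals = sub.loc[sub["stage"] == stage, "value"].to_numpy()
        if len(vals) == 0:
            continue
        ax.plot(np.full(len(vals), x) + np.random.default_rng(0).uniform(
            -0.06, 0.06, len(vals)), vals, "o", ms=4, alpha=0.6)
        ax.plot([x - 0.15, x + 0.15], [np.median(vals)] * 2, "k-", lw=2)
    ax.set_xticks(range(len(stages)), stages)
    ax.set_ylabel(metric)
    if logy:
        ax.set_yscale("log")
    return _save(fig, path)


def plot_memory_traces(traces: pd.DataFrame, path: Path) -> Path:
    """Normalized distance from the fixed point after an observation."""
    fig, axes = plt.subplots(1, 2, figsize=(7, 3), sharey=True)
    for ax, kind in zip(axes, ("odor", "reward")):
        sub = traces[traces["kind"] == kind]
        for label, s in sub.groupby("model"):
            style = "k-" if label == "beliefs" else "-"
            ax.plot(s["t"], s["eta_norm"], style, lw=1, alpha=0.8, label=str(label))
        ax.axhline(1e-3, color="gray", ls=":", lw=0.8)
        ax.set_yscale("log")
        ax.set_title(f"{kind} response")
        ax.set_xlabel("steps since observation")
    axes[0].set_ylabel("normalized distance from fixed point")
    axes[0].legend(fontsize=6)
    return _save(fig, path)


def plot_pca_trajectory(proj: pd.DataFrame, path: Path,
                        title: str = "hidden-state trajectory (top-2 PCs)") -> Path:
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    for label, sub in proj.groupby("segment"):
        ax.plot(sub["pc1"], sub["pc2"], "-o", ms=2, lw=0.8, label=str(label))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(title)
    ax.legend(fontsize=6)
    return _save(fig, path)


def plot_capacity_sweep(summary: pd.DataFrame, path: Path) -> Path:
    """RPE MSE, belief R², decoder log-likelihood as functions of H."""
    metrics = ["rpe_mse", "belief_r2", "decoder_loglik"]
    fig, axes = plt.subplots(1, len(metrics), figsize=(9, 2.8))
    for ax, metric in zip(axes, metrics):
        sub = summary[(summary["metric"] == metric)
                      & (summary["stage"] == "trained")]
        if len(sub) == 0:
            continue
        ax.errorbar(sub["hidden"], sub["mean"], yerr=sub["sem"], fmt="-o", ms=4)
        ax.set_xscale("log")
        ax.set_xlabel("hidden units")
        ax.set_ylabel(metric)
        if metric == "rpe_mse":
            ax.set_yscale("log")
    return _save(fig, path)


def plot_esn_sweep(summary: pd.DataFrame, path: Path) -> Path:
    """Odor memory, RPE MSE and belief R² against initialization gain."""
    metrics = ["odor_memory", "rpe_mse", "belief_r2"]
    fig, axes = plt.subplots(1, len(metrics), figsize=(9, 2.8))
    for ax, metric in zip(axes, metrics):
        sub = summary[summary["metric"] == metric]
        if len(sub) == 0:
            continue
        ax.errorbar(sub["gain"], sub["mean"], yerr=sub["sem"], fmt="-o", ms=4)
        ax.set_xlabel("initialization gain")
        ax.set_ylabel(metric)
        if metric == "rpe_mse":
            ax.set_yscale("log")
    return _save(fig, path)


_RENDERERS = {
    "rpe_curves": ("rpe_curves.csv", plot_rpe_by_reward_time),
    "memory_traces": ("memory_traces.csv", plot_memory_traces),
    "pca_trajectory": ("pca_trajectory.csv", plot_pca_trajectory),
}


def render_all(results_dir: Path, outdir: Path) -> list[Path]:
    """Render every figure whose input table exists in ``results_dir``."""
    written: list[Path] = []
    for name, (csv_name, fn) in _RENDERERS.items():
        src = results_dir / csv_name
        if src.exists():
            written.append(fn(pd.read_csv(src), outdir / f"{name}.png"))
    for csv in sorted(results_dir.glob("cohort_*_summary.csv")):
        summary = pd.read_csv(csv)
        if summary["hidden"].nunique() > 1:
            written.append(
                plot_capacity_sweep(summary, outdir / f"{csv.stem}_capacity.png")
            )
    for csv in sorted(results_dir.glob("cohort_*.csv")):
        if csv.stem.endswith("_summary") or csv.stem.endswith("_config"):
            continue
        results = pd.read_csv(csv)
        for metric, logy in (("rpe_mse", True), ("belief_r2", False)):
            if (results["metric"] == metric).any():
                written.append(plot_cohort_metric(
                    results, metric, outdir / f"{csv.stem}_{metric}.png", logy=logy
                ))
    sweep = results_dir / "esn_sweep_summary.csv"
    if sweep.exists():
        written.append(plot_esn_sweep(pd.read_csv(sweep), outdir / "esn_sweep.png"))
    return written
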