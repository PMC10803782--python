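"""Plotting helpers: performance curves, null histograms, task rasters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_performance_curve(curve, path: str | Path, metric: str | None = None) -> Path:
    """Mean performance vs alpha with a 95% CI band, one line per activation."""
    s = curve.summary
    metric = metric or sorted(s["metric"].unique())[0]
    s = s[s["metric"] == metric]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for act, grp in s.groupby("activation"):
        grp = grp.sort_values("alpha")
        ax.plot(grp["alpha"], grp["mean"], label=act)
        ax.fill_between(grp["alpha"], grp["ci_low"], grp["ci_high"], alpha=0.25)
    ax.axvline(1.0, ls=":", c="k", lw=0.8)
    ax.set_xlabel(r"spectral radius $\alpha$")
    ax.set_ylabel(metric)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_null_distribution(comparison, path: str | Path) -> Path:
    """Histogram of the null statistic with the empirical value marked."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.hist(comparison.null_values, bins=20, color="0.6", label="rewired nulls")
    ax.axvline(comparison.empirical_value, color="crimson", lw=2, label="empirical")
    ax.set_xlabel(comparison.metric)
    ax.set_ylabel("count")
    ax.set_title(f"p = {comparison.p_value:.4g} ({comparison.alternative})")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_task_raster(dataset, path: str | Path, max_timesteps: int = 200) -> Path:
    """Stacked input channels and target over time, trial boundaries dotted."""
    T = min(dataset.n_timesteps, max_timesteps)
    X = dataset.inputs[:T]
    y = np.atleast_2d(dataset.targets.T).T[:T]
    fig, axes = plt.subplots(2, 1, figsize=(7, 4), sharex=True,
                             height_ratios=[3, 1])
    offset = 0.0
    for c in range(X.shape[1]):
        span = X[:, c].ptp() or 1.0
        axes[0].plot(X[:, c] / span + offset, lw=0.8)
        offset += 1.2
    axes[1].plot(y[:, 0], c="k", lw=1.0)
    for s, _ in dataset.trial_bounds:
        if s == 0 or s >= T:
            continue
        for ax in axes:
            ax.axvline(s, ls=":", c="k", lw=0.6)
    axes[0].set_ylabel("inputs $x_i$")
    axes[1].set_ylabel("target $y$")
    axes[1].set_xlabel("timestep")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
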