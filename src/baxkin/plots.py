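"""Publication-style figures for recruitment-kinetics populations.

Frequency outlines of log2 rates, rate-vs-initiation scatter plots with
per-cell highlighting, box-and-whisker condition comparisons, and per-cell
CV dot plots.  All functions draw on a supplied Axes (or create one) and
return it; file output is left to the caller except for
:func:`summary_figure`.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "frequency_outline",
    "rate_vs_initiation",
    "condition_boxplot",
    "cv_dot_plot",
    "summary_figure",
]


def frequency_outline(values, ax=None, bins=25, label=None, color=None):
    """Outline of a frequency histogram (no fill), one line per population."""
    ax = ax or plt.gca()
    counts, edges = np.histogram(np.asarray(values), bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2
    ax.plot(centers, counts, drawstyle="steps-mid", label=label, color=color)
    ax.set_ylabel("foci")
    return ax


def rate_vs_initiation(metrics: pd.DataFrame, ax=None, highlight_cells=2, seed=0):
    """Scatter of log2 rate vs corrected initiation; a few cells highlighted.

    Vertically stacked markers from one highlighted cell show synchronous
    initiation with stratified rates.
    """
    ax = ax or plt.gca()
    ax.scatter(metrics["initiation_corrected_min"], metrics["log2_rate"],
               s=12, c="0.7", label="all foci")
    cells = sorted(metrics["cell_id"].unique())
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cells, size=min(highlight_cells, len(cells)), replace=False)
    for cell, color in zip(chosen, ("crimson", "goldenrod", "teal")):
        sub = metrics[metrics["cell_id"] == cell]
        ax.scatter(sub["initiation_corrected_min"], sub["log2_rate"],
                   s=24, c=color, label=str(cell))
    ax.set_xlabel("BAX recruitment initiation (min after stimulus)")
    ax.set_ylabel("recruitment rate (log2 RFU/min)")
    ax.legend(fontsize="x-small")
    return ax


def condition_boxplot(metrics: pd.DataFrame, column: str, ax=None):
    """Box-and-whisker of one metric per condition."""
    ax = ax or plt.gca()
    conditions = sorted(metrics["condition"].unique())
    data = [metrics.loc[metrics["condition"] == c, column].dropna() for c in conditions]
    ax.boxplot(data, tick_labels=conditions)
    ax.set_ylabel(column)
    return ax


def cv_dot_plot(per_cell: pd.DataFrame, ax=None):
    """Per-cell CV dots for rate vs initiation, with condition means as bars."""
    ax = ax or plt.gca()
    for i, (name, color) in enumerate((("cv_rate", "crimson"),
                                       ("cv_initiation", "royalblue"))):
        x = np.full(len(per_cell), i) + np.linspace(-0.15, 0.15, len(per_cell))
        ax.scatter(x, per_cell[name], s=14, c=color, alpha=0.8)
        ax.hlines(per_cell[name].mean(), i - 0.25, i + 0.25, color=color)
    ax.set_xticks([0, 1], ["rate", "initiation"])
    ax.set_ylabel("per-cell CV (%)")
    return ax


def summary_figure(metrics: pd.DataFrame, cv_report, path: str | Path):
    """Four-panel summary (frequency outline, scatter, box, CV dots) to file."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    frequency_outline(metrics["log2_rate"].dropna(), ax=axes[0, 0])
    axes[0, 0].set_xlabel("recruitment rate (log2 RFU/min)")
    rate_vs_initiation(metrics, ax=axes[0, 1])
    condition_boxplot(metrics, "log2_rate", ax=axes[1, 0])
    per_cell = cv_report.per_cell if hasattr(cv_report, "per_cell") else cv_report
    if len(per_cell):
        cv_dot_plot(per_cell, ax=axes[1, 1])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
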