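"""Population and per-cell statistics for recruitment kinetics.

Implements the statistical workflow applied to per-focus kinetic metrics:
log2 transformation of recruitment rates (rates are approximately lognormal,
so the transform normalizes their distribution), a single-pass two-standard-
deviation outlier screen, one-way ANOVA across conditions, per-cell
coefficient-of-variation (CV) analysis — the statistic that exposes
synchronous initiation (CV of a few percent) against heterogeneous rates
(CV of 50–150%) — and Pearson chi-square tests for localization
distributions (punctate vs diffuse scoring).

The "two-tailed covariance test" sometimes invoked for comparing the
variability of two metrics has no standard identity; :func:`compare_cv`
offers two labelled interpretations — a paired two-sided Wilcoxon signed-rank test on per-cell
CV differences (default) and a sign-flip permutation test on the same
differences — both exact about what they test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CVReport",
    "transform_rates",
    "remove_outliers",
    "anova_oneway",
    "cv_per_cell",
    "compare_cv",
    "chi2_localization",
]


@dataclass
class CVReport:
    """Per-cell CVs (percent) and their condition-level means."""

    per_cell: pd.DataFrame  # condition, cell_id, n_foci, cv_rate, cv_initiation
    per_condition: pd.DataFrame  # condition, n_cells, mean_cv_rate, mean_cv_initiation


def transform_rates(table: pd.DataFrame, rate_column: str = "max_rate") -> pd.DataFrame:
    """Add (or refresh) a log2_rate column; idempotent.

    Rows with nonpositive rates cannot be transformed; they are excluded and
    reported with a warning naming them.
    """
    if rate_column not in table.columns:
        raise ValueError(f"missing column {rate_column!r}")
    bad = table[table[rate_column] <= 0]
    if len(bad):
        ids = bad[["cell_id", "focus_id"]].to_records(index=False).tolist() \
            if {"cell_id", "focus_id"} <= set(table.columns) else bad.index.tolist()
        warnings.warn(
            f"excluding {len(bad)} rows with nonpositive {rate_column}: {ids[:10]}",
            stacklevel=2,
        )
    out = table[table[rate_column] > 0].copy()
    out["log2_rate"] = np.log2(out[rate_column])
    return out


def remove_outliers(
    table: pd.DataFrame,
    column: str,
    by: str | None = "condition",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass 2-SD outlier screen; returns (kept, removed).

    A row is an outlier when |x - mean| >= 2 * SD, with mean and SD
    (population, ddof=0) computed once from the full input — the screen is
    non-iterative.  By default the screen is applied within each level of
    ``by`` (per condition); pass ``by=None`` for a pooled screen.
    """
    if column not in table.columns:
        raise ValueError(f"missing column {column!r}")
    if by is not None and by not in table.columns:
        by = None
    groups = [g for _, g in table.groupby(by, sort=False)] if by else [table]
    kept_parts, removed_parts = [], []
    for g in groups:
        if len(g) < 3:
            raise ValueError("need at least 3 rows for the outlier screen")
        x = g[column].to_numpy(dtype=float)
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=0))
        if sd == 0.0:
            outlier = np.zeros(len(g), dtype=bool)
        else:
            outlier = np.abs(x - mean) >= 2.0 * sd
        kept_parts.append(g[~outlier])
        removed_parts.append(g[outlier])
    kept = pd.concat(kept_parts).sort_index()
    removed = pd.concat(removed_parts).sort_index()
    return kept, removed


def anova_oneway(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p).

    Degenerate inputs (no between- or within-group variance) are handled:
    identical data in every group gives F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    grand = np.concatenate(arrays)
    ssb = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    dfb = len(arrays) - 1
    dfw = len(grand) - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return float(f), p


def cv_per_cell(
    table: pd.DataFrame,
    rate_column: str = "max_rate",
    initiation_column: str = "initiation_corrected_min",
    epsilon: float = 1e-12,
) -> CVReport:
    """Per-cell coefficient of variation (percent) of rate and initiation.

    CV = 100 * SD / |mean| with sample SD (ddof=1), computed per cell over
    its foci — rates untransformed.  Cells with fewer than 2 foci are
    undefined and dropped; a cell whose metric mean is ~0 is excluded with a
    warning.  Condition-level mean CVs summarize each condition.
    """
    cols = {"cell_id", rate_column, initiation_column}
    missing = cols - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    has_condition = "condition" in table.columns
    keys = ["condition", "cell_id"] if has_condition else ["cell_id"]
    rows = []
    for key, g in table.groupby(keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        if len(g) < 2:
            continue
        row = dict(zip(keys, key))
        row["n_foci"] = len(g)
        skip = False
        for name, col in (("cv_rate", rate_column), ("cv_initiation", initiation_column)):
            x = g[col].to_numpy(dtype=float)
            if abs(x.mean()) < epsilon:
                warnings.warn(
                    f"cell {key} excluded: |mean {col}| < {epsilon}", stacklevel=2
                )
                skip = True
                break
            row[name] = 100.0 * float(np.std(x, ddof=1)) / abs(float(x.mean()))
        if not skip:
            rows.append(row)
    per_cell = pd.DataFrame(rows)
    if len(per_cell) == 0:
        return CVReport(per_cell, pd.DataFrame())
    if not has_condition:
        per_cell.insert(0, "condition", "all")
    per_condition = (
        per_cell.groupby("condition")
        .agg(n_cells=("cell_id", "size"),
             mean_cv_rate=("cv_rate", "mean"),
             mean_cv_initiation=("cv_initiation", "mean"))
        .reset_index()
    )
    return CVReport(per_cell, per_condition)


def compare_cv(
    report: CVReport | pd.DataFrame,
    metric_a: str = "cv_rate",
    metric_b: str = "cv_initiation",
    method: Literal["wilcoxon", "permutation"] = "wilcoxon",
    n_permutations: int = 10000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Two-sided paired test of equal variability between two metrics' CVs.

    Tests whether the per-cell CVs of ``metric_a`` and ``metric_b`` differ,
    via the paired per-cell differences: either a Wilcoxon signed-rank test
    (default) or a sign-flip permutation test of the mean difference.
    Returns (statistic, p).  Identical CV vectors give statistic 0, p = 1.
    """
    per_cell = report.per_cell if isinstance(report, CVReport) else report
    if metric_a not in per_cell.columns or metric_b not in per_cell.columns:
        raise ValueError(f"need columns {metric_a!r} and {metric_b!r}")
    diff = (per_cell[metric_a] - per_cell[metric_b]).to_numpy(dtype=float)
    if len(diff) < 3:
        raise ValueError("need at least 3 cells for compare_cv")
    if np.all(diff == 0):
        return 0.0, 1.0
    if method == "wilcoxon":
        res = sps.wilcoxon(diff, alternative="two-sided", zero_method="wilcox",
                           method="approx", correction=False)
        return float(res.statistic), float(res.pvalue)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        observed = float(np.mean(diff))
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(diff)))
        null = (signs * diff).mean(axis=1)
        p = (1 + np.sum(np.abs(null) >= abs(observed))) / (1 + n_permutations)
        return observed, float(p)
    raise ValueError(f"unknown method {method!r}")


def chi2_localization(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    *more: Sequence[int],
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on localization counts.

    Each argument is a (cytosolic, mitochondrial) count pair — or, more
    generally, category counts — for one test group; the table is 2xk (or
    mxk).  Identical proportions give chi2 = 0, p = 1.  A zero expected cell
    count is an error.
    """
    table = np.asarray([counts_a, counts_b, *more], dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected cell count; test undefined")
    chi2, p, _dof, _exp = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
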