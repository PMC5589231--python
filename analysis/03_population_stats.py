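"""Population comparisons and per-cell synchrony statistics.

Log2-transforms recruitment rates, applies the per-condition 2-SD outlier
screen, compares the three cell lines by one-way ANOVA (initiation times and
rates), computes per-cell CVs — the statistic separating synchronous
initiation (CV of a few percent) from heterogeneous rates (CV of 50-150%) —
and tests rate-vs-initiation variability per condition.  Writes tidy tables
and a four-panel summary figure under results/stats/.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from baxkin import plots, stats

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "stats"
CELL_LINES = ("d407", "hela", "hct116")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = [pd.read_csv(ROOT / "metrics" / f"{n}_metrics.csv") for n in CELL_LINES]
    metrics = pd.concat(tables, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        metrics = stats.transform_rates(metrics)
    kept, removed = stats.remove_outliers(metrics, "log2_rate")
    print(f"{len(removed)} rate outliers removed (2 SD, per condition)")

    summary: dict = {"n_foci": int(len(kept))}
    for column, label in (("log2_rate", "recruitment rate (log2 RFU/min)"),
                          ("initiation_corrected_min", "initiation time (min)")):
        groups = [g[column].to_numpy() for _, g in kept.groupby("condition")]
        f, p = stats.anova_oneway(*groups)
        summary[f"anova_{column}"] = {"F": f, "p": p}
        print(f"one-way ANOVA on {label}: F = {f:.1f}, p = {p:.3g}")

    cv = stats.cv_per_cell(kept)
    cv.per_cell.to_csv(OUT / "cv_per_cell.csv", index=False)
    cv.per_condition.to_csv(OUT / "cv_per_condition.csv", index=False)
    print(cv.per_condition.to_string(index=False))
    for cond, g in cv.per_cell.groupby("condition"):
        stat, p = stats.compare_cv(g)
        summary[f"compare_cv_{cond}"] = {"statistic": stat, "p": p}
        print(f"{cond}: rate vs initiation variability, Wilcoxon p = {p:.3g}")

    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    plots.summary_figure(kept, cv, OUT / "summary.png")
    print(f"wrote {OUT}/summary.json and summary.png")


if __name__ == "__main__":
    main()
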