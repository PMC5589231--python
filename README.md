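# baxkin

Kinetic analysis of BAX recruitment and mitochondrial outer membrane
permeabilization (MOMP) at individual mitochondrial foci, from live-cell
time-lapse fluorescence traces.

During intrinsic apoptosis the pro-apoptotic BCL2-family protein BAX
translocates from the cytosol to discrete mitochondrial foci, oligomerizes,
and permeabilizes the outer membrane, releasing cytochrome c, SMAC and AIF.
Followed with fluorescent BAX fusion proteins at one z-stack per minute,
each focus traces out a sigmoidal rise in fluorescence; released molecules
trace a mirrored decay.  `baxkin` turns such traces (or synthetic 3D+t image
stacks emulating them) into per-focus kinetic metrics and population
statistics: it is aimed at cell biologists quantifying MOMP dynamics in
time-lapse data, and at anyone needing a fully testable, ground-truthed
reference implementation of that workflow.

## The model

Each normalized per-focus trace is fitted by nonlinear least squares with
the modified sigmoid

```
y(x) = a / (b + e^{-k (x - x0)}) + y0
```

(`b` is redundant with `a` and `x0`; the fitter fixes `b = 1`, an exact
reparameterization).  All kinetic metrics are closed forms of the fit:

| metric | formula | meaning |
| --- | --- | --- |
| amplitude | `a/b` | total fluorescence gain (RFU) |
| maximum rate | `a·k/(4b)` | slope at the inflection (RFU/min) |
| inflection | `x0 − ln(b)/k` | time of maximum rate |
| initiation | `inflection − 2/k` | tangent at the inflection meets `y = y0` |
| completion | `inflection + 2/k` | tangent meets the upper plateau |

At initiation the curve has risen by exactly `amplitude/(1 + e²)` ≈ 11.9% —
the "12% threshold".  Times are corrected by adding the delay between the
apoptotic stimulus and the first frame.  Decay traces of released molecules
are fitted with the same model (`a < 0`); the per-focus release time is
referenced to the same focus's BAX initiation.  Population statistics follow
the study workflow: log2-transformed rates, a single-pass 2-SD outlier
screen, one-way ANOVA between conditions, Pearson χ² for localization
scoring, and per-cell coefficients of variation — the statistic showing that
recruitment *initiation* is synchronous within a cell (CV ≈ 1–5%) while
recruitment *rates* are heterogeneous (CV ≈ 50–150%).

A seeded synthetic-data generator (`baxkin.synthetic`) emulates the imaging
output — per-cell synchronous onsets, lognormal per-focus rates, paired
release decays, acquisition noise, and optionally rendered 3D+t TIFF stacks —
and records every sampled parameter, so each pipeline stage is testable
against ground truth without any external data.

## Worked example

```python
import baxkin
from baxkin import kinetics, stats, synthetic

pop = synthetic.get_preset("d407")              # 41 cells, ~16 foci each
traces, truth = synthetic.simulate_population(pop, seed=1)
metrics, excluded = kinetics.fit_trace_table(
    traces, acquisition_delay_min=pop.cell.acquisition_delay_min)
metrics.insert(0, "condition", "d407")

kept, _ = stats.remove_outliers(stats.transform_rates(metrics), "log2_rate")
cv = stats.cv_per_cell(kept)
print(cv.per_condition.round(2).to_string(index=False))
stat, p = stats.compare_cv(cv)
print(f"rate vs initiation variability: p = {p:.2e}")
```

prints

```
condition  n_cells  mean_cv_rate  mean_cv_initiation
     d407       41         55.34                2.04
rate vs initiation variability: p = 2.42e-08
```

i.e. within a cell the fitted recruitment rates vary by ~55% of their mean
while initiation times vary by only ~2% — recruitment starts synchronously
at all of a cell's foci but proceeds at focus-specific rates, and the
difference in variability is significant.  The same workflow is laid out as
numbered drivers under `analysis/` (simulate → fit → population stats →
release timing → imaging round trip), which write their tables under
`results/`.  A command-line interface mirrors the stages:

```
baxkin simulate --preset cytc --seed 1 --out traces.csv
baxkin track --stack ch_bax.tif --out traces.csv      # from rendered stacks
baxkin fit --traces traces.csv --delay-min 90 --out metrics.csv
baxkin stats --metrics metrics.csv --out report/
baxkin run --config run.yaml                          # full seeded pipeline
```

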