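# Methods

This note documents the model, the synthetic-data generator, the numerical
choices and the known limitations of `baxkin`. It states how quantities are
defined and computed; every empirical number it mentions is one the test
suite or `scripts/acceptance.py` computes at run time.

## The sigmoid model and its metrics

A per-focus fluorescence trace during BAX recruitment is modelled as

    y(x) = a / (b + exp(-k (x - x0))) + y0

with amplitude A = a/b, steepness k (per minute), and plateaus y0 and
y0 + A. The five-parameter form is over-parameterized: (a, b, x0) enter the
curve only through a/b and x0 − ln(b)/k, so the same curve corresponds to a
one-parameter family of (a, b, x0) triples. The fitter therefore fixes
b = 1 — an exact reparameterization, not an approximation — and reports
b = 1.0 in `SigmoidFit`; `derive_metrics` keeps the general-b closed forms
so externally constructed parameter sets are handled.

Metric definitions (all closed forms; oracle-equivalence tests check them
against grid maximization of the derivative and a geometric line
intersection):

- maximum rate `a·k/(4b)`: the slope at the inflection `x0 − ln(b)/k`;
- initiation `inflection − 2/k`: where the tangent through the inflection,
  with slope equal to the maximum rate, meets the lower plateau y = y0. The
  curve there has risen by exactly A/(1+e²) ≈ 11.92% of the amplitude — the
  "12% threshold". The older 5%-threshold convention is deliberately not
  implemented; the tangent rule is the operative definition;
- completion `inflection + 2/k`: the symmetric upper counterpart (≈ 88%
  level). The definition is symmetric by construction;
- corrected times add the stimulus-to-acquisition delay, so all reported
  times are minutes after apoptotic induction;
- log2 rate: rates are approximately lognormal across foci, so population
  statistics use log2-transformed rates.

Release of a pro-apoptotic molecule (cytochrome c, SMAC, AIF) is a mirrored
sigmoid (a < 0) whose upper plateau is the pre-release level. The same
tangent rule applied to the departure from that plateau defines the release
time; the release rate is the maximum decay slope `a·k/(4b) < 0`. The
per-focus offset is release time minus the same focus's BAX initiation;
both are on the acquisition clock, so the offset is delay-invariant
(whether the source study corrected release times before differencing is
unknowable; the offset defined here does not depend on it).

### Scale conventions

BAX traces are normalized to their first time point ("relative fluorescence
units", RFU), so recruitment rates are in normalized RFU/min. Release
traces are fitted on the acquisition intensity scale instead: a
unit-normalized decay has at most 1 RFU of amplitude, so a sustained decay
slope of magnitude ≈ 1 RFU/min would complete its 12–88% transition in
under one 1-minute sampling interval and carry no identifiable steepness;
magnitudes like the reported cytochrome c and SMAC release rates are only
measurable on the acquisition scale. Offsets and release times are
scale-invariant and unaffected by this convention.

## Fitting

`fit_sigmoid` is nonlinear least squares (`scipy.optimize.curve_fit`,
trust-region reflective, tolerances 1e-14) on the identifiable
four-parameter form. Initialization is data-driven: plateau from the quiet
end, x0 at the steepest smoothed finite difference, k = 4·slope/range.
Because a single start can be trapped by a noise step masquerading as the
transition, three deterministic starts are tried (gradient-based,
mid-range-crossing, and a slow-k variant) and the lowest-SSE solution kept;
the fit remains deterministic given data and options.

A fit is marked failed (and the focus excluded, with the reason counted in
the run report) when:

- the trace range is below `flat_epsilon` ("no transition");
- the optimizer fails, or k ends pinned at its bounds (no resolvable
  transition, or one faster than the sampling supports);
- the fitted |a| is less than half the observed trace range — the fit
  latched onto a noise step rather than the event;
- the fitted initiation→completion interval is not contained in the
  acquisition window ("event not encompassed"). This is the trace-level
  analogue of the track-selection criterion that a track must encompass the
  recruitment event: a transition truncated by the movie boundary has no
  identifiable kinetics. It applies to recruitment and release fits alike,
  and is what keeps slow, movie-truncated decays (an AIF-like regime) from
  contributing arbitrary timings.

## Synthetic data: what it emulates

`simulate_cell`/`simulate_population` generate, per focus, a noiseless
sigmoid whose parameters are solved in closed form from sampled onset
(initiation time), maximum rate, amplitude and baseline, plus i.i.d.
additive Gaussian noise; 1-minute sampling over 2–3 h after a
stimulus-to-acquisition delay. The statistical structure follows the
live-cell observations being emulated:

- onsets: Normal within a cell (small spread — synchronous initiation);
  cell-level mean onsets Normal across cells, truncated to
  [0.05, 0.60] × duration because treatments are staggered precisely so the
  recruitment event falls inside the movie — cells recruiting before the
  first frame are never recorded;
- rates: log2-Normal within and between cells (motivating the pipeline's
  log2 transform);
- release: per-focus release time offset from that focus's BAX onset by a
  Normal; decay-slope magnitudes lognormal, moment-matched to the stated
  mean ± SD (a Normal with those moments would put substantial mass at
  non-negative slopes, i.e. no decay, and truncating it would shift the
  mean);
- noise: additive Gaussian, default SD 5% of the mean amplitude. No
  photophysics (bleaching, blinking), no fission/fusion, no
  retrotranslocation.

Named presets (`d407`, `hela`, `hct116`, `cytc`, `smac`, `aif`) carry the
headline conditions — cell and focus counts, mean log2 rates, within-cell
CVs, release offsets and rates — as *emulation targets, not measurements*.
Two calibrations make the emulated condition reproduce the reported
statistic rather than its large-sample limit:

- a reported per-cell CV is the mean of *sample* CVs over ~16 (or 7, 8)
  foci, a statistic whose expectation sits below the distribution CV;
  `within_cell_log2_sd` inverts that mapping numerically (and
  `sample_sd_correction` applies the c4 correction for the normal onsets);
- release-rate lognormals are moment-matched to the stated mean ± SD.

Free parameters the source data do not constrain: amplitude statistics
(mean 2.0 ± 0.5 RFU over a baseline of 1 — a 3× fluorescence gain) and
release start levels, which are chosen per molecule so the sampled decay
slopes give transition widths resolvable at 1-minute sampling. The HeLa
preset is internally strained: a 150% mean sample CV at ~7 foci/cell
requires a within-cell log2-SD (≈ 2.8) exceeding the condition's stated
population SD; the preset prioritizes the CV and sets the between-cell rate
spread to zero.

`simulate_stack` renders traces as drifting 3D Gaussian spots (peak
proportional to trace intensity) over a constant background with Gaussian
noise, one uint16 T-Z-Y-X TIFF per channel, and records the noiseless peak
voxel value of every spot in every frame as ground truth.

Because the generator *is* the test bed, passing tests demonstrate correct
recovery of the generative model — sigmoid kinetics with Gaussian noise —
not robustness to everything real microscopy produces (focus drift,
bleaching, segmentation errors, non-Gaussian noise).

## Tracking

The tracking module is a transparent stand-in for a commercial "spots"
workflow, with every threshold config-exposed: constant-background
subtraction (clipped at zero) and 3D Gaussian smoothing; detection as
thresholded 3D local maxima (default threshold background + 5 × noise SD)
greedily pruned to a minimum separation (brighter wins; ties by voxel
order); greedy nearest-neighbour linking (default max displacement 5
voxels/frame, one missed frame tolerated); per-frame maximum fluorescence
extracted from the background-subtracted but *unsmoothed* stack, so
intensities stay on the acquisition scale. Track selection mirrors the
study's criteria: longevity (≥ 80% of the movie), a captured recruitment
event (BAX dynamic range ≥ 1.5×, the fold-change operationalization of a
qualitative criterion), spatial isolation at every frame, and an optional
user-supplied cell mask. Coordinates are 0-based (z, y, x) voxel indices;
times are frame × sampling interval.

## Statistics

- Outlier screen: single pass, |x − mean| ≥ 2 SD with population SD
  (ddof=0) computed once from the full input, per condition by default.
  The inclusive boundary and ddof=0 are chosen so that a lone extreme value
  in a tiny sample is actually removable (with sample SD and n=5 the
  largest attainable z-score is (n−1)/√n ≈ 1.79 < 2).
- Per-cell CV: 100·SD/|mean| with *sample* SD (ddof=1), per cell over its
  foci; rates untransformed, initiation on the corrected clock. Cells with
  < 2 foci are undefined and dropped. The pipeline computes CVs on the
  outlier-screened table (transform → screen → ANOVA/CV, in that order).
- ANOVA: classical one-way, on foci pooled across cells. Pooling ignores
  within-cell correlation, so its p-values are calibrated only under
  exchangeable foci — the null-calibration test draws i.i.d. foci; with a
  between-cell variance component the test is anticonservative (a
  limitation inherited from the workflow being implemented).
- "Two-tailed covariance test": not a standard named test. `compare_cv`
  provides two labelled interpretations of comparing the variability of two
  metrics — a paired two-sided Wilcoxon signed-rank test on per-cell CV
  differences (default) and a sign-flip permutation test of the mean
  difference — both exposed in config; neither claims to be the original
  test. χ² is Pearson without continuity correction. No multiple-testing
  correction is applied (raw p-values are reported).

## Pipeline, determinism, configuration

`run_pipeline` chains simulate → fit → stats, writing every intermediate
table (traces, ground truth, metrics, exclusions, CV reports) as delimited
text plus a JSON run report containing the full resolved configuration and
the counts of foci generated/fitted/excluded with reasons; re-running a
config is bit-identical. All randomness flows from one mandatory integer
seed through spawned `numpy` seed sequences (one stream per cell). YAML
configs are validated with explicit Python checks (unknown keys rejected).

## Problem sizes

The acceptance script generates ~1000 foci per release condition (the
conditions themselves are unchanged; larger n only shrinks the Monte-Carlo
error of a recovered mean) and eight seeded replicates of the 41-cell
condition for the CV statistics; the test suite uses the preset sizes
(41–56 foci to 656 foci) and 200–500 replicates for calibration checks.

## Known limitations

- Transitions faster than about one sampling interval (k ≳ 4/Δt) have
  unidentifiable steepness; such fits are excluded rather than reported.
- Per-cell CV is a non-robust statistic; a single catastrophic rate
  estimate can dominate a cell. The outlier screen is what keeps the
  population CV statistics anchored; without it they are inflated by the
  heavy tail of steepness estimates.
- Greedy nearest-neighbour linking has no motion model and will swap
  identities when spots approach within the displacement bound; the
  isolation selection criterion removes exactly those cases.
- The double-sigmoid regime (delayed recruitment of a mutant co-expressed
  with wild type) is out of scope; only single-transition fits are offered.
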