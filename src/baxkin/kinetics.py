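"""Sigmoid kinetics of BAX recruitment at mitochondrial foci.

During intrinsic apoptosis BAX translocates from the cytosol to discrete
mitochondrial foci, where its accumulation — followed by a fluorescent
fusion protein in live-cell time lapse — traces out a sigmoid in time.
This module fits the modified sigmoid

    y(x) = a / (b + exp(-k (x - x0))) + y0

to per-focus fluorescence traces and derives the kinetic metrics used for
population analysis, all in closed form:

* amplitude            A     = a / b
* maximum rate         r_max = a k / (4 b)            (slope at inflection)
* inflection time            = x0 - ln(b) / k
* initiation time            = inflection - 2 / k
* completion time            = inflection + 2 / k

Initiation is the tangent-intersection onset: the line through the
inflection point with slope r_max meets the lower plateau y = y0 at
inflection - 2/k, where the curve has risen by A / (1 + e^2) ~ 11.9% of its
amplitude ("the 12% threshold").  Completion is the symmetric upper
counterpart (the ~88% level).  Release of pro-apoptotic molecules
(cytochrome c, SMAC, AIF) is analyzed with the same machinery on decaying
traces (a < 0), anchored per focus to the BAX initiation time.

The five-parameter form is over-parameterized: (a, b, x0) enter the curve
only through a/b and x0 - ln(b)/k.  Fitting therefore fixes b = 1 — an
exact reparameterization, not an approximation — and reports b = 1.0; the
metric formulas keep the general-b closed forms so externally supplied
parameter sets are handled too.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "INITIATION_FRACTION",
    "FluorescenceTrace",
    "FitOptions",
    "SigmoidFit",
    "KineticMetrics",
    "ReleaseMetrics",
    "sigmoid",
    "sigmoid_slope",
    "normalize_trace",
    "fit_sigmoid",
    "derive_metrics",
    "derive_release",
    "fit_trace_table",
]

#: Fraction of the amplitude reached at the tangent-intersection onset,
#: 1/(1+e^2) ~ 0.1192 — the "12%" threshold.
INITIATION_FRACTION = 1.0 / (1.0 + math.e**2)


# ---------------------------------------------------------------------------
# containers


@dataclass
class FluorescenceTrace:
    """One focus/channel time series: minutes vs (relative) fluorescence."""

    time_min: np.ndarray
    intensity: np.ndarray
    cell_id: str = ""
    focus_id: str = ""
    channel: str = "bax"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_min.shape != self.intensity.shape:
            raise ValueError("time and intensity must have the same length")
        if self.time_min.ndim != 1:
            raise ValueError("trace arrays must be one-dimensional")
        if len(self.time_min) >= 2 and not np.all(np.diff(self.time_min) > 0):
            raise ValueError("time points must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_min)


@dataclass
class FitOptions:
    """Options for the nonlinear least-squares sigmoid fit.

    ``k_min``/``k_max`` bound the steepness (per minute); a fit pinned at
    either bound is reported as not converged (no resolvable transition /
    transition faster than the sampling can support).  ``flat_epsilon`` is
    the minimum intensity range below which a trace is rejected outright as
    having no transition.
    """

    k_min: float = 1e-4
    k_max: float = 1e4
    flat_epsilon: float = 1e-9
    max_nfev: int = 20000
    tol: float = 1e-14


@dataclass
class SigmoidFit:
    """Fitted parameters of the modified sigmoid, with diagnostics."""

    a: float
    b: float
    k: float
    x0: float
    y0: float
    residual_sse: float = float("nan")
    converged: bool = True
    n_points: int = 0
    direction: Literal["rising", "falling"] = "rising"
    message: str = ""

    @property
    def amplitude(self) -> float:
        return self.a / self.b

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(x, self.a, self.b, self.k, self.x0, self.y0)


@dataclass
class KineticMetrics:
    """Closed-form kinetic metrics of one fitted recruitment (or decay) curve."""

    amplitude: float
    max_rate: float
    inflection_min: float
    initiation_min: float
    completion_min: float
    initiation_corrected_min: float
    completion_corrected_min: float
    log2_rate: float
    acquisition_delay_min: float = 0.0


@dataclass
class ReleaseMetrics:
    """Release timing/rate of a pro-apoptotic molecule, anchored to BAX onset."""

    release_time_min: float
    release_time_corrected_min: float
    release_rate: float
    offset_vs_bax_min: float
    molecule: str = ""


# ---------------------------------------------------------------------------
# model


def sigmoid(x, a, b, k, x0, y0):
    """Modified sigmoid y = a/(b + exp(-k(x - x0))) + y0 (vectorized)."""
    x = np.asarray(x, dtype=float)
    return a / (b + np.exp(-k * (x - x0))) + y0


def sigmoid_slope(x, a, b, k, x0, y0):
    """Analytic derivative dy/dx of :func:`sigmoid`."""
    x = np.asarray(x, dtype=float)
    e = np.exp(-k * (x - x0))
    return a * k * e / (b + e) ** 2


def _logistic4(x, a, k, x0, y0):
    # identifiable form fitted internally (b fixed at 1); exponent clipped
    # to keep the optimizer's trial steps free of overflow
    z = np.clip(-k * (x - x0), -700.0, 700.0)
    return a / (1.0 + np.exp(z)) + y0


# ---------------------------------------------------------------------------
# operations


def normalize_trace(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Divide a trace by its first time-point's intensity.

    Every intensity becomes relative to the initial value, so the first
    normalized value is exactly 1.  A nonpositive first value signals bad
    background subtraction and is an error naming the focus.
    """
    first = trace.intensity[0]
    if not first > 0:
        raise ValueError(
            f"cannot normalize trace (cell={trace.cell_id!r}, focus={trace.focus_id!r}, "
            f"channel={trace.channel!r}): first intensity {first!r} is not positive "
            "(check background subtraction)"
        )
    return replace(trace, intensity=trace.intensity / first)


def fit_sigmoid(
    trace: FluorescenceTrace,
    direction: Literal["rising", "falling"] = "rising",
    options: FitOptions | None = None,
) -> SigmoidFit:
    """Least-squares fit of the modified sigmoid to one trace.

    ``direction="falling"`` fits the same model with a < 0 (decay as a
    mirrored sigmoid).  The fit is deterministic given data + options.  A
    trace with no transition (range below ``flat_epsilon``), a failed
    optimization, or a steepness pinned at its bounds is returned with
    ``converged=False`` and a reason in ``message``; such foci are excluded
    downstream and counted in the run report.
    """
    opts = options or FitOptions()
    t = trace.time_min
    y = trace.intensity
    n = len(t)
    if n < 5:
        raise ValueError(f"need at least 5 points to fit, got {n}")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time points must be strictly increasing")
    if direction not in ("rising", "falling"):
        raise ValueError(f"unknown direction {direction!r}")

    yrange = float(np.max(y) - np.min(y))
    failed = SigmoidFit(
        a=float("nan"), b=1.0, k=float("nan"), x0=float("nan"), y0=float("nan"),
        residual_sse=float("nan"), converged=False, n_points=n, direction=direction,
    )
    if yrange < opts.flat_epsilon:
        return replace(failed, message="no transition")

    # initialization: plateau from the quiet end, steepness from the largest
    # smoothed finite-difference slope (k = 4 * slope_max / amplitude at
    # b = 1).  Noisy traces can trap a single start in a local minimum (a
    # noise step mistaken for the transition), so a small set of
    # deterministic candidate starts is tried and the lowest SSE kept.
    if n >= 7:
        kernel = np.ones(5) / 5.0
        y_smooth = np.convolve(y, kernel, mode="same")
        y_smooth[:2], y_smooth[-2:] = y[:2], y[-2:]
    else:
        y_smooth = y
    grad = np.gradient(y_smooth, t)
    sign = 1.0 if direction == "rising" else -1.0
    i_steep = int(np.argmax(sign * grad))
    a0 = sign * yrange
    y00 = float(np.min(y_smooth)) if direction == "rising" else float(np.max(y_smooth))
    slope0 = abs(float(grad[i_steep])) or yrange / (t[-1] - t[0])
    k0 = float(np.clip(4.0 * slope0 / yrange, opts.k_min * 1.01, opts.k_max * 0.99))
    x00 = float(t[i_steep])
    # mid-range crossing of the smoothed trace as an alternative center
    mid = (np.min(y_smooth) + np.max(y_smooth)) / 2.0
    crossings = np.nonzero(np.diff(np.signbit(sign * (y_smooth - mid))))[0]
    x0_cross = float(t[crossings[0]]) if len(crossings) else float(np.median(t))

    span = float(t[-1] - t[0])
    if direction == "rising":
        lower = [0.0, opts.k_min, t[0] - span, -np.inf]
        upper = [np.inf, opts.k_max, t[-1] + span, np.inf]
    else:
        lower = [-np.inf, opts.k_min, t[0] - span, -np.inf]
        upper = [0.0, opts.k_max, t[-1] + span, np.inf]

    def clip_k(k):
        return float(np.clip(k, opts.k_min * 1.01, opts.k_max * 0.99))

    starts = [
        [a0, k0, x00, y00],
        [a0, clip_k(k0 / 4.0), x0_cross, y00],
        [a0, clip_k(4.0 / span), x0_cross, y00],
    ]
    best = None
    errors: list[str] = []
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _logistic4, t, y, p0=p0, bounds=(lower, upper), method="trf",
                    xtol=opts.tol, ftol=opts.tol, gtol=opts.tol,
                    max_nfev=opts.max_nfev,
                )
        except (RuntimeError, ValueError) as exc:
            errors.append(str(exc))
            continue
        sse = float(np.sum((_logistic4(t, *popt) - y) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return replace(failed, message=f"optimizer failure: {errors[-1]}")
    popt, sse = best
    a, k, x0, y0 = (float(v) for v in popt)
    fit = SigmoidFit(
        a=a, b=1.0, k=k, x0=x0, y0=y0, residual_sse=sse, converged=True,
        n_points=n, direction=direction,
    )
    if k <= opts.k_min * (1 + 1e-6):
        return replace(fit, converged=False, message="no transition (k at lower bound)")
    if k >= opts.k_max * (1 - 1e-6):
        return replace(fit, converged=False,
                       message="transition faster than sampling (k at upper bound)")
    if abs(a) < 0.5 * yrange:
        # a transition much smaller than the trace's excursion means the fit
        # latched onto a noise step, not the recruitment/release event
        return replace(fit, converged=False,
                       message="amplitude inconsistent with trace range")
    return fit


def derive_metrics(fit: SigmoidFit, acquisition_delay_min: float = 0.0) -> KineticMetrics:
    """Closed-form kinetic metrics from a converged sigmoid fit.

    Corrected times add the treatment-to-acquisition delay, putting all time
    metrics on the clock of the apoptotic stimulus.  The sigmoid evaluated at
    initiation sits exactly amplitude/(1+e^2) above the lower plateau.
    """
    if not fit.converged:
        raise ValueError(f"metrics undefined for a failed fit ({fit.message})")
    if not fit.k > 0:
        raise ValueError(f"metrics undefined for k = {fit.k} (need k > 0)")
    if not fit.b > 0:
        raise ValueError(f"metrics undefined for b = {fit.b} (need b > 0)")
    amplitude = fit.a / fit.b
    max_rate = fit.a * fit.k / (4.0 * fit.b)
    inflection = fit.x0 - math.log(fit.b) / fit.k
    initiation = inflection - 2.0 / fit.k
    completion = inflection + 2.0 / fit.k
    log2_rate = math.log2(max_rate) if max_rate > 0 else float("nan")
    return KineticMetrics(
        amplitude=amplitude,
        max_rate=max_rate,
        inflection_min=inflection,
        initiation_min=initiation,
        completion_min=completion,
        initiation_corrected_min=initiation + acquisition_delay_min,
        completion_corrected_min=completion + acquisition_delay_min,
        log2_rate=log2_rate,
        acquisition_delay_min=acquisition_delay_min,
    )


def derive_release(
    fit_decay: SigmoidFit,
    bax_metrics: KineticMetrics,
    molecule: str = "",
) -> ReleaseMetrics:
    """Release timing/rate of a decay fit, anchored to the paired BAX onset.

    The release time is the tangent-intersection rule applied to the decay
    curve's departure from its initial plateau (same closed form,
    inflection - 2/k); the release rate is the maximum decay slope
    a k / (4 b) < 0.  The offset is release time minus BAX initiation, both
    on the uncorrected (acquisition) clock — the offset is delay-invariant.
    """
    if not fit_decay.converged:
        raise ValueError(f"release undefined for a failed fit ({fit_decay.message})")
    if fit_decay.amplitude >= 0:
        raise ValueError(
            "direction mismatch: decay fit has nonnegative amplitude "
            f"({fit_decay.amplitude})"
        )
    m = derive_metrics(fit_decay, bax_metrics.acquisition_delay_min)
    return ReleaseMetrics(
        release_time_min=m.initiation_min,
        release_time_corrected_min=m.initiation_corrected_min,
        release_rate=m.max_rate,
        offset_vs_bax_min=m.initiation_min - bax_metrics.initiation_min,
        molecule=molecule,
    )


# ---------------------------------------------------------------------------
# table-level driver


def iter_traces(table: pd.DataFrame) -> Iterable[FluorescenceTrace]:
    """Yield :class:`FluorescenceTrace` objects from a long-format table.

    Expected columns: cell_id, focus_id, time_min, channel, intensity.
    """
    for (cell, focus, channel), grp in table.groupby(
        ["cell_id", "focus_id", "channel"], sort=True
    ):
        grp = grp.sort_values("time_min")
        yield FluorescenceTrace(
            time_min=grp["time_min"].to_numpy(),
            intensity=grp["intensity"].to_numpy(),
            cell_id=str(cell),
            focus_id=str(focus),
            channel=str(channel),
        )


def fit_trace_table(
    traces: pd.DataFrame,
    bax_channel: str = "bax",
    release_channel: str | None = None,
    acquisition_delay_min: float = 0.0,
    options: FitOptions | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every focus in a long-format trace table; return (metrics, exclusions).

    BAX traces are normalized to their first value before fitting (kinetic
    rates are therefore in normalized RFU/min); release traces are fitted on
    the acquisition intensity scale, falling direction, and anchored to the
    focus's BAX initiation.  Foci whose BAX fit fails are excluded with a
    reason; a focus with a failed release fit keeps its BAX metrics but has
    empty release columns.

    A fitted event whose initiation-to-completion interval is not contained
    in the acquisition window is excluded ("event not encompassed") — the
    trace-level analogue of the track-selection criterion that the track
    must encompass the recruitment event; a transition truncated by the
    movie boundary has no identifiable kinetics.
    """
    required = {"cell_id", "focus_id", "time_min", "channel", "intensity"}
    missing = required - set(traces.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")

    by_focus: dict[tuple[str, str], dict[str, FluorescenceTrace]] = {}
    for tr in iter_traces(traces):
        by_focus.setdefault((tr.cell_id, tr.focus_id), {})[tr.channel] = tr

    rows: list[dict] = []
    excluded: list[dict] = []
    for (cell, focus), chans in sorted(by_focus.items()):
        if bax_channel not in chans:
            excluded.append({"cell_id": cell, "focus_id": focus,
                             "stage": "fit", "reason": "missing BAX channel"})
            continue
        try:
            bax = normalize_trace(chans[bax_channel])
        except ValueError as exc:
            excluded.append({"cell_id": cell, "focus_id": focus,
                             "stage": "normalize", "reason": str(exc)})
            continue
        fit = fit_sigmoid(bax, "rising", options)
        if not fit.converged:
            excluded.append({"cell_id": cell, "focus_id": focus,
                             "stage": "fit", "reason": fit.message})
            continue
        m = derive_metrics(fit, acquisition_delay_min)
        t0, t1 = bax.time_min[0], bax.time_min[-1]
        if m.initiation_min < t0 or m.completion_min > t1:
            excluded.append({"cell_id": cell, "focus_id": focus, "stage": "fit",
                             "reason": "recruitment event not encompassed"})
            continue
        row = {
            "cell_id": cell, "focus_id": focus, "channel": bax_channel,
            "a": fit.a, "b": fit.b, "k": fit.k, "x0": fit.x0, "y0": fit.y0,
            "sse": fit.residual_sse, "converged": fit.converged,
            "amplitude": m.amplitude, "max_rate": m.max_rate,
            "log2_rate": m.log2_rate,
            "initiation_min": m.initiation_min,
            "initiation_corrected_min": m.initiation_corrected_min,
            "completion_min": m.completion_min,
            "completion_corrected_min": m.completion_corrected_min,
            "inflection_min": m.inflection_min,
        }
        rel_name = release_channel
        if rel_name is None:
            others = [c for c in chans if c != bax_channel]
            rel_name = others[0] if others else None
        if rel_name is not None and rel_name in chans:
            rel_trace = chans[rel_name]
            dfit = fit_sigmoid(rel_trace, "falling", options)
            if dfit.converged:
                dm = derive_metrics(dfit, acquisition_delay_min)
                if (dm.initiation_min < rel_trace.time_min[0]
                        or dm.completion_min > rel_trace.time_min[-1]):
                    excluded.append({
                        "cell_id": cell, "focus_id": focus, "stage": "release-fit",
                        "reason": "release event not encompassed",
                    })
                    dfit = None
            if dfit is not None and dfit.converged:
                rel = derive_release(dfit, m, molecule=rel_name)
                row.update({
                    "release_molecule": rel.molecule,
                    "release_time_min": rel.release_time_min,
                    "release_time_corrected_min": rel.release_time_corrected_min,
                    "release_rate": rel.release_rate,
                    "offset_vs_bax_min": rel.offset_vs_bax_min,
                })
            elif dfit is not None:
                excluded.append({"cell_id": cell, "focus_id": focus,
                                 "stage": "release-fit", "reason": dfit.message})
        rows.append(row)

    metrics = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excluded, columns=["cell_id", "focus_id", "stage", "reason"])
    return metrics, exclusions
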