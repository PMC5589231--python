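"""Sigmoid model, fitting and closed-form kinetic metrics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from baxkin import kinetics, synthetic
from baxkin.kinetics import (
    INITIATION_FRACTION,
    FluorescenceTrace,
    SigmoidFit,
    derive_metrics,
    derive_release,
    fit_sigmoid,
    normalize_trace,
    sigmoid,
    sigmoid_slope,
)

params_strategy = st.tuples(
    st.floats(0.2, 5.0),      # a
    st.floats(0.2, 5.0),      # b
    st.floats(0.05, 3.0),     # k
    st.floats(-50.0, 400.0),  # x0
    st.floats(-2.0, 5.0),     # y0
)


def _fit_roundtrip(seed):
    rng = np.random.default_rng(seed)
    from conftest import random_sigmoid_cell

    params = random_sigmoid_cell(rng)
    traces, truth = synthetic.simulate_cell(params, seed=seed)
    trace = next(kinetics.iter_traces(traces))
    fit = fit_sigmoid(trace)
    return fit, derive_metrics(fit), truth.iloc[0]


# ---------------------------------------------------------------------------
# model identities


@given(params_strategy)
def test_b_is_a_reparameterization(p):
    """General-b parameters map exactly onto the b=1 form used for fitting."""
    a, b, k, x0, y0 = p
    x = np.linspace(x0 - 30, x0 + 30, 101)
    equivalent = sigmoid(x, a / b, 1.0, k, x0 - math.log(b) / k, y0)
    np.testing.assert_allclose(sigmoid(x, *p), equivalent, rtol=1e-12)


@given(params_strategy)
def test_initiation_sits_at_the_12_percent_level(p):
    """The tangent-rule onset is exactly amplitude/(1+e^2) above baseline."""
    fit = SigmoidFit(*p)
    m = derive_metrics(fit)
    rise = float(sigmoid(m.initiation_min, *p)) - fit.y0
    assert abs(rise - m.amplitude * INITIATION_FRACTION) <= 1e-9 * abs(m.amplitude)
    fall = float(sigmoid(m.completion_min, *p)) - fit.y0
    assert abs(fall - m.amplitude * (1 - INITIATION_FRACTION)) <= 1e-9 * abs(m.amplitude)


@given(params_strategy)
def test_max_rate_matches_grid_derivative_oracle(p):
    """Closed-form a*k/(4b) equals a fine-grid maximum of the derivative."""
    a, b, k, x0, y0 = p
    m = derive_metrics(SigmoidFit(*p))
    x = np.linspace(m.inflection_min - 10 / k, m.inflection_min + 10 / k, 10_000)
    grid_max = float(np.max(sigmoid_slope(x, *p)))
    assert abs(grid_max - m.max_rate) <= 1e-6 * m.max_rate
    assert abs(x[np.argmax(sigmoid_slope(x, *p))] - m.inflection_min) <= 3 * (x[1] - x[0])


@given(params_strategy)
def test_initiation_matches_tangent_line_oracle(p):
    """Geometric construction: the max-slope tangent hits y=y0 at the closed form."""
    m = derive_metrics(SigmoidFit(*p))
    y_inflection = float(sigmoid(m.inflection_min, *p))
    # line through (inflection, y_inflection) with slope max_rate, solved for y = y0
    x_intersect = m.inflection_min - (y_inflection - p[4]) / m.max_rate
    assert abs(x_intersect - m.initiation_min) <= 1e-9
    assert m.initiation_min < m.inflection_min < m.completion_min


def test_metrics_hand_example():
    """a=b=k=1, x0=y0=0: inflection 0, initiation -2, completion 2, rate 1/4."""
    m = derive_metrics(SigmoidFit(a=1.0, b=1.0, k=1.0, x0=0.0, y0=0.0))
    assert m.inflection_min == pytest.approx(0.0, abs=1e-12)
    assert m.initiation_min == pytest.approx(-2.0, abs=1e-12)
    assert m.completion_min == pytest.approx(2.0, abs=1e-12)
    assert m.max_rate == pytest.approx(0.25, abs=1e-12)
    assert m.amplitude == pytest.approx(1.0, abs=1e-12)


def test_acquisition_delay_is_added():
    m = derive_metrics(SigmoidFit(a=1.0, b=1.0, k=0.5, x0=324.0, y0=0.0),
                       acquisition_delay_min=95.0)
    assert m.initiation_min == pytest.approx(320.0)
    assert m.initiation_corrected_min == pytest.approx(415.0)


def test_metrics_reject_bad_fits():
    with pytest.raises(ValueError, match="k"):
        derive_metrics(SigmoidFit(a=1.0, b=1.0, k=-0.5, x0=0.0, y0=0.0))
    failed = SigmoidFit(a=1.0, b=1.0, k=1.0, x0=0.0, y0=0.0,
                        converged=False, message="no transition")
    with pytest.raises(ValueError, match="no transition"):
        derive_metrics(failed)


# ---------------------------------------------------------------------------
# normalization


def test_normalize_examples():
    tr = FluorescenceTrace([0.0, 1.0, 2.0], [10.0, 20.0, 40.0])
    np.testing.assert_allclose(normalize_trace(tr).intensity, [1.0, 2.0, 4.0])
    const = FluorescenceTrace([0.0, 1.0, 2.0], [7.0, 7.0, 7.0])
    np.testing.assert_allclose(normalize_trace(const).intensity, [1.0, 1.0, 1.0])


def test_normalize_rejects_nonpositive_first_value():
    tr = FluorescenceTrace([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], focus_id="focus007")
    with pytest.raises(ValueError, match="focus007"):
        normalize_trace(tr)


def test_normalized_plateau_is_one_plus_amplitude_over_baseline():
    """Baseline beta and plateau beta+A normalize to 1 and 1 + A/beta."""
    beta, amp = 2.0, 3.0
    params = synthetic.CellSimParams(
        n_foci=1, onset_mean_min=40.0, onset_within_cell_sd_min=0.0,
        rate_log2_mean=-1.0, rate_log2_sd=0.0, amplitude_mean=amp,
        amplitude_sd=0.0, baseline=beta, noise_sd=0.0, duration_min=150.0,
    )
    traces, _ = synthetic.simulate_cell(params, seed=0)
    tr = normalize_trace(next(kinetics.iter_traces(traces)))
    assert tr.intensity[0] == 1.0
    assert tr.intensity[-1] == pytest.approx(1 + amp / beta, rel=1e-3)


# ---------------------------------------------------------------------------
# fitting


@pytest.mark.parametrize("seed", range(8))
def test_noiseless_round_trip_recovers_generative_parameters(seed):
    """fit(simulate) with zero noise recovers every parameter to <= 1e-6."""
    fit, m, truth = _fit_roundtrip(seed)
    assert fit.converged and fit.b == 1.0
    assert abs(m.amplitude - truth.amplitude) <= 1e-6 * truth.amplitude
    assert abs(fit.k - truth.k) <= 1e-6 * truth.k
    assert abs(m.max_rate - truth.rate) <= 1e-6 * truth.rate
    assert abs(m.initiation_min - truth.onset_min) <= 1e-6 * abs(truth.onset_min)
    assert abs(fit.y0 - truth.baseline) <= 1e-6 * truth.baseline


def test_time_shift_equivariance():
    """Shifting the time axis by +delta shifts x0 by +delta, nothing else."""
    params = synthetic.CellSimParams(
        n_foci=1, onset_mean_min=30.0, onset_within_cell_sd_min=0.0,
        rate_log2_sd=0.0, amplitude_sd=0.0, noise_sd=0.02,
    )
    traces, _ = synthetic.simulate_cell(params, seed=4)
    tr = next(kinetics.iter_traces(traces))
    fit = fit_sigmoid(tr)
    delta = 37.5
    shifted = FluorescenceTrace(tr.time_min + delta, tr.intensity)
    fit2 = fit_sigmoid(shifted)
    assert fit2.x0 - fit.x0 == pytest.approx(delta, abs=1e-6)
    for attr in ("a", "k", "y0"):
        assert getattr(fit2, attr) == pytest.approx(getattr(fit, attr), abs=1e-8)


def test_intensity_scaling_of_metrics():
    """Uniform intensity rescaling scales amplitude/rate, shifts log2, keeps times."""
    traces, _ = synthetic.simulate_cell(
        synthetic.CellSimParams(n_foci=1, onset_within_cell_sd_min=0.0,
                                rate_log2_sd=0.0, amplitude_sd=0.0, noise_sd=0.0),
        seed=2,
    )
    tr = next(kinetics.iter_traces(traces))
    scale = 3.5
    m1 = derive_metrics(fit_sigmoid(tr))
    m2 = derive_metrics(fit_sigmoid(FluorescenceTrace(tr.time_min, tr.intensity * scale)))
    assert m2.initiation_min == pytest.approx(m1.initiation_min, abs=1e-6)
    assert m2.completion_min == pytest.approx(m1.completion_min, abs=1e-6)
    assert m2.amplitude == pytest.approx(scale * m1.amplitude, rel=1e-8)
    assert m2.max_rate == pytest.approx(scale * m1.max_rate, rel=1e-8)
    assert m2.log2_rate - m1.log2_rate == pytest.approx(math.log2(scale), abs=1e-8)


def test_noisy_max_rate_recovery_calibration():
    """5% noise, 60 points: max rate within 10% of truth in >= 90% of 200 fits."""
    hits = 0
    for i in range(200):
        params = synthetic.CellSimParams(
            n_foci=1, onset_mean_min=15.0, onset_within_cell_sd_min=0.0,
            rate_log2_mean=-3.0, rate_log2_sd=0.0,
            amplitude_mean=2.0, amplitude_sd=0.0, noise_sd=0.1, duration_min=59.0,
        )
        traces, truth = synthetic.simulate_cell(params, seed=1000 + i)
        m = derive_metrics(fit_sigmoid(next(kinetics.iter_traces(traces))))
        hits += abs(m.max_rate - truth.rate[0]) / truth.rate[0] <= 0.10
    assert hits / 200 >= 0.90


def test_flat_trace_is_rejected_as_no_transition():
    tr = FluorescenceTrace(np.arange(10.0), np.full(10, 2.0))
    fit = fit_sigmoid(tr)
    assert not fit.converged and "no transition" in fit.message


def test_too_few_points_raise():
    with pytest.raises(ValueError, match="5 points"):
        fit_sigmoid(FluorescenceTrace(np.arange(4.0), np.arange(4.0)))


# ---------------------------------------------------------------------------
# release / decay analysis


def test_mirrored_sigmoid_release_rate_hand_example():
    """a=-1, b=1, k=1, y0=1: maximum decay slope is -0.25 RFU/min."""
    bax = derive_metrics(SigmoidFit(a=1.0, b=1.0, k=1.0, x0=0.0, y0=0.0))
    decay = SigmoidFit(a=-1.0, b=1.0, k=1.0, x0=0.0, y0=1.0, direction="falling")
    rel = derive_release(decay, bax)
    assert rel.release_rate == pytest.approx(-0.25, abs=1e-12)
    # departure from the upper plateau follows the same tangent rule
    assert rel.release_time_min == pytest.approx(-2.0, abs=1e-12)


def test_release_direction_mismatch_is_an_error():
    bax = derive_metrics(SigmoidFit(a=1.0, b=1.0, k=1.0, x0=0.0, y0=0.0))
    rising = SigmoidFit(a=1.0, b=1.0, k=1.0, x0=0.0, y0=0.0)
    with pytest.raises(ValueError, match="direction mismatch"):
        derive_release(rising, bax)


def test_release_offset_noiseless_round_trip():
    """Noiseless paired traces: offset recovered to machine-level accuracy."""
    cell = synthetic.CellSimParams(
        n_foci=3, onset_mean_min=40.0, onset_within_cell_sd_min=1.0,
        rate_log2_sd=0.2, noise_sd=0.0, duration_min=150.0,
    )
    release = synthetic.ReleaseSimParams(
        molecule_label="cytc", offset_mean_min=-2.5, offset_sd_min=0.0,
        release_rate_mean=-0.78, release_rate_sd=0.1, start_level=7.5,
        noise_sd=0.0,
    )
    traces, truth = synthetic.simulate_cell(cell, release, seed=6)
    metrics, excl = kinetics.fit_trace_table(traces, release_channel="cytc")
    assert len(excl) == 0
    merged = metrics.merge(truth, on=["cell_id", "focus_id"])
    np.testing.assert_allclose(
        merged["offset_vs_bax_min"], merged["release_offset_min"], atol=1e-6
    )
    np.testing.assert_allclose(
        merged["release_rate_x"], merged["release_rate_y"], rtol=1e-6
    )


def test_slow_decay_recovers_positive_offset():
    """An AIF-like slow decay generated after BAX onset yields a positive offset."""
    cell = synthetic.CellSimParams(
        n_foci=2, onset_mean_min=30.0, onset_within_cell_sd_min=0.5,
        noise_sd=0.0, duration_min=180.0,
    )
    release = synthetic.ReleaseSimParams(
        molecule_label="aif", offset_mean_min=10.3, offset_sd_min=0.0,
        release_rate_mean=-0.08, release_rate_sd=0.0, start_level=1.0,
        release_fraction=0.5, noise_sd=0.0,
    )
    traces, _ = synthetic.simulate_cell(cell, release, seed=8)
    metrics, _ = kinetics.fit_trace_table(traces, release_channel="aif")
    offsets = metrics["offset_vs_bax_min"].dropna()
    assert len(offsets) == 2
    assert np.all(offsets > 0)
    np.testing.assert_allclose(offsets, 10.3, atol=1e-4)
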