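import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    """Fitting near-degenerate traces emits benign runtime warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def random_sigmoid_cell(rng, noise_sd=0.0, n_foci=1, release=None):
    """A random, well-posed single-cell simulation for round-trip checks."""
    from baxkin import synthetic

    return synthetic.CellSimParams(
        n_foci=n_foci,
        onset_mean_min=float(rng.uniform(15.0, 60.0)),
        onset_within_cell_sd_min=0.0 if n_foci == 1 else 2.0,
        rate_log2_mean=float(rng.uniform(-3.5, -1.0)),
        rate_log2_sd=0.0,
        amplitude_mean=float(rng.uniform(1.0, 3.0)),
        amplitude_sd=0.0,
        baseline=float(rng.uniform(0.5, 2.0)),
        noise_sd=noise_sd,
        duration_min=150.0,
    )
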