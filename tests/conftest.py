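import numpy as np
import pytest

from kayakpace import Event, published_params
from kayakpace.synthetic import simulate_score_sequences


@pytest.fixture(scope="session")
def womens_params_nocov():
    """Published women's four-state model, intercepts only, SD 0.2."""
    return published_params(Event.W_K1_500, sigma=0.2, include_covariates=False)


@pytest.fixture(scope="session")
def score_dataset_100x30(womens_params_nocov):
    """100 athletes x 30 races simulated from the published women's model."""
    sequences, paths = simulate_score_sequences(
        womens_params_nocov, n_athletes=100, races_per_athlete=30, seed=11
    )
    return sequences, paths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
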