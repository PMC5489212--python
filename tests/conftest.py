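import numpy as np
import pytest
from scipy.signal import lfilter

import rsdenoise as rd


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def ar1_noise(rng, n, nvox, gamma, sd=1.0):
    """AR(1) series with marginal SD ``sd`` (stationary start)."""
    innov = sd * np.sqrt(1.0 - gamma**2) * rng.standard_normal((n, nvox))
    return lfilter([1.0], [1.0, -gamma], innov, axis=0)


@pytest.fixture
def small_design(rng):
    """One nuisance column + quadratic detrending on 160 points at TR=2 s."""
    n = 160
    x = rng.standard_normal(n)
    reg = rd.Regressor("x1", x - x.mean(), dt=2.0)
    det = rd.legendre_detrend(n, 2, dt=2.0)
    return rd.assemble_design([reg], det)


@pytest.fixture(scope="session")
def lagged_dataset():
    """Synthetic BOLD dataset with a +6 s lagged CO2-like regressor injected."""
    tr, n = 2.0, 160
    trace = rd.synth_physio(n * tr, 0.2, "rest", rng_seed=5)
    truth = rd.SyntheticDatasetTruth(
        regressors=[rd.Regressor("petco2_raw", trace, 0.2)],
        lags_s=[6.0], weight_mean=1.0, weight_scale=0.3, seed=2)
    image, info = rd.synth_bold_dataset((8, 8, 8), n, tr, truth)
    return image, info, trace
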