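import math

import numpy as np
import pytest

from lookelsewhere.noise import make_psd, simulate_stationary_gaussian


@pytest.fixture(scope="session")
def white_psd():
    """Unit-variance white PSD for a 30-min cadence."""
    return make_psd("white", np.linspace(1e-5, 24.0, 200), sigma=1.0, cadence=1 / 48)


@pytest.fixture(scope="session")
def short_white_series(white_psd):
    """A 50-day, 30-min-cadence white Gaussian series (seed 11)."""
    return simulate_stationary_gaussian(white_psd, 2400, 1 / 48, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
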