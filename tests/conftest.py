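import numpy as np
import pytest

from wormdmd.connectome import conductance_matrices
from wormdmd.dynamics import ModelParams, find_fixed_point
from wormdmd.synthetic import surrogate_connectome

# the six reference decay timescales (s) used as the multi-exponential
# generator set throughout the suite: well-separated, spanning ~3 decades
SIX_TAUS = (0.00052, 0.00151, 0.00455, 0.00872, 0.02681, 0.09094)


@pytest.fixture(scope="session")
def small_net():
    """A 20-neuron surrogate with conductances, calibrated params, fixed point."""
    c = surrogate_connectome(n=20, n_syn=80, n_gap=16, n_bclass=6, seed=42)
    cond = conductance_matrices(c, 100.0)
    params = ModelParams().with_thresholds(cond)
    fp = find_fixed_point(cond, params)
    return c, cond, params, fp


@pytest.fixture(scope="session")
def medium_net():
    """A 50-neuron surrogate used for rewiring and ensemble statistics."""
    return surrogate_connectome(n=50, n_syn=400, n_gap=60, n_bclass=10, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
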