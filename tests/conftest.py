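import numpy as np
import pytest

from mitomotor.behavior import MixtureParams, simulate_from_params


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def true_params():
    return MixtureParams(omega=0.7, mu=np.log(20.0), sigma=0.4)


@pytest.fixture
def simulated_latencies(rng, true_params):
    return simulate_from_params(true_params, 300, rng)
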