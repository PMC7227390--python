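import numpy as np
import pytest

from hhetd import SynapseParams, hh_default, rtm_default, table1_config, simulate


@pytest.fixture(scope="session")
def hh():
    return hh_default()


@pytest.fixture(scope="session")
def rtm():
    return rtm_default()


@pytest.fixture(scope="session")
def syn():
    return SynapseParams()


@pytest.fixture(scope="session")
def small_result():
    """A short driven 20-neuron run reused by several structural tests."""
    cfg = table1_config(n=20, n_exc=16, n_inh=4, T=300.0, dt=0.02,
                        method="aetd2", seed=11, record_every=50)
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
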