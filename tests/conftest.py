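import numpy as np
import pytest

from shifted_stdp import (
    InputEnsembleConfig,
    NeuronParams,
    PairSTDPParams,
    SynapseParams,
)


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def synapses():
    return SynapseParams()


@pytest.fixture(scope="session")
def stdp_default():
    return PairSTDPParams()


@pytest.fixture(scope="session")
def small_synapses():
    """A 20-synapse ensemble for fast closed-loop tests."""
    return SynapseParams(n_excitatory=20, n_inhibitory=5)


@pytest.fixture(scope="session")
def small_ensemble():
    return InputEnsembleConfig(n_excitatory=20, n_inhibitory=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
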