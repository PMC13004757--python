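import numpy as np
import pytest

from mmnsim.core import NeuronParams, NetworkSpec, PopulationSpec


@pytest.fixture(scope="session")
def default_neuron() -> NeuronParams:
    return NeuronParams()


@pytest.fixture()
def single_neuron_spec(default_neuron) -> NetworkSpec:
    return NetworkSpec([PopulationSpec("A", 1, neuron=default_neuron)])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
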