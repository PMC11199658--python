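import numpy as np
import pytest

from spikedream import NeuronParams


@pytest.fixture
def small_params() -> NeuronParams:
    """A 10-neuron module with the published time constants."""
    return NeuronParams(n=10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
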