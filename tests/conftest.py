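import numpy as np
import pytest

from chipdpcr import ClassificationBands, NoiseParams, RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def bands():
    return ClassificationBands()


@pytest.fixture
def noise_off():
    return NoiseParams.off()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
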