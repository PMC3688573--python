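import numpy as np
import pytest

from habitat_split import ModelParams


@pytest.fixture
def defaults() -> ModelParams:
    """Package default parameter set (closed edge, unit rates)."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130620)
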