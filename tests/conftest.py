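import numpy as np
import pytest

from thetaflicker.model_core import STPParams
from thetaflicker.simulator import ModelConfig


@pytest.fixture(scope="session")
def stp_default() -> STPParams:
    """Published plasticity parameters (U=0.25, tau_r=0.6 s, tau_f=1.9 s)."""
    return STPParams()


@pytest.fixture(scope="session")
def scaled_model() -> ModelConfig:
    """Published model regime scaled to a 20x20 grid per map."""
    return ModelConfig(n_per_map=400)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
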