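import numpy as np
import pytest

from fraccable.solver import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20151202)


@pytest.fixture
def small_cfg():
    """A cheap fibre configuration for solver-level unit tests."""
    return ModelConfig(N=100, dt=0.02, t_final=60.0, stim_start=5.0,
                       record=(0.25, 0.5, 0.75))
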