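import numpy as np
import pytest

from ring_atg import initialize_melt
from ring_atg.params import SimParams


@pytest.fixture(scope="session")
def small_melt():
    """Small equilibrated passive melt reused across simulator tests."""
    params = SimParams(M=2, N=32, seed=7)
    frame, topo = initialize_melt(params, ramp_steps=2000, burnin_steps=5000)
    return params, frame, topo


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
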