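import numpy as np
import pytest

from multiregion.simulate import SimConfig, simulate_case


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_case():
    """A small perfect-calling case: 50/20/30 trunk/branch/private."""
    cfg = SimConfig(
        n_trunk=50, n_branch=20, n_private=30, n_microsat=0,
        dropout=0.0, seq_error=0.0, seed=11,
    )
    return simulate_case(cfg)


@pytest.fixture(scope="session")
def dropout_case():
    """Same architecture with 20% per-region caller dropout."""
    cfg = SimConfig(
        n_trunk=200, n_branch=80, n_private=120, n_microsat=0,
        dropout=0.2, seq_error=0.0, seed=13,
    )
    return simulate_case(cfg)
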