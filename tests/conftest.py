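import numpy as np
import pytest

from cnscreen.simulate import EffectPriors, SimConfig, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A 200-gene screen with 10 planted facilitators and 10 brakes."""
    cfg = SimConfig(
        n_genes=200, n_nt=100, seed=7,
        effects=EffectPriors(n_facilitators=10, n_brakes=10),
    )
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def null_screen():
    """A 300-gene screen with no planted effects."""
    cfg = SimConfig(n_genes=300, n_nt=150, seed=13)
    return simulate_screen(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
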