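import numpy as np
import pytest

from ringslit import RunConfig, init_melt, run_kmc


@pytest.fixture(scope="session")
def small_melt():
    """A tiny bulk melt, lightly equilibrated; shared read-only."""
    state = init_melt(RunConfig(N=40, M=6, seed=3, crossing_rate=1e-2))
    run_kmc(state, 2_000_000, rng=11)
    return state


@pytest.fixture(scope="session")
def entangled_melt():
    """A bulk melt driven to a topologically nontrivial state."""
    state = init_melt(RunConfig(N=80, M=12, seed=1, crossing_rate=1e-2))
    run_kmc(state, 40_000_000, rng=7)
    return state


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
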