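import numpy as np
import pytest

from sirs1d import SIRSParams, LatticeState


@pytest.fixture
def fig_params():
    """The small worked-example ring: 11 sites, k=1, certain infection."""
    return SIRSParams(N=11, lam=1.0, k=1, tau_I=2, tau_R=3, max_steps=100, seed=0)


@pytest.fixture
def default_params():
    """Study defaults: k=3, tau_I=7, tau_R=9."""
    return SIRSParams(N=200, lam=0.1, max_steps=500, seed=1)


def random_state(params: SIRSParams, rng: np.random.Generator) -> LatticeState:
    """A random configuration satisfying all lattice invariants."""
    comp = rng.integers(0, 3, params.N).astype(np.int8)
    clock = np.zeros(params.N, dtype=np.int32)
    infected = comp == 1
    refractory = comp == 2
    clock[infected] = rng.integers(0, params.tau_I, int(infected.sum()))
    clock[refractory] = rng.integers(0, params.tau_R, int(refractory.sum()))
    return LatticeState(comp, clock, 0)
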