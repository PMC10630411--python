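import numpy as np
import pytest

import silkcg as s
from silkcg.forcefield import Evaluator


@pytest.fixture(scope="session")
def masp1_seq():
    return s.masp1_sequence()

@pytest.fixture(scope="session")
def short_seq():
    # first 10 residues of the construct: enough for every bonded term kind
    return s.masp1_sequence()[:10]


@pytest.fixture(scope="session")
def masp1_ff(masp1_seq):
    return s.default_forcefield(masp1_seq)


@pytest.fixture(scope="session")
def short_ff(short_seq):
    return s.default_forcefield(short_seq)


@pytest.fixture(scope="session")
def bundle16(masp1_ff):
    topo, state = s.make_test_assembly("bundle16", ff=masp1_ff)
    return topo, state


@pytest.fixture(scope="session")
def bundle16_minimized(bundle16, masp1_ff):
    topo, state = bundle16
    mn, report = s.minimize(state, topo, masp1_ff, force_tol=0.5, max_iter=600)
    assert np.isfinite(report.energy_final)
    return topo, mn


def random_chain_system(seq, ff, seed, jitter=0.3):
    """Perturbed extended chain: safe geometry for gradient checks."""
    topo = s.build_chain(seq)
    state = s.chain_state(topo)
    rng = np.random.default_rng(seed)
    state.positions = state.positions + rng.normal(0, jitter, state.positions.shape)
    return topo, state


@pytest.fixture()
def evaluator_factory():
    return lambda topo, ff: Evaluator(topo, ff)
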