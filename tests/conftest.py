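import numpy as np
import pytest

from grn_softmem import (
    SignedDigraph,
    build_reservoir,
    ecoli_core_surrogate,
)


@pytest.fixture(scope="session")
def surrogate():
    """A fully recurrent 70-node / 317-edge / 41%-repression surrogate core."""
    return ecoli_core_surrogate(12345)


@pytest.fixture(scope="session")
def surrogate_reservoir(surrogate):
    return build_reservoir(surrogate, rho=0.95, n_inputs=1, seed=7)


@pytest.fixture()
def three_cycle():
    g = SignedDigraph()
    g.add_edge("a", "b", 1)
    g.add_edge("b", "c", 1)
    g.add_edge("c", "a", 1)
    return g


def random_graph_tuples(rng: np.random.Generator, n: int, m: int):
    """m distinct signed edge tuples on nodes 0..n-1 (self-loops allowed)."""
    codes = rng.choice(n * n, size=m, replace=False)
    signs = rng.choice([-1, 1], size=m)
    return [(int(c) // n, int(c) % n, int(s)) for c, s in zip(codes, signs)]
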