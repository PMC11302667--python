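import numpy as np
import pytest

import rdistance as rd


@pytest.fixture(scope="session")
def p3():
    return rd.path_graph(3)


@pytest.fixture(scope="session")
def p3_oracle(p3):
    return rd.oracle_apsp(p3)


@pytest.fixture(scope="session")
def grid3():
    return rd.grid_graph(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240701)


def small_random_graphs(n_graphs=12, n_max=8, seed0=100):
    """A deterministic batch of tiny directed and undirected graphs."""
    out = []
    for k in range(n_graphs):
        rng = np.random.default_rng(seed0 + k)
        n = int(rng.integers(2, n_max + 1))
        directed = bool(k % 2)
        g = rd.dense_random(n, p=0.4, directed=directed, seed=seed0 + k)
        out.append(g)
    return out
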