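import numpy as np
import pytest

import hyperricci as hr


@pytest.fixture(scope="session")
def toys():
    return hr.toy_complexes()


def unit_weighted(network: hr.InteractionNetwork) -> hr.WeightedComplex:
    """Weighted complex with all weights 1 (uniform-expression chain)."""
    cx = hr.build_complex(network)
    x = {v: 1.0 for v in network.vertices}
    transition = hr.mass_action_transition(network, x)
    stationary = hr.stationary_distribution(transition, x=x)
    return hr.WeightedComplex(
        complex=cx,
        w_vertex={v: 1.0 for v in network.vertices},
        w_edge={e: 1.0 for e in network.skeleton_edges()},
        w_face={f: 1.0 for f in cx.faces},
        transition=transition,
        stationary=stationary,
    )


def random_weighted_complex(rng: np.random.Generator, n: int, p: float = 0.35):
    """Random connected weighted complex with positive random weights."""
    import networkx as nx

    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() > 1:
            break
    net = hr.InteractionNetwork.from_edges(
        [(f"v{u}", f"v{v}") for u, v in g.edges()]
    )
    cx = hr.build_complex(net)
    x = {v: float(rng.uniform(0.2, 5.0)) for v in net.vertices}
    transition = hr.mass_action_transition(net, x)
    stationary = hr.stationary_distribution(transition, x=x)
    return hr.WeightedComplex(
        complex=cx,
        w_vertex={v: float(rng.uniform(0.2, 5.0)) for v in net.vertices},
        w_edge={e: float(rng.uniform(0.2, 5.0)) for e in net.skeleton_edges()},
        w_face={f: float(rng.uniform(0.2, 5.0)) for f in cx.faces},
        transition=transition,
        stationary=stationary,
    )
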