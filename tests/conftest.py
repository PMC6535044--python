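import networkx as nx
import pytest

from ppifunc.network import LEVELS, ProteinNetwork, WeightTables, edge_weights, node_weights


@pytest.fixture
def g5() -> ProteinNetwork:
    """The canonical 5-node graph: A-B, A-C, B-C, C-D, D-E."""
    return ProteinNetwork.from_edges([("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture
def g5_weights_025(g5) -> WeightTables:
    """G5 weight tables with every threshold pinned at 0.25 (node) / 0.25 (edge)."""
    nw = node_weights(g5)
    ew = edge_weights(g5)
    thresholds = {("node", lvl): 0.0 for lvl in LEVELS}
    thresholds.update({("edge", lvl): 0.25 for lvl in LEVELS})
    return WeightTables(
        node_weight=nw, edge_weight=ew, mean_nw=1.0, std_nw=0.0, mean_ew=0.0, std_ew=0.0,
        thresholds=thresholds,
    )


def random_network(seed: int, n: int = 12, p: float = 0.3) -> ProteinNetwork:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return ProteinNetwork.from_edges(
        ((f"P{u}", f"P{v}") for u, v in g.edges), isolated=(f"P{i}" for i in g.nodes)
    )
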