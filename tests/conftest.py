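import numpy as np
import pandas as pd
import pytest

from costim.core import LogicNetwork, MeanSurface, NodeRole, StimulationDesign
from costim.core import OBSERVED


@pytest.fixture
def design():
    return StimulationDesign()


@pytest.fixture
def toy_network():
    """Small two-pathway cascade: NaCl->A->B<-|C<-Phe, B->D."""
    net = LogicNetwork()
    net.add_node("NaCl", NodeRole.STIMULUS)
    net.add_node("Phe", NodeRole.STIMULUS)
    for n in "ABCD":
        net.add_node(n, NodeRole.PPEP, True)
    net.add_edge("NaCl", 1, "A")
    net.add_edge("A", 1, "B")
    net.add_edge("Phe", 1, "C")
    net.add_edge("C", -1, "B")
    net.add_edge("B", 1, "D")
    return net


def boolean_eval(network: LogicNetwork, inputs: dict[str, int]) -> dict[str, int]:
    """Independent oracle: topological Boolean evaluation of the gate logic."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for s, _sg, t in network.edges:
        g.add_edge(s, t)
    for _gid, (ins, t) in network.and_gates.items():
        for s, _sg in ins:
            g.add_edge(s, t)
    values = dict(inputs)
    for node in nx.topological_sort(g):
        if node in values:
            continue
        terms = []
        for (s, sg, t) in network.edges:
            if t == node:
                u = values[s]
                terms.append(u if sg == 1 else 1 - u)
        for _gid, (ins, t) in network.and_gates.items():
            if t == node:
                terms.append(
                    int(all((values[s] if sg == 1 else 1 - values[s]) for s, sg in ins))
                )
        values[node] = int(any(terms)) if terms else 0
    return values


def surface_from_grids(grids: dict[str, np.ndarray], design: StimulationDesign) -> MeanSurface:
    """Build a fully-observed MeanSurface from per-ppep value grids."""
    rows = []
    for ppep, grid in grids.items():
        grid = np.asarray(grid, dtype=float)
        for i, tn in enumerate(design.nacl_times):
            for j, tp in enumerate(design.phe_times):
                rows.append((ppep, tn, tp, grid[i, j], 0.0, 3, OBSERVED))
    df = pd.DataFrame(
        rows, columns=["ppep_id", "t_nacl", "t_phe", "mean", "sd", "n", "provenance"]
    ).set_index(["ppep_id", "t_nacl", "t_phe"])
    return MeanSurface(df, design)
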