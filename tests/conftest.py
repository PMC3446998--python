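import io

import numpy as np
import pytest

from prorank.network_io import InteractionNetwork
from prorank.pagerank import rank_network


@pytest.fixture
def three_cycle() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def single_edge() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B")])


@pytest.fixture
def in_star() -> InteractionNetwork:
    """Four leaves all pointing at one center."""
    return InteractionNetwork.from_edges([(f"L{i}", "C") for i in range(4)])


@pytest.fixture
def ten_node_network() -> InteractionNetwork:
    rng = np.random.default_rng(7)
    names = [f"N{i}" for i in range(10)]
    edges = [
        (names[i], names[j])
        for i in range(10)
        for j in range(10)
        if i != j and rng.random() < 0.3
    ]
    return InteractionNetwork.from_edges(edges, extra_nodes=names)


@pytest.fixture
def ranking_ten(ten_node_network):
    return rank_network(ten_node_network, "forward")


def edge_table_stream(rows, header="source\ttarget\tpids"):
    body = "\n".join(f"{u}\t{v}\t{p}" for u, v, p in rows)
    return io.StringIO(f"{header}\n{body}\n")
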