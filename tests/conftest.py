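import networkx as nx
import numpy as np
import pytest

from netdiffuse.graph_io import PathwayNetwork, SeedSet
from netdiffuse.synthetic_data import (
    PlantedNetworkSpec,
    generate_planted_pathway_network,
)


def make_network(edges, nodes=()):
    """Build a PathwayNetwork from (a, b) or (a, b, pathway_set) tuples."""
    triples = []
    for e in edges:
        if len(e) == 2:
            triples.append((e[0], e[1], set()))
        else:
            triples.append((e[0], e[1], set(e[2])))
    return PathwayNetwork.from_edges(triples, nodes=nodes)


def seeds_for(network, genes):
    return SeedSet.from_genes(genes, network)


def random_connected_network(n, p, seed):
    """ER graph conditioned on connectedness, with string labels."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
    return PathwayNetwork(g)


@pytest.fixture
def path_abc():
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def planted_network():
    """The default planted-pathway fixture: 4 pathways x 20 genes."""
    return generate_planted_pathway_network(PlantedNetworkSpec())


@pytest.fixture(scope="session")
def small_planted_network():
    """A cheaper planted fixture for unit tests."""
    spec = PlantedNetworkSpec(
        n_pathways=2, pathway_size=8, intra_edge_prob=0.4,
        n_linker_edges=3, n_background_nodes=6, background_edge_prob=0.05,
        rng_seed=3,
    )
    return generate_planted_pathway_network(spec)
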