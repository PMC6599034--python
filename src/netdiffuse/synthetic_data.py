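"""Planted-pathway networks, null seed sets, and toy drug-screen tables.

The planted-pathway generator emulates the structure the workflow assumes of
a curated pathway resource distributed as pairwise interactions: pathways are
annotated edge communities (each pathway a connected random graph on its
members, every intra-pathway edge carrying the pathway's name), cross-talk is
modelled by unannotated linker edges between pathways, and a fringe of
sparsely attached background nodes stands in for the rest of the interactome.
Pathway membership is defined by the annotated edges themselves, exactly as
it is derived from an extended-SIF file.

The drug-screen generator plants a known (gene pair, drug) signal: for the
planted drugs, every cell line mutated in either planted gene has an IC50
below the drug's maximum screening concentration and every wild-type line
lies above it; for all other drugs the construction guarantees that both the
mutant and wild-type groups contain at least one responder and one
non-responder, so no tested stratification can separate them perfectly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .drug_response import DrugScreenTable
from .graph_io import PathwayNetwork, SeedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Shape of a synthetic pathway-annotated network.

    Defaults give four pathways of 20 genes each (dense enough for diffusion
    to stay mostly inside a pathway), 15 unannotated cross-pathway linker
    edges, and 40 sparsely attached background nodes.
    """

    n_pathways: int = 4
    pathway_size: int = 20
    intra_edge_prob: float = 0.25
    n_linker_edges: int = 15
    n_background_nodes: int = 40
    background_edge_prob: float = 0.02
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")
        if self.pathway_size < 3:
            raise ValueError("pathway_size must be >= 3")
        for p in (self.intra_edge_prob, self.background_edge_prob):
            if not 0 < p <= 1:
                raise ValueError("probabilities must be in (0, 1]")
        if self.n_linker_edges > 0 and self.n_pathways < 2:
            raise ValueError("linker edges need >= 2 pathways")

    def pathway_name(self, i: int) -> str:
        return f"PW{i + 1}"


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_planted_pathway_network(spec: PlantedNetworkSpec) -> PathwayNetwork:
    """Build a simple graph of annotated pathway communities plus background.

    Each pathway subgraph is connected by construction: a uniform random
    recursive tree on its members plus Bernoulli(intra_edge_prob) extra edges.
    """
    rng = _as_rng(spec.rng_seed)
    g = nx.Graph()

    for i in range(spec.n_pathways):
        name = spec.pathway_name(i)
        members = [f"P{i + 1}G{j:02d}" for j in range(spec.pathway_size)]
        order = list(rng.permutation(members))
        g.add_nodes_from(members)
        # random spanning tree: attach each node to a uniformly chosen earlier one
        for j in range(1, len(order)):
            k = int(rng.integers(0, j))
            g.add_edge(order[j], order[k], pathways={name}, interaction=None)
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                a, b = members[a_idx], members[b_idx]
                if not g.has_edge(a, b) and rng.random() < spec.intra_edge_prob:
                    g.add_edge(a, b, pathways={name}, interaction=None)

    # unannotated cross-pathway linker edges (cross-talk outside any pathway)
    pathway_nodes = [
        [f"P{i + 1}G{j:02d}" for j in range(spec.pathway_size)]
        for i in range(spec.n_pathways)
    ]
    added = 0
    guard = 0
    while added < spec.n_linker_edges:
        guard += 1
        if guard > 1000 * max(spec.n_linker_edges, 1):
            raise RuntimeError("could not place requested linker edges")
        i, j = rng.choice(spec.n_pathways, size=2, replace=False)
        a = pathway_nodes[i][int(rng.integers(spec.pathway_size))]
        b = pathway_nodes[j][int(rng.integers(spec.pathway_size))]
        if g.has_edge(a, b):
            continue
        g.add_edge(a, b, pathways=set(), interaction=None)
        added += 1

    # sparsely attached background nodes, never annotated
    core = list(g.nodes)
    for j in range(spec.n_background_nodes):
        node = f"BG{j:03d}"
        g.add_node(node)
        neighbors = [v for v in core if rng.random() < spec.background_edge_prob]
        if not neighbors:
            neighbors = [core[int(rng.integers(len(core)))]]
        for v in neighbors:
            g.add_edge(node, v, pathways=set(), interaction=None)

    return PathwayNetwork(g)


def generate_null_seed_set(network: PathwayNetwork, size: int, rng=None) -> SeedSet:
    """Seeds drawn uniformly without replacement from all nodes (calibration)."""
    rng = _as_rng(rng)
    nodes = network.node_list
    if size > len(nodes):
        raise ValueError(f"requested {size} seeds from {len(nodes)} nodes")
    chosen = rng.choice(nodes, size=size, replace=False)
    return SeedSet.from_genes(chosen, network)


def generate_drug_screen(
    n_cell_lines: int = 9,
    n_drugs: int = 12,
    planted_pair: tuple[str, str] = ("GENE_A", "GENE_B"),
    planted_drugs: tuple[str, ...] | None = None,
    rng=None,
) -> DrugScreenTable:
    """Toy IC50 / max-concentration / mutation tables with a planted signal.

    For every planted drug, mutation in either planted-pair gene implies an
    IC50 below the drug's maximum screening concentration (responder) and
    wild-type implies an IC50 above it.  For every other drug both strata mix
    responders and non-responders, so only the planted combinations separate.
    Two decoy genes ("DECOY1", "DECOY2") are each mutated in exactly one
    distinct mutant line, so decoy-based strata are strict subsets of the
    planted mutant group and can never reproduce the planted split.
    """
    rng = _as_rng(rng)
    if n_cell_lines < 2:
        raise ValueError("need at least 2 cell lines")
    drugs = [f"drug{k + 1:02d}" for k in range(n_drugs)]
    if planted_drugs is None:
        planted_drugs = tuple(drugs[: min(3, n_drugs)])
    unknown = set(planted_drugs) - set(drugs)
    if unknown:
        raise ValueError(f"planted drugs not in panel: {sorted(unknown)}")

    lines = [f"CL{k + 1:02d}" for k in range(n_cell_lines)]
    gene_a, gene_b = planted_pair

    # mutant group: roughly a third of the panel, at least 1
    n_mut = max(1, min(n_cell_lines - 1, round(n_cell_lines / 3) + 1))
    mutant_lines = list(rng.choice(lines, size=n_mut, replace=False))
    wildtype_lines = [l for l in lines if l not in mutant_lines]

    mut = pd.DataFrame(0, index=lines, columns=[gene_a, gene_b], dtype=int)
    for k, line in enumerate(mutant_lines):
        # alternate the two genes so neither covers the whole mutant group
        gene = (gene_a, gene_b)[k % 2]
        mut.loc[line, gene] = 1
        if rng.random() < 0.25:  # occasional double mutant
            mut.loc[line] = 1
    if n_mut >= 3:
        for d, line in zip(("DECOY1", "DECOY2"), mutant_lines[:2]):
            mut[d] = 0
            mut.loc[line, d] = 1
    else:
        logger.warning("too few mutant lines for decoy genes; none added")

    max_conc = pd.Series(
        rng.choice([0.1, 1.0, 10.0], size=n_drugs), index=drugs, name="max_conc"
    )
    ic50 = pd.DataFrame(index=lines, columns=drugs, dtype=float)
    for drug in drugs:
        conc = max_conc[drug]
        if drug in planted_drugs:
            for line in lines:
                if line in mutant_lines:
                    ic50.loc[line, drug] = conc * 10 ** (-rng.uniform(0.5, 2.0))
                else:
                    ic50.loc[line, drug] = conc * 10 ** (rng.uniform(0.3, 1.5))
        else:
            ic50[drug] = conc * 10 ** rng.normal(0.0, 0.8, size=n_cell_lines)
            # guarantee mixed response inside each stratum where possible
            if len(mutant_lines) >= 2 and len(wildtype_lines) >= 2:
                mr, mn = rng.choice(mutant_lines, size=2, replace=False)
                wr, wn = rng.choice(wildtype_lines, size=2, replace=False)
                ic50.loc[mr, drug] = conc * 10 ** (-rng.uniform(0.5, 1.5))
                ic50.loc[mn, drug] = conc * 10 ** (rng.uniform(0.5, 1.5))
                ic50.loc[wr, drug] = conc * 10 ** (-rng.uniform(0.5, 1.5))
                ic50.loc[wn, drug] = conc * 10 ** (rng.uniform(0.5, 1.5))

    return DrugScreenTable(ic50=ic50, max_conc=max_conc, mutations=mut)
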