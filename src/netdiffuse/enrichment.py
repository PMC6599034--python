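"""Pathway enrichment of an extracted subnetwork.

Each subnetwork edge inherits the pathway annotations of its parent edge; a
pathway is over-represented when the subnetwork contains more of its edges
than a random draw of the same number of edges from the parent network would.
The test is the hypergeometric upper tail on the edge universe:

    p = P[X >= k],  X ~ Hypergeom(N = parent edges, K = pathway edges,
                                  n = subnetwork edges)

with BH adjustment across the pathways actually represented (k >= 1) in the
subnetwork.  A gene-based variant (sample = subnetwork nodes, universe =
parent nodes, category = pathway members) is available via ``unit="gene"``.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .graph_io import PathwayNetwork
from .null_model import Subnetwork, bh_adjust

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeom(N, K, n)."""
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


def annotate_subnetwork_pathways(subnetwork: Subnetwork) -> dict[str, list[tuple[str, str]]]:
    """Map each pathway to the subnetwork edges annotated with it.

    An edge carrying m pathway names appears in m lists; unannotated edges
    appear in none.
    """
    mapping: dict[str, list[tuple[str, str]]] = {}
    net = subnetwork.as_network()
    for edge, pathways in net.edge_pathways.items():
        for p in pathways:
            mapping.setdefault(p, []).append(edge)
    return mapping


def _edge_based_rows(subnetwork: Subnetwork, network: PathwayNetwork):
    N = network.n_edges()
    sub_edges = subnetwork.edges
    n = len(sub_edges)
    parent_counts: dict[str, int] = {}
    for pathways in network.edge_pathways.values():
        for p in pathways:
            parent_counts[p] = parent_counts.get(p, 0) + 1
    sub_counts = {p: len(e) for p, e in annotate_subnetwork_pathways(subnetwork).items()}
    return N, n, parent_counts, sub_counts


def _gene_based_rows(subnetwork: Subnetwork, network: PathwayNetwork):
    N = network.n_nodes()
    n = len(subnetwork.nodes)
    parent_counts = {p: len(m) for p, m in network.pathway_members.items()}
    sub_counts = {}
    for p, members in network.pathway_members.items():
        k = len(members & subnetwork.nodes)
        if k:
            sub_counts[p] = k
    return N, n, parent_counts, sub_counts


def pathway_enrichment(
    subnetwork: Subnetwork,
    network: PathwayNetwork | None = None,
    unit: str = "edge",
) -> pd.DataFrame:
    """Hypergeometric enrichment of pathways represented in a subnetwork.

    Returns a DataFrame with columns ``pathway, k, n, K, N, p, q`` sorted by
    q then p.  Only pathways with at least one subnetwork edge (or node, for
    ``unit="gene"``) are tested; BH m is the number tested.
    """
    network = network if network is not None else subnetwork.parent
    if unit == "edge":
        N, n, parent_counts, sub_counts = _edge_based_rows(subnetwork, network)
    elif unit == "gene":
        N, n, parent_counts, sub_counts = _gene_based_rows(subnetwork, network)
    else:
        raise ValueError(f"unit must be 'edge' or 'gene', got {unit!r}")

    if n == 0:
        logger.warning("subnetwork has no %ss; nothing to test", unit)
        return pd.DataFrame(columns=["pathway", "k", "n", "K", "N", "p", "q"])

    rows = []
    for pathway, k in sorted(sub_counts.items()):
        K = parent_counts[pathway]
        p = hypergeom_tail(k, N, K, n)
        rows.append({"pathway": pathway, "k": k, "n": n, "K": K, "N": N, "p": p})
    if not rows:
        return pd.DataFrame(columns=["pathway", "k", "n", "K", "N", "p", "q"])
    frame = pd.DataFrame(rows)
    frame["q"] = bh_adjust(frame["p"].to_numpy())
    return frame.sort_values(["q", "p", "pathway"], ignore_index=True)
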