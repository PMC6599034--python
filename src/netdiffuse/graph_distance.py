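"""Labeled maximal-common-subgraph distance between result networks.

Two subnetworks are compared through the maximal common subgraph (MCS) whose
node matching is constrained to identical gene labels.  Because both graphs
are uniquely labeled, the maximum-node common subgraph is exactly the
intersection of the label sets together with the intersection of the edge
sets — no isomorphism search is needed (a common subgraph need not be
induced, so every shared label can always be kept, with or without edges).
The distance is

    d(G1, G2) = 1 - |MCS(G1, G2)| / max(|G1|, |G2|)

where |.| counts nodes.  d is symmetric and lies in [0, 1]; the triangle
inequality is not relied upon anywhere.

Pairwise matrices feed scipy's agglomerative clustering; cophenetic
correlation between two matrices' dendrograms serves as a stability measure
across parameter settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

LINKAGES = ("average", "complete", "single")


def _canon(edge) -> tuple:
    a, b = edge
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class LabeledGraph:
    """A simple graph with unique node labels (no per-node payload needed)."""

    nodes: frozenset
    edges: frozenset  # of canonical (a, b) tuples

    @classmethod
    def build(cls, nodes, edges=()) -> "LabeledGraph":
        nodes = frozenset(nodes)
        canon = frozenset(_canon(e) for e in edges if e[0] != e[1])
        for a, b in canon:
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge ({a}, {b}) references a missing node")
        return cls(nodes=nodes, edges=canon)

    @classmethod
    def from_subnetwork(cls, subnetwork) -> "LabeledGraph":
        # the full subnetwork: seeds + significant nodes + induced edges
        return cls.build(subnetwork.nodes, subnetwork.edges)

    def __len__(self) -> int:
        return len(self.nodes)


def labeled_mcs(g1: LabeledGraph, g2: LabeledGraph) -> LabeledGraph:
    """Maximum-node common subgraph under the identical-label constraint.

    With unique labels this is the node-set intersection with the shared
    edges; the result may be disconnected or empty.
    """
    nodes = g1.nodes & g2.nodes
    edges = g1.edges & g2.edges
    return LabeledGraph(nodes=nodes, edges=edges)


def mcs_distance(g1: LabeledGraph, g2: LabeledGraph) -> float:
    """MCS distance 1 - |MCS|/max(|G1|, |G2|), node-counted, in [0, 1]."""
    bigger = max(len(g1), len(g2))
    if bigger == 0:
        logger.warning("both graphs empty; distance defined as 0")
        return 0.0
    return 1.0 - len(labeled_mcs(g1, g2)) / bigger


@dataclass
class DistanceMatrix:
    """Named symmetric pairwise distance matrix with zero diagonal."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match names")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def pairwise_distances(items: dict[str, LabeledGraph]) -> DistanceMatrix:
    """MCS-distance matrix over a named collection of labeled graphs."""
    names = list(items)
    if len(names) != len(set(names)):
        raise ValueError("duplicate item names")
    if len(names) < 2:
        raise ValueError("need at least 2 items")
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = mcs_distance(items[names[i]], items[names[j]])
    return DistanceMatrix(names=names, values=d)


def hierarchical_cluster(matrix: DistanceMatrix, linkage: str = "average"):
    """Agglomerative clustering on precomputed distances.

    Returns the scipy linkage matrix (merge tree with heights).  Leaf order
    for heatmap display is available via ``leaf_order``.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if len(matrix.names) < 2:
        raise ValueError("need at least 2 items to cluster")
    return sch.linkage(matrix.condensed(), method=linkage)


def leaf_order(matrix: DistanceMatrix, linkage: str = "average") -> list[str]:
    Z = hierarchical_cluster(matrix, linkage)
    return [matrix.names[i] for i in sch.leaves_list(Z)]


def cophenetic_correlation(
    m1: DistanceMatrix, m2: DistanceMatrix, linkage: str = "average"
) -> float:
    """Pearson correlation between the cophenetic distances of two clusterings.

    Both matrices must be over the same item names (order-insensitive; m2 is
    realigned to m1's order).  Returns NaN with a warning if either
    dendrogram's cophenetic vector has zero variance.
    """
    if set(m1.names) != set(m2.names):
        raise ValueError("matrices must cover the same item names")
    if m1.names != m2.names:
        perm = [m2.names.index(n) for n in m1.names]
        m2 = DistanceMatrix(names=list(m1.names), values=m2.values[np.ix_(perm, perm)])
    c1 = sch.cophenet(hierarchical_cluster(m1, linkage))
    c2 = sch.cophenet(hierarchical_cluster(m2, linkage))
    if np.std(c1) == 0 or np.std(c2) == 0:
        logger.warning("zero-variance cophenetic vector; correlation undefined")
        return float("nan")
    return float(pearsonr(c1, c2)[0])


def to_newick(matrix: DistanceMatrix, linkage: str = "average") -> str:
    """Dendrogram as a Newick string with branch lengths from merge heights."""
    Z = hierarchical_cluster(matrix, linkage)
    tree = sch.to_tree(Z)

    def walk(node, parent_height) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{matrix.names[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
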