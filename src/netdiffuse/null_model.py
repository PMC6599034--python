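"""Degree-preserving null networks and empirical significance of diffusion scores.

The null model is strictly an edge-switched ensemble (Maslov–Sneppen double
edge swaps): repeated replacement of edge pairs (a,b),(c,d) by (a,d),(c,b)
whenever the swap creates no self-loop and no duplicate edge.  This preserves
every node's degree exactly while destroying higher-order structure, so a
node whose observed diffusion score beats the ensemble received more seed
diffusion than its degree alone explains.

Per-node p-values use the add-one permutation estimator
``p = (1 + #{f_random >= f_observed}) / (1 + n_random)`` with ties counted
(conservative), followed by Benjamini–Hochberg step-up adjustment across all
unlabeled nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .graph_io import PathwayNetwork, SeedSet
from .propagation import DEFAULT_ITERATIONS, _adjacency, propagate_scores

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RandomizationSpec:
    """Parameters of the null ensemble.

    ``n_random`` random networks (default 1000), each produced by
    ``swaps_per_edge * |E|`` attempted double edge swaps (Q, default 10).
    """

    n_random: int = 1000
    swaps_per_edge: float = 10.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.swaps_per_edge <= 0:
            raise ValueError("swaps_per_edge must be > 0")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _attempt_swaps(edges: list, adj: dict, n_attempts: int, rng: np.random.Generator) -> int:
    """Attempt ``n_attempts`` double edge swaps in place; return number applied."""
    m = len(edges)
    applied = 0
    # draw indices in blocks to avoid per-attempt Generator overhead
    idx = rng.integers(0, m, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    for k in range(n_attempts):
        i, j = idx[k]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip[k]:
            c, d = d, c
        if a == d or c == b:
            continue  # would create a self-loop
        if d in adj[a] or b in adj[c]:
            continue  # would create a duplicate edge
        adj[a].discard(b)
        adj[b].discard(a)
        adj[c].discard(d)
        adj[d].discard(c)
        adj[a].add(d)
        adj[d].add(a)
        adj[c].add(b)
        adj[b].add(c)
        edges[i] = (a, d)
        edges[j] = (c, b)
        applied += 1
    return applied


def edge_switch_randomize(
    network: PathwayNetwork, swaps_per_edge: float = 10.0, rng=None
) -> PathwayNetwork:
    """Fully rewire a network by repeated double edge swaps.

    Performs ``swaps_per_edge * |E|`` attempted swaps; illegal proposals
    (self-loop or duplicate) are rejected.  The degree multiset is preserved
    exactly.  Pathway annotations are dropped: null networks exist only to be
    propagated on.
    """
    rng = _as_rng(rng)
    edges = [tuple(e) for e in network.graph.edges]
    if len(edges) < 2:
        logger.warning("network has < 2 edges; no swap possible, returning a copy")
        out = network.copy()
        for _, _, data in out.graph.edges(data=True):
            data["pathways"] = set()
        return out
    adj = {v: set(network.graph.adj[v]) for v in network.graph.nodes}
    n_attempts = int(round(swaps_per_edge * len(edges)))
    applied = _attempt_swaps(edges, adj, n_attempts, rng)
    if applied == 0:
        logger.warning("no legal edge swap found in %d attempts; network unchanged", n_attempts)
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    g.add_edges_from(edges, pathways=set())
    return PathwayNetwork(g)


def rewired_fraction(original: PathwayNetwork, perturbed: PathwayNetwork) -> float:
    """Fraction of the original edges absent from the perturbed network."""
    if original.nodes != perturbed.nodes:
        raise ValueError("rewired_fraction requires identical node sets")
    e0 = original.edges
    if not e0:
        return 0.0
    return len(e0 - perturbed.edges) / len(e0)


def perturb_network(
    network: PathwayNetwork, target_fraction: float, rng=None
) -> PathwayNetwork:
    """Partially rewire: apply legal swaps one at a time until the fraction of
    original edges replaced reaches ``target_fraction``.

    Pathway annotations survive on original edges that remain; new edges are
    unannotated.  One applied swap replaces at most 2 of |E| original edges,
    so the achieved fraction lies in [target, target + 2/|E|].
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    rng = _as_rng(rng)
    edges = [tuple(e) for e in network.graph.edges]
    m = len(edges)
    if m < 2:
        raise ValueError("cannot perturb a network with < 2 edges")
    adj = {v: set(network.graph.adj[v]) for v in network.graph.nodes}
    original = network.edges

    def current_fraction() -> float:
        kept = sum(1 for e in edges if frozenset(e) in _orig_fs)
        return (m - kept) / m

    _orig_fs = {frozenset(e) for e in original}
    max_attempts = 100 * m
    attempts = 0
    frac = 0.0
    while frac < target_fraction:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"perturbation target {target_fraction:.4g} unreachable after "
                f"{max_attempts} attempts; achieved {frac:.4g}"
            )
        applied = _attempt_swaps(edges, adj, 1, rng)
        attempts += 1
        if applied:
            frac = current_fraction()

    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for a, b in edges:
        if frozenset((a, b)) in _orig_fs:
            data = network.graph.edges[a, b]
            g.add_edge(a, b, pathways=set(data.get("pathways", ())),
                       interaction=data.get("interaction"))
        else:
            g.add_edge(a, b, pathways=set(), interaction=None)
    return PathwayNetwork(g)


# ---------------------------------------------------------------------------
# significance


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order-preserving, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SignificanceTable:
    """Observed f, empirical p, and BH q for every unlabeled node."""

    frame: pd.DataFrame  # index: gene; columns: f, p, q
    n_random: int
    seeds: SeedSet
    t: int

    def significant(self, alpha: float, on: str = "q", strict: bool = True) -> set[str]:
        col = self.frame[on]
        mask = col < alpha if strict else col <= alpha
        return set(self.frame.index[mask])


def build_ensemble(
    network: PathwayNetwork, spec: RandomizationSpec
) -> list[PathwayNetwork]:
    """Generate the shared random-network ensemble for one significance run."""
    rng = _as_rng(spec.rng_seed)
    return [
        edge_switch_randomize(network, spec.swaps_per_edge, rng)
        for _ in range(spec.n_random)
    ]


def empirical_pvalues(
    network: PathwayNetwork,
    seeds: SeedSet,
    t: int = DEFAULT_ITERATIONS,
    spec: RandomizationSpec | None = None,
    ensemble: list[PathwayNetwork] | None = None,
) -> SignificanceTable:
    """Empirical per-node p-values of diffusion scores against the null ensemble.

    Propagation runs with identical seeds and t on the original network and on
    every random network (node sets coincide; only wiring differs).  A single
    shared ensemble serves all nodes.  ``ensemble`` may be passed explicitly
    to reuse one ensemble across parameter sweeps.
    """
    spec = spec or RandomizationSpec()
    if ensemble is None:
        ensemble = build_ensemble(network, spec)
    if not ensemble:
        raise ValueError("empty null ensemble")

    nodes, A = _adjacency(network)
    seed_mask = np.array([v in seeds.mapped for v in nodes])
    if not seed_mask.any():
        raise ValueError("seed set maps to no network node")
    f_obs = propagate_scores(A, seed_mask, t)

    counts = np.zeros(len(nodes), dtype=int)
    for random_net in ensemble:
        A_r = nx.to_scipy_sparse_array(
            random_net.graph, nodelist=nodes, weight=None, format="csr"
        ).astype(float)
        f_r = propagate_scores(A_r, seed_mask, t)
        counts += f_r >= f_obs

    n_random = len(ensemble)
    unlabeled = ~seed_mask
    p = (1.0 + counts[unlabeled]) / (1.0 + n_random)
    q = bh_adjust(p)
    frame = pd.DataFrame(
        {"f": f_obs[unlabeled], "p": p, "q": q},
        index=pd.Index(np.array(nodes)[unlabeled], name="gene"),
    )
    return SignificanceTable(frame=frame, n_random=n_random, seeds=seeds, t=t)


@dataclass
class Subnetwork:
    """Seeds plus significant nodes with the parent-induced annotated edges."""

    parent: PathwayNetwork
    seeds: SeedSet
    table: SignificanceTable
    alpha: float
    nodes: frozenset[str]
    graph: nx.Graph = field(repr=False)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return PathwayNetwork(self.graph).edges

    def as_network(self) -> PathwayNetwork:
        return PathwayNetwork(self.graph)

    def n_nodes(self) -> int:
        return len(self.nodes)


def extract_subnetwork(
    network: PathwayNetwork,
    seeds: SeedSet,
    table: SignificanceTable,
    alpha: float = 0.05,
    on: str = "q",
) -> Subnetwork:
    """Induce the subnetwork of seeds plus nodes significant at ``alpha``.

    ``on`` selects the thresholded column: BH-adjusted ``q`` (default) or raw
    ``p``.  No connected-component filtering is applied.  The cut is strict
    (q < alpha) except at alpha = 1, which admits every tested node.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    significant = table.significant(alpha, on=on, strict=alpha < 1)
    nodes = frozenset(seeds.mapped | significant)
    sub = network.graph.subgraph(nodes).copy()
    return Subnetwork(
        parent=network, seeds=seeds, table=table, alpha=alpha,
        nodes=nodes, graph=sub,
    )
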