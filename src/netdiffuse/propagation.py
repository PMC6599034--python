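"""Harmonic-function label propagation from a clamped seed set.

The model: given an undirected graph with symmetric 0/1 weight matrix ``W``,
seed (labeled) nodes are clamped to value 1 and every unlabeled node ``j`` is
repeatedly replaced by the degree-normalized average of its neighbours,

    f(x_j) <- sum_k w_jk f(x_k) / sum_k w_jk,

starting from f = 0 on unlabeled nodes.  Updates are synchronous (Jacobi
style): each iteration uses only the previous iteration's values, so results
do not depend on node order.  After ``t`` iterations the score of a node
reflects how much diffusion it has received from the seeds within a
t-step horizon; the fixed point (t -> infinity) is the harmonic extension of
the boundary values, which with a single all-1 boundary is identically 1 on
every seed-containing component.  The finite-t scores, compared against a
degree-preserving null ensemble, are what carry the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_io import PathwayNetwork, SeedSet

DEFAULT_ITERATIONS = 10  # default diffusion horizon t


@dataclass(frozen=True)
class PropagationResult:
    """Per-node diffusion scores after ``t`` synchronous iterations."""

    f: dict[str, float]
    t: int
    seeds: SeedSet

    def scores_for(self, nodes) -> np.ndarray:
        return np.array([self.f[v] for v in nodes])


def _adjacency(network: PathwayNetwork):
    nodes = network.node_list
    A = nx.to_scipy_sparse_array(network.graph, nodelist=nodes, weight=None, format="csr")
    return nodes, A.astype(float)


def propagate_scores(
    A: sp.csr_array, seed_mask: np.ndarray, t: int
) -> np.ndarray:
    """Vectorized core: run ``t`` clamped synchronous iterations on adjacency ``A``.

    ``seed_mask`` is boolean; degree-0 unlabeled nodes keep score 0.
    """
    deg = np.asarray(A.sum(axis=1)).ravel()
    unlabeled = ~seed_mask
    safe_deg = np.where(deg > 0, deg, 1.0)
    f = seed_mask.astype(float)
    for _ in range(t):
        new = (A @ f) / safe_deg
        new[deg == 0] = 0.0
        f = np.where(unlabeled, new, 1.0)
    return f


def propagate(network: PathwayNetwork, seeds: SeedSet, t: int = DEFAULT_ITERATIONS) -> PropagationResult:
    """Run label propagation for exactly ``t`` iterations.

    Seeds are clamped to 1 throughout; unlabeled nodes start at 0.  Raises
    ``ValueError`` for ``t < 1`` or an empty mapped seed set.
    """
    if t < 1:
        raise ValueError(f"iteration count t must be >= 1, got {t}")
    if not seeds.mapped:
        raise ValueError("seed set maps to no network node")
    nodes, A = _adjacency(network)
    seed_mask = np.array([v in seeds.mapped for v in nodes])
    f = propagate_scores(A, seed_mask, t)
    return PropagationResult(f=dict(zip(nodes, f)), t=t, seeds=seeds)


def harmonic_fixed_point(
    network: PathwayNetwork,
    seeds: SeedSet,
    pinned: dict[str, float] | None = None,
) -> PropagationResult:
    """Solve the t -> infinity limit of propagation as a sparse linear system.

    Every unlabeled node in a component containing boundary nodes satisfies
    the harmonic (neighbour-average) condition exactly; components without
    boundary get 0.  ``pinned`` optionally holds extra nodes at fixed values
    (a testing generalization: with seeds at 1 and pinned zeros the interior
    interpolates, instead of the all-1 solution of the single-boundary case).
    """
    if not seeds.mapped:
        raise ValueError("seed set maps to no network node")
    pinned = dict(pinned or {})
    boundary = {v: 1.0 for v in seeds.mapped}
    boundary.update(pinned)

    nodes, A = _adjacency(network)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    y = np.zeros(n)
    b_mask = np.zeros(n, dtype=bool)
    for v, val in boundary.items():
        y[index[v]] = val
        b_mask[index[v]] = True

    # restrict the solve to interior nodes in boundary-containing components
    reachable = np.zeros(n, dtype=bool)
    for comp in nx.connected_components(network.graph):
        if any(v in boundary for v in comp):
            for v in comp:
                reachable[index[v]] = True

    interior = reachable & ~b_mask
    f = np.where(b_mask, y, 0.0)
    if interior.any():
        deg = np.asarray(A.sum(axis=1)).ravel()
        D_ii = sp.diags(deg[interior])
        A_ii = A[interior][:, interior]
        A_ib = A[interior][:, b_mask]
        rhs = A_ib @ y[b_mask]
        sol = spla.spsolve((D_ii - A_ii).tocsc(), rhs)
        f[interior] = np.atleast_1d(sol)
    return PropagationResult(f=dict(zip(nodes, f)), t=-1, seeds=seeds)
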