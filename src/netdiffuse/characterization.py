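"""Benchmarking the workflow: pathway recovery, parameter sweeps, stability.

The central measurement is the pair of recovery rates of a significance run
seeded from a subsample of one pathway's genes:

* in-pathway rate — significant genes inside the pathway of interest, over
  all pathway genes not already used as seeds (sensitivity surrogate);
* out-pathway rate — remaining significant genes outside the pathway, over
  all network genes outside the pathway (false-positive surrogate).

Sweeping the iteration parameter t traces one averaged ROC-like curve per t;
sweeping the rewired-edge fraction of a degree-preserving perturbation
measures robustness to annotation noise; and comparing the hierarchical
clusterings of subnetwork distance matrices obtained at different t values
(via cophenetic correlation) measures stability of the downstream
comparisons to parameter choice.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .graph_distance import LabeledGraph, cophenetic_correlation, pairwise_distances
from .graph_io import PathwayNetwork, SeedSet
from .null_model import (
    RandomizationSpec,
    SignificanceTable,
    build_ensemble,
    empirical_pvalues,
    extract_subnetwork,
)

logger = logging.getLogger(__name__)

#: threshold grid for recovery curves (on q by default)
DEFAULT_THRESHOLDS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)
#: iteration values swept when tuning t
DEFAULT_T_VALUES = (5, 10, 15, 20, 25)
#: rewired-edge fractions for the perturbation sweep
DEFAULT_FRACTIONS = (0.001, 0.005, 0.015, 0.025, 0.05, 0.10, 0.25, 0.50)
#: seed-set sizes for pathway subsampling
DEFAULT_SEED_SIZES = (10, 20, 35, 50)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def sample_seed_genes(
    network: PathwayNetwork, pathway: str, size: int, rng=None
) -> SeedSet:
    """Uniform sample without replacement from a pathway's member genes."""
    rng = _as_rng(rng)
    members = network.pathway_members.get(pathway)
    if not members:
        raise ValueError(f"pathway {pathway!r} has no members in this network")
    if size > len(members):
        raise ValueError(
            f"requested {size} seeds but pathway {pathway!r} has {len(members)} members"
        )
    chosen = rng.choice(sorted(members), size=size, replace=False)
    return SeedSet.from_genes(chosen, network)


def recovery_rates(
    table: SignificanceTable,
    seeds: SeedSet,
    pathway_members: set[str],
    network: PathwayNetwork,
    threshold: float,
    on: str = "q",
) -> tuple[float, float]:
    """In-/out-pathway recovery at a significance threshold (inclusive).

    in_rate = |S ∩ P \\ seeds| / |P \\ seeds|, out_rate = |S \\ P| / |V \\ P|
    where S is the significant unlabeled set.  If every pathway gene is a
    seed the in-rate is undefined and returned as NaN.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    significant = table.significant(threshold, on=on, strict=False)
    pathway = set(pathway_members)
    non_seed_pathway = pathway - seeds.mapped
    outside = network.nodes - pathway
    if not non_seed_pathway:
        logger.warning("pathway fully covered by seeds; in-rate undefined")
        in_rate = float("nan")
    else:
        in_rate = len(significant & non_seed_pathway) / len(non_seed_pathway)
    out_rate = len(significant - pathway) / len(outside) if outside else 0.0
    return in_rate, out_rate


def _curve_rows(table, seeds, members, network, thresholds, on="q"):
    for thr in thresholds:
        in_rate, out_rate = recovery_rates(table, seeds, members, network, thr, on=on)
        yield thr, in_rate, out_rate


def iteration_sweep(
    network: PathwayNetwork,
    pathways: list[str],
    sizes: list[int],
    t_values=DEFAULT_T_VALUES,
    reps: int = 5,
    spec: RandomizationSpec | None = None,
    rng=None,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Full factorial pathway x size x replicate x t recovery sweep.

    Within one replicate the same seed set and the same null ensemble serve
    every t value (only the horizon changes), so differences across t are not
    confounded by sampling noise.  Returns one row per
    (pathway, size, rep, t, threshold); average over pathway/size/rep to get
    the per-t curve.
    """
    spec = spec or RandomizationSpec()
    rng = _as_rng(rng)
    members_map = network.pathway_members
    rows = []
    for pathway in pathways:
        members = members_map[pathway]
        for size in sizes:
            for rep in range(reps):
                seeds = sample_seed_genes(network, pathway, size, rng)
                run_spec = replace(spec, rng_seed=_child_seed(rng))
                ensemble = build_ensemble(network, run_spec)
                for t in t_values:
                    table = empirical_pvalues(network, seeds, t=t, ensemble=ensemble)
                    for thr, in_r, out_r in _curve_rows(
                        table, seeds, members, network, thresholds
                    ):
                        rows.append({
                            "pathway": pathway, "size": size, "rep": rep, "t": t,
                            "threshold": thr, "in_rate": in_r, "out_rate": out_r,
                        })
    return pd.DataFrame(rows)


def in_rate_at(curve: pd.DataFrame, out_grid) -> np.ndarray:
    """Interpolate a recovery curve's in-rate at matched out-rate values.

    ``curve`` holds one condition's (out_rate, in_rate) points across the
    threshold grid; the endpoints (0, 0) and (1, 1) anchor the interpolation
    (nothing significant / everything significant).
    """
    pts = curve[["out_rate", "in_rate"]].dropna().sort_values("out_rate")
    x = np.concatenate([[0.0], pts["out_rate"].to_numpy(), [1.0]])
    y = np.concatenate([[0.0], pts["in_rate"].to_numpy(), [1.0]])
    return np.interp(np.asarray(out_grid, dtype=float), x, y)


def mean_curves(sweep: pd.DataFrame, by=("t", "threshold")) -> pd.DataFrame:
    """Average recovery curves over pathways, sizes, and replicates."""
    return (
        sweep.groupby(list(by), as_index=False)[["in_rate", "out_rate"]]
        .mean()
        .sort_values(list(by), ignore_index=True)
    )


def perturbation_sweep(
    network: PathwayNetwork,
    pathway: str,
    fractions=DEFAULT_FRACTIONS,
    reps: int = 5,
    t: int = 10,
    seed_size: int = 5,
    spec: RandomizationSpec | None = None,
    rng=None,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Recovery after degree-preserving partial rewiring of the network.

    For each rewired fraction and replicate the propagation runs on the
    perturbed network while recovery is judged against the original pathway
    membership.  Returns one row per (fraction, rep, threshold); fraction 0
    is always included as the unperturbed reference.
    """
    from .null_model import perturb_network  # local to avoid cycle at import

    spec = spec or RandomizationSpec()
    rng = _as_rng(rng)
    members = network.pathway_members[pathway]
    rows = []
    for fraction in fractions:
        if not 0 <= fraction < 1:
            raise ValueError("fractions must lie in [0, 1)")
        for rep in range(reps):
            if fraction == 0:
                perturbed = network
            else:
                perturbed = perturb_network(network, fraction, rng)
            seeds = sample_seed_genes(network, pathway, seed_size, rng)
            run_spec = replace(spec, rng_seed=_child_seed(rng))
            table = empirical_pvalues(perturbed, seeds, t=t, spec=run_spec)
            for thr, in_r, out_r in _curve_rows(table, seeds, members, network, thresholds):
                rows.append({
                    "fraction": fraction, "rep": rep, "threshold": thr,
                    "in_rate": in_r, "out_rate": out_r,
                })
    return pd.DataFrame(rows)


def stability_across_t(
    network: PathwayNetwork,
    seed_sets: dict[str, SeedSet],
    t_values=DEFAULT_T_VALUES,
    spec: RandomizationSpec | None = None,
    rng=None,
    linkage: str = "average",
    alpha: float = 0.05,
    on: str = "p",
) -> pd.DataFrame:
    """Cophenetic correlation of subnetwork clusterings across t values.

    For each t, every seed set is expanded into a subnetwork (same null
    ensemble throughout, so t is the only variable) and the pairwise MCS
    distance matrix over the subnetworks is clustered; the returned square
    DataFrame holds the cophenetic correlation between each pair of t values.

    Extraction thresholds on raw p by default (``on="p"``): at the ensemble
    sizes practical for sweeps the BH-adjusted floor can leave every
    subnetwork equal to its seeds, which makes all matrices identical and the
    correlation uninformative.
    """
    if len(seed_sets) < 3:
        raise ValueError("need at least 3 seed sets for a non-trivial matrix")
    spec = spec or RandomizationSpec()
    rng = _as_rng(rng)
    run_spec = replace(spec, rng_seed=_child_seed(rng))
    ensemble = build_ensemble(network, run_spec)

    matrices = {}
    for t in t_values:
        graphs = {}
        for name, seeds in seed_sets.items():
            table = empirical_pvalues(network, seeds, t=t, ensemble=ensemble)
            sub = extract_subnetwork(network, seeds, table, alpha=alpha, on=on)
            graphs[name] = LabeledGraph.from_subnetwork(sub)
        matrices[t] = pairwise_distances(graphs)

    t_list = list(t_values)
    out = pd.DataFrame(np.eye(len(t_list)), index=t_list, columns=t_list)
    for i, ti in enumerate(t_list):
        for j in range(i + 1, len(t_list)):
            tj = t_list[j]
            c = cophenetic_correlation(matrices[ti], matrices[tj], linkage=linkage)
            out.loc[ti, tj] = out.loc[tj, ti] = c
    return out
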