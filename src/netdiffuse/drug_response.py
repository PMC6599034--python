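"""Responder classification and the mutant-pair perfect-separation drug screen.

A cell line counts as a responder to a drug when its IC50 lies strictly below
the drug's maximum screening concentration; IC50 at or above that boundary
means the drug never reached its half-maximal effect within the tested dose
range.  Cell lines are stratified by a gene pair — mutant if carrying a
mutation in either gene, wild-type if in neither — and a (pair, drug) hit is
emitted only when the two groups fall into opposite response classes with no
overlap at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NON_RESPONDER = "non_responder"

#: variant classifications counted as silent (no protein change)
SILENT_CLASSES = frozenset({"Silent", "synonymous", "Synonymous", "silent"})
#: common non-silent MAF variant classifications (anything unknown is treated
#: as non-silent, with a log message)
KNOWN_NONSILENT = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins", "Splice_Site",
    "Nonstop_Mutation", "Translation_Start_Site",
})


@dataclass
class DrugScreenTable:
    """IC50s (cell line x drug), per-drug max screening concentration, and
    binary mutation calls (cell line x gene).  Missing IC50s are NaN."""

    ic50: pd.DataFrame
    max_conc: pd.Series
    mutations: pd.DataFrame

    def __post_init__(self):
        missing = set(self.ic50.columns) - set(self.max_conc.index)
        if missing:
            raise ValueError(f"drugs without max screening concentration: {sorted(missing)}")
        if (self.max_conc <= 0).any():
            raise ValueError("max screening concentrations must be positive")
        vals = self.ic50.to_numpy(dtype=float)
        if np.nanmin(vals) <= 0:
            raise ValueError("IC50 values must be positive")
        if not set(self.ic50.index) == set(self.mutations.index):
            raise ValueError("ic50 and mutation tables must share cell lines")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.ic50.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.ic50.columns)


@dataclass(frozen=True)
class SeparationHit:
    """A gene pair and drug whose mutant/wild-type groups fall into opposite
    response classes with no overlap."""

    gene_pair: tuple[str, str]
    drug: str
    direction: str  # mutant_responsive | wildtype_responsive
    n_mutant: int
    n_wildtype: int


def classify_response(ic50_value: float, max_conc: float) -> str:
    """Responder iff IC50 < max screening concentration; ties are non-responders."""
    if not (ic50_value > 0 and max_conc > 0):
        raise ValueError("IC50 and max concentration must be positive")
    return RESPONDER if ic50_value < max_conc else NON_RESPONDER


def stratify_by_pair(
    table: DrugScreenTable, gene_a: str, gene_b: str
) -> tuple[list[str], list[str]]:
    """Mutant group = lines mutated in either gene; wild-type = the rest."""
    for g in (gene_a, gene_b):
        if g not in table.mutations.columns:
            raise ValueError(f"gene {g!r} absent from mutation table")
    calls = table.mutations[[gene_a, gene_b]].astype(bool)
    mutant_mask = calls.any(axis=1)
    mutant = list(table.mutations.index[mutant_mask])
    wildtype = list(table.mutations.index[~mutant_mask])
    return mutant, wildtype


def find_separating_drugs(
    table: DrugScreenTable, pairs: list[tuple[str, str]]
) -> list[SeparationHit]:
    """Search every (gene pair, drug) combination for perfect separation.

    Lines with a missing IC50 for a drug are excluded from that drug's
    classification (logged).  Pairs with an empty mutant or wild-type group
    are skipped with a warning.
    """
    hits: list[SeparationHit] = []
    for gene_a, gene_b in pairs:
        mutant, wildtype = stratify_by_pair(table, gene_a, gene_b)
        if not mutant or not wildtype:
            logger.warning(
                "pair (%s, %s): empty %s group; skipped", gene_a, gene_b,
                "mutant" if not mutant else "wild-type",
            )
            continue
        for drug in table.drugs:
            conc = float(table.max_conc[drug])
            col = table.ic50[drug]
            mut_vals = col.loc[mutant].dropna()
            wt_vals = col.loc[wildtype].dropna()
            n_missing = col.loc[mutant + wildtype].isna().sum()
            if n_missing:
                logger.info("drug %s: %d lines with missing IC50 excluded", drug, n_missing)
            if mut_vals.empty or wt_vals.empty:
                continue
            mut_resp = np.array([classify_response(v, conc) == RESPONDER for v in mut_vals])
            wt_resp = np.array([classify_response(v, conc) == RESPONDER for v in wt_vals])
            if mut_resp.all() and not wt_resp.any():
                direction = "mutant_responsive"
            elif wt_resp.all() and not mut_resp.any():
                direction = "wildtype_responsive"
            else:
                continue
            hits.append(SeparationHit(
                gene_pair=(gene_a, gene_b), drug=drug, direction=direction,
                n_mutant=len(mut_vals), n_wildtype=len(wt_vals),
            ))
    return hits


@dataclass(frozen=True)
class MutationStrata:
    """Sample partition by a gene's mutation status.

    Samples whose only calls for the gene are silent are excluded from both
    groups: they have no non-silent mutation (not mutant) yet do carry a
    mutation (not mutation-free wild-type).
    """

    mutant: frozenset[str]
    wildtype: frozenset[str]
    excluded: frozenset[str]


def stratify_by_mutation(
    calls: pd.DataFrame, gene: str, samples=None
) -> MutationStrata:
    """Stratify samples by any non-silent mutation in ``gene``.

    ``calls`` is a tidy table with columns ``sample, gene, variant_classification``
    (one row per mutation event).  ``samples`` optionally fixes the sample
    universe; by default it is every sample appearing in ``calls``.
    """
    required = {"sample", "gene", "variant_classification"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    universe = set(samples) if samples is not None else set(calls["sample"])
    gene_calls = calls[calls["gene"] == gene]

    def is_silent(vc: str) -> bool:
        if vc in SILENT_CLASSES:
            return True
        if vc not in KNOWN_NONSILENT:
            logger.warning("unknown variant classification %r treated as non-silent", vc)
        return False

    with_any: set[str] = set(gene_calls["sample"]) & universe
    with_nonsilent = {
        s for s, vc in zip(gene_calls["sample"], gene_calls["variant_classification"])
        if s in universe and not is_silent(vc)
    }
    mutant = with_nonsilent
    excluded = with_any - with_nonsilent  # only silent calls
    wildtype = universe - with_any
    return MutationStrata(
        mutant=frozenset(mutant),
        wildtype=frozenset(wildtype),
        excluded=frozenset(excluded),
    )


# ---------------------------------------------------------------------------
# table I/O (TSV, one file each for IC50s, max concentrations, mutations)


def read_drug_screen(ic50_path, max_conc_path, mutations_path) -> DrugScreenTable:
    ic50 = pd.read_csv(ic50_path, sep="\t", index_col=0, comment="#")
    max_conc = pd.read_csv(max_conc_path, sep="\t", index_col=0, comment="#").iloc[:, 0]
    mutations = pd.read_csv(mutations_path, sep="\t", index_col=0, comment="#").astype(int)
    return DrugScreenTable(ic50=ic50, max_conc=max_conc, mutations=mutations)


def write_drug_screen(table: DrugScreenTable, ic50_path, max_conc_path, mutations_path) -> None:
    table.ic50.to_csv(ic50_path, sep="\t", index_label="cell_line")
    table.max_conc.rename("max_conc").to_csv(max_conc_path, sep="\t", index_label="drug")
    table.mutations.to_csv(mutations_path, sep="\t", index_label="cell_line")


def all_pairs(genes) -> list[tuple[str, str]]:
    """All unordered gene pairs, for exhaustive screens on small panels."""
    return list(combinations(sorted(genes), 2))
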