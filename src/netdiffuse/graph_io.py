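"""Readers and writers for the network, pathway, seed, and table formats.

The central container is :class:`PathwayNetwork`, an undirected simple graph
of gene symbols whose edges may carry pathway-name annotations (as produced
by Pathway Commons style extended-SIF exports of curated pathway databases).
All computation downstream treats every interaction as an undirected edge of
weight 1; interaction-type strings are preserved for round-tripping but never
interpreted.

Gene-symbol matching is exact and case-sensitive throughout: no alias
resolution is attempted, and seed symbols absent from the network are dropped
with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: canonical extended-SIF header columns (pathway column optional in files)
SIF_COLUMNS = ("PARTICIPANT_A", "INTERACTION_TYPE", "PARTICIPANT_B", "PATHWAY_NAMES")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered representation of an edge."""
    return (a, b) if a <= b else (b, a)


class PathwayNetwork:
    """Undirected simple graph with unique gene labels and per-edge pathway sets.

    Wraps a :class:`networkx.Graph`; each edge carries a ``pathways`` set
    (possibly empty) and an optional ``interaction`` string.  Node labels are
    the gene symbols themselves, so the graph is uniquely labeled — a property
    the maximal-common-subgraph distance relies on.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        for _, _, data in self.graph.edges(data=True):
            data.setdefault("pathways", set())

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, Iterable[str]]],
        nodes: Iterable[str] = (),
    ) -> "PathwayNetwork":
        """Build from ``(a, b, pathway_names)`` triples plus optional extra nodes."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b, pws in edges:
            if a == b:
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["pathways"].update(pws)
            else:
                g.add_edge(a, b, pathways=set(pws), interaction=None)
        return cls(g)

    # -- basic views -------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def node_list(self) -> list[str]:
        """Deterministic (sorted) node ordering used for all matrix work."""
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_edge_key(a, b) for a, b in self.graph.edges}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edge_pathways(self) -> dict[tuple[str, str], set[str]]:
        return {
            _edge_key(a, b): set(data.get("pathways", ()))
            for a, b, data in self.graph.edges(data=True)
        }

    @property
    def pathway_members(self) -> dict[str, set[str]]:
        """Pathway name -> nodes incident to at least one edge annotated with it."""
        members: dict[str, set[str]] = {}
        for a, b, data in self.graph.edges(data=True):
            for p in data.get("pathways", ()):
                members.setdefault(p, set()).update((a, b))
        return members

    def degree_sequence(self) -> list[int]:
        """Degree multiset, sorted; conserved by every randomization op."""
        return sorted(d for _, d in self.graph.degree())

    def copy(self) -> "PathwayNetwork":
        return PathwayNetwork(self.graph.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.edge_pathways == other.edge_pathways
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PathwayNetwork({self.n_nodes()} nodes, {self.n_edges()} edges, "
            f"{len(self.pathway_members)} pathways)"
        )


@dataclass(frozen=True)
class SeedSet:
    """A requested gene list split into symbols mapped to the network and dropped."""

    requested: tuple[str, ...]
    mapped: frozenset[str]
    dropped: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_genes(cls, genes: Iterable[str], network: PathwayNetwork) -> "SeedSet":
        requested = tuple(dict.fromkeys(genes))  # de-dup, order-preserving
        present = network.nodes
        mapped = frozenset(g for g in requested if g in present)
        dropped = frozenset(requested) - mapped
        for g in sorted(dropped):
            logger.warning("seed gene %r not found in network; dropped", g)
        return cls(requested=requested, mapped=mapped, dropped=dropped)

    def __len__(self) -> int:
        return len(self.mapped)


# ---------------------------------------------------------------------------
# readers


def read_extended_sif(path) -> PathwayNetwork:
    """Read a tab-delimited extended-SIF interaction file.

    Columns: participant A, interaction type, participant B, and optionally a
    ';'-separated pathway-names column.  A header line is auto-detected by the
    literal string ``PARTICIPANT_A``.  Duplicate and reversed rows are merged
    with pathway-set union; self-loop rows are skipped with a warning.
    """
    g = nx.Graph()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip() == "PARTICIPANT_A":
                continue  # header
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least 3 tab-delimited "
                    f"columns (PARTICIPANT_A, INTERACTION_TYPE, PARTICIPANT_B), "
                    f"got {len(fields)}"
                )
            a, itype, b = (f.strip() for f in fields[:3])
            if not a or not b:
                raise FormatError(
                    f"{path}: line {lineno}: empty participant column"
                )
            pathways = set()
            if len(fields) >= 4 and fields[3].strip():
                pathways = {p.strip() for p in fields[3].split(";") if p.strip()}
            n_rows += 1
            if a == b:
                logger.warning("%s: line %d: self-loop %s-%s skipped", path, lineno, a, b)
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["pathways"].update(pathways)
            else:
                g.add_edge(a, b, pathways=pathways, interaction=itype or None)
    if n_rows == 0:
        raise FormatError(f"{path}: no interaction rows found")
    return PathwayNetwork(g)


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file: ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >=3 fields "
                    f"(name, description, gene...), got {len(fields)}"
                )
            name = fields[0].strip()
            genes = {g.strip() for g in fields[2:] if g.strip()}
            sets[name] = genes
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return sets


def read_seed_list(path, network: PathwayNetwork) -> SeedSet:
    """Read a one-symbol-per-line seed file and map it onto ``network``.

    Blank lines and lines starting with ``#`` are ignored.  Raises if no
    symbol maps into the network.
    """
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            genes.append(sym)
    seeds = SeedSet.from_genes(genes, network)
    if not seeds.mapped:
        raise ValueError(f"{path}: no seed genes found in network")
    return seeds


# ---------------------------------------------------------------------------
# writers


def write_network_sif(network: PathwayNetwork, path) -> None:
    """Write a PathwayNetwork as extended SIF (with header)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SIF_COLUMNS) + "\n")
        for a, b in sorted(network.edges):
            data = network.graph.edges[a, b]
            itype = data.get("interaction") or "interacts-with"
            pws = ";".join(sorted(data.get("pathways", ())))
            fh.write(f"{a}\t{itype}\t{b}\t{pws}\n")


def write_subnetwork(subnetwork, sif_path, node_table_path) -> None:
    """Write a subnetwork's induced edges as SIF and its per-node statistics as TSV.

    The node table has columns ``gene, is_seed, f, p, q``; seed rows carry
    ``f = 1`` and empty p/q (seeds are clamped, not tested).
    """
    write_network_sif(subnetwork.as_network(), sif_path)
    table = subnetwork.table
    with open(node_table_path, "w") as fh:
        fh.write("gene\tis_seed\tf\tp\tq\n")
        for gene in sorted(subnetwork.nodes):
            if gene in subnetwork.seeds.mapped:
                fh.write(f"{gene}\t1\t1.0\t\t\n")
            else:
                row = table.frame.loc[gene]
                fh.write(
                    f"{gene}\t0\t{row['f']:.6g}\t{row['p']:.6g}\t{row['q']:.6g}\n"
                )


def write_distance_matrix(matrix, path) -> None:
    """Write a DistanceMatrix as TSV with row/column names."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(matrix.names) + "\n")
        for i, name in enumerate(matrix.names):
            row = "\t".join(f"{v:.6g}" for v in matrix.values[i])
            fh.write(f"{name}\t{row}\n")
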