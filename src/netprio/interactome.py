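"""Interactome data model: file I/O, seed scoring and basic network statistics.

The interactome is represented as a :class:`networkx.Graph` whose nodes are
opaque string identifiers (gene or protein symbols, assumed pre-mapped) and
whose edges are undirected physical interactions.  Self-loops and duplicate
edges are not part of the model: readers drop them on input.

Phenotype associations are held in :class:`PhenotypeSeeds`: the set of genes
with a known association to a disease ("seeds"), which receive the maximum
relevance score (1.0 by default) while every other network node receives the
minimum (0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: Node-level relevance scores; defined for every node of the associated graph.
NodeScores = dict


class NetworkParseError(ValueError):
    """Raised when a network or association file cannot be parsed."""


class NoSeedError(ValueError):
    """Raised when no seed of a phenotype maps onto the network."""


@dataclass
class PhenotypeSeeds:
    """Seed set of one pathophenotype with its initial scoring convention.

    Parameters
    ----------
    phenotype_id:
        Label of the phenotype (e.g. an OMIM keyword such as ``"alzheimer"``).
    seeds:
        Genes associated with the phenotype.  May contain genes absent from a
        given interactome; those are dropped only at scoring time.
    seed_score, nonseed_score:
        Initial relevance scores.  Seeds start at the network maximum,
        everything else at the minimum; ``seed_score > nonseed_score > 0``.
    """

    phenotype_id: str
    seeds: set = field(default_factory=set)
    seed_score: float = 1.0
    nonseed_score: float = 0.01

    def __post_init__(self) -> None:
        self.seeds = set(self.seeds)
        if not self.seed_score > self.nonseed_score > 0:
            raise ValueError("require seed_score > nonseed_score > 0")

    def mapped_seeds(self, net: nx.Graph) -> set:
        """Seeds that are present as nodes of *net*."""
        return self.seeds & set(net.nodes)


def _parse_edge(line: str, lineno: int, fmt: str) -> tuple:
    parts = line.split()
    if fmt == "edgelist":
        if len(parts) < 2:
            raise NetworkParseError(f"line {lineno}: expected two columns, got {len(parts)}")
        return parts[0], parts[1]
    if fmt == "sif":
        if len(parts) < 3:
            raise NetworkParseError(
                f"line {lineno}: expected three columns (node relation node), got {len(parts)}"
            )
        return parts[0], parts[2]
    raise ValueError(f"unknown format {fmt!r}; use 'edgelist' or 'sif'")


def read_network(path, format: str = "edgelist") -> nx.Graph:
    """Read an undirected interactome from an edge-list or SIF file.

    Duplicate lines (including reversed duplicates) are collapsed; self-loops
    are dropped with a logged warning.  Lines starting with ``#`` are skipped.

    Raises
    ------
    NetworkParseError
        On a malformed line (the message names the line number) or an empty
        file.
    """
    net = nx.Graph()
    n_loops = 0
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            u, v = _parse_edge(line, lineno, format)
            if u == v:
                n_loops += 1
                net.add_node(u)
                continue
            net.add_edge(u, v)
    if n_lines == 0:
        raise NetworkParseError(f"{path}: empty network file")
    if n_loops:
        logger.warning("%s: dropped %d self-loop line(s)", path, n_loops)
    return net


def write_network(net: nx.Graph, path) -> None:
    """Write *net* as a two-column edge list (deterministic sorted order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{u}\t{v}\n")


def read_associations(path) -> list:
    """Read a two-column (phenotype_id, gene_id) association table.

    Returns one :class:`PhenotypeSeeds` per distinct phenotype, in order of
    first appearance.  Genes absent from any particular interactome are kept
    here and only dropped at scoring time.
    """
    by_phenotype: dict = {}
    order: list = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise NetworkParseError(f"line {lineno}: expected phenotype_id and gene_id")
            phen, gene = parts[0], parts[1]
            if phen not in by_phenotype:
                by_phenotype[phen] = set()
                order.append(phen)
            by_phenotype[phen].add(gene)
    return [PhenotypeSeeds(phenotype_id=p, seeds=by_phenotype[p]) for p in order]


def filter_phenotypes(
    assocs: Iterable[PhenotypeSeeds], net: nx.Graph, min_seeds: int = 25
) -> list:
    """Keep phenotypes with at least *min_seeds* seeds mapped onto *net*.

    Mirrors the inclusion rule that a disorder enters the analysis only when
    at least 25 associated genes are present.  Order is preserved.
    """
    if min_seeds < 1:
        raise ValueError("min_seeds must be >= 1")
    return [ph for ph in assocs if len(ph.mapped_seeds(net)) >= min_seeds]


def assign_scores(net: nx.Graph, ph: PhenotypeSeeds) -> NodeScores:
    """Initial relevance scores: seed_score for mapped seeds, nonseed_score else.

    Raises :class:`NoSeedError` if no seed maps onto the network.  Seeds not in
    the network are dropped (count logged).
    """
    mapped = ph.mapped_seeds(net)
    if not mapped:
        raise NoSeedError(f"phenotype {ph.phenotype_id!r}: no seed maps onto the network")
    n_dropped = len(ph.seeds) - len(mapped)
    if n_dropped:
        logger.info(
            "phenotype %s: %d seed(s) not in network, dropped", ph.phenotype_id, n_dropped
        )
    return {
        u: (ph.seed_score if u in mapped else ph.nonseed_score) for u in net.nodes
    }


def network_stats(net: nx.Graph, ph: PhenotypeSeeds | None = None) -> dict:
    """Summary statistics of the network and (optionally) one seed set.

    Returns node/edge counts and, when a phenotype is given, the seed count,
    seed fraction, the number and fraction of edges touching at least one seed,
    and the degree of each mapped seed.
    """
    stats = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_components": nx.number_connected_components(net) if net.number_of_nodes() else 0,
    }
    if ph is not None:
        mapped = ph.mapped_seeds(net)
        seed_edges = sum(1 for u, v in net.edges if u in mapped or v in mapped)
        stats.update(
            {
                "n_seeds": len(mapped),
                "seed_fraction": len(mapped) / stats["n_nodes"] if stats["n_nodes"] else 0.0,
                "n_seed_edges": seed_edges,
                "seed_edge_fraction": seed_edges / stats["n_edges"] if stats["n_edges"] else 0.0,
                "seed_degrees": {u: net.degree(u) for u in sorted(mapped)},
            }
        )
    return stats


def write_scores(scores: Mapping, path) -> None:
    """Write scores as a two-column TSV sorted by descending score, then id."""
    with open(path, "w", encoding="utf-8") as fh:
        for node, s in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{node}\t{s:.6g}\n")


def read_scores(path) -> NodeScores:
    """Read a two-column (node, score) TSV written by :func:`write_scores`."""
    scores: NodeScores = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            node, s = line.split("\t")
            scores[node] = float(s)
    return scores
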