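"""Perturbation ensembles N(p, k): edge rewiring, edge deletion, seed swapping.

A perturbation ensemble is the indexed family N(p, k) of networks (or seed
sets) where p is the perturbation level in percent and k the replicate index.
Each instance is fully determined by (kind, p, k, rng_seed), so ensembles are
reproducible and can be generated lazily.

Rewiring removes whole edges and draws entirely new node pairs (both
endpoints free); it deliberately does NOT preserve degrees — the
degree-preserving shuffle is a separate null model used only inside NetZcore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import networkx as nx
import numpy as np

from .interactome import PhenotypeSeeds


class PerturbationInfeasible(ValueError):
    """Raised when the requested perturbation cannot be realized."""


KINDS = ("rewire", "delete", "seed_swap")


@dataclass(frozen=True)
class PerturbationSpec:
    """Identity of one ensemble instance N(p, k)."""

    kind: str
    level: float
    replicate: int
    rng_seed: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not 0 <= self.level <= 100:
            raise ValueError("level must be a percentage in [0, 100]")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")


def _round_half_away(x: float) -> int:
    """round-half-away-from-zero; fixed so instance sizes are deterministic."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _n_perturbed(p: float, total: int) -> int:
    m = _round_half_away(p / 100.0 * total)
    if m > total:
        raise PerturbationInfeasible(f"cannot perturb {m} of {total} items")
    return m


def rewire_edges(net: nx.Graph, p: float, rng_seed: int) -> nx.Graph:
    """Replace round(p% of |E|) edges by uniformly drawn new node pairs.

    Exactly m original edges are removed and m new edges added between node
    pairs that were not connected in the original network (no self-loops, no
    duplicates, no re-insertion of a removed edge), so the node set and the
    edge count are preserved and exactly |E| - m original edges survive.
    """
    rng = np.random.default_rng(rng_seed)
    m = _n_perturbed(p, net.number_of_edges())
    out = net.copy()
    if m == 0:
        return out
    nodes = sorted(net.nodes)
    n = len(nodes)
    max_edges = n * (n - 1) // 2
    if max_edges - net.number_of_edges() < m:
        raise PerturbationInfeasible("graph too dense to place new edges")
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    removed_idx = rng.choice(len(edges), size=m, replace=False)
    for i in removed_idx:
        out.remove_edge(*edges[i])
    added = 0
    attempts = 0
    while added < m and attempts < 200 * m + 1000:
        attempts += 1
        u, v = nodes[rng.integers(n)], nodes[rng.integers(n)]
        if u == v or net.has_edge(u, v) or out.has_edge(u, v):
            continue
        out.add_edge(u, v)
        added += 1
    if added < m:
        # rejection sampling stalls only on near-complete graphs; enumerate
        free = sorted(
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if not net.has_edge(nodes[i], nodes[j]) and not out.has_edge(nodes[i], nodes[j])
        )
        for i in rng.choice(len(free), size=m - added, replace=False):
            out.add_edge(*free[i])
    return out


def delete_edges(net: nx.Graph, p: float, rng_seed: int) -> nx.Graph:
    """Remove round(p% of |E|) edges uniformly; nodes stay even if isolated."""
    rng = np.random.default_rng(rng_seed)
    m = _n_perturbed(p, net.number_of_edges())
    out = net.copy()
    if m == 0:
        return out
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    removed_idx = rng.choice(len(edges), size=m, replace=False)
    for i in removed_idx:
        out.remove_edge(*edges[i])
    return out


def swap_seeds(ph: PhenotypeSeeds, net: nx.Graph, p: float, rng_seed: int) -> PhenotypeSeeds:
    """Replace round(p% of |seeds|) seeds by uniformly drawn non-seed nodes.

    Models mis-annotated disease-gene associations; the seed-set size is
    preserved.
    """
    rng = np.random.default_rng(rng_seed)
    seeds = sorted(ph.mapped_seeds(net))
    m = _n_perturbed(p, len(seeds))
    if m == 0:
        return PhenotypeSeeds(ph.phenotype_id, set(seeds), ph.seed_score, ph.nonseed_score)
    non_seeds = sorted(set(net.nodes) - set(seeds))
    if len(non_seeds) < m:
        raise PerturbationInfeasible(
            f"need {m} replacement non-seeds but only {len(non_seeds)} exist"
        )
    dropped = {seeds[i] for i in rng.choice(len(seeds), size=m, replace=False)}
    replacements = {non_seeds[i] for i in rng.choice(len(non_seeds), size=m, replace=False)}
    new_seeds = (set(seeds) - dropped) | replacements
    return PhenotypeSeeds(ph.phenotype_id, new_seeds, ph.seed_score, ph.nonseed_score)


def derive_seed(base_seed: int, kind: str, p: float, k: int) -> int:
    """Deterministic per-instance RNG seed for N(p, k) (stable across runs)."""
    key = (base_seed, KINDS.index(kind), int(round(p * 10)), k)
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


@dataclass
class PerturbedEnsemble:
    """Lazy family of perturbed instances with a fixed enumeration order."""

    source: object  # Interactome (networkx Graph) or PhenotypeSeeds
    kind: str
    levels: tuple
    n: int
    base_seed: int
    net: nx.Graph | None = None  # node universe, needed for seed_swap

    def specs(self) -> list:
        return [
            PerturbationSpec(self.kind, p, k, derive_seed(self.base_seed, self.kind, p, k))
            for p in self.levels
            for k in range(1, self.n + 1)
        ]

    def instance(self, spec: PerturbationSpec):
        if self.kind == "rewire":
            return rewire_edges(self.source, spec.level, spec.rng_seed)
        if self.kind == "delete":
            return delete_edges(self.source, spec.level, spec.rng_seed)
        return swap_seeds(self.source, self.net, spec.level, spec.rng_seed)

    def __iter__(self) -> Iterator:
        for spec in self.specs():
            yield spec, self.instance(spec)


def make_ensemble(
    source,
    kind: str,
    levels,
    n: int,
    base_seed: int,
    net: nx.Graph | None = None,
) -> PerturbedEnsemble:
    """Build the ensemble N(p, k) for p in *levels*, k = 1..n.

    Instances are generated lazily; each has an RNG seed derived
    deterministically from (base_seed, kind, p, k) so distinct instances use
    independent streams and the whole ensemble is reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    levels = tuple(levels)
    if any(not 0 <= p <= 100 for p in levels):
        raise ValueError("levels must lie in [0, 100]")
    if kind not in KINDS:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    if kind == "seed_swap":
        if not isinstance(source, PhenotypeSeeds):
            raise TypeError("seed_swap ensembles take a PhenotypeSeeds source")
        if net is None:
            raise ValueError("seed_swap ensembles need the network (node universe)")
    elif not isinstance(source, nx.Graph):
        raise TypeError(f"{kind} ensembles take a networkx Graph source")
    return PerturbedEnsemble(source=source, kind=kind, levels=levels, n=n, base_seed=base_seed, net=net)
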