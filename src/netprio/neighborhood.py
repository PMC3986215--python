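"""Seed-neighborhood coverage of an independent disease-related gene set.

Measures how much of an independently curated disease gene list lies in the
direct neighborhood of the phenotype's seeds, and how that coverage behaves
when the interactome is perturbed.  Under random edge deletion the
neighborhood shrinks, but genes genuinely wired to several seeds tend to stay
attached — so the coverage *ratio* holds up (or rises) while the raw counts
fall.  A size-matched random-gene-set baseline calibrates the observed ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .perturb import make_ensemble


@dataclass
class NeighborhoodCoverage:
    """Coverage of a related-gene set inside the seed neighborhood."""

    n_neighbors: int
    n_related_in_neighborhood: int
    ratio: float


def seed_neighborhood(net: nx.Graph, seeds) -> set:
    """Union of the direct neighbors of the seeds, excluding seeds themselves."""
    seeds = set(seeds) & set(net.nodes)
    out: set = set()
    for s in seeds:
        out.update(net.neighbors(s))
    return out - seeds


def coverage(net: nx.Graph, seeds, related) -> NeighborhoodCoverage:
    """How many related genes sit in the seed neighborhood.

    Related genes that are themselves seeds are excluded (they are known
    associations, not discoveries).
    """
    nbrs = seed_neighborhood(net, seeds)
    related = set(related) - set(seeds)
    hit = len(nbrs & related)
    return NeighborhoodCoverage(
        n_neighbors=len(nbrs),
        n_related_in_neighborhood=hit,
        ratio=hit / len(nbrs) if nbrs else 0.0,
    )


def coverage_under_perturbation(
    net: nx.Graph, seeds, related, kind: str, levels, n: int, base_seed: int
) -> list:
    """Mean coverage per perturbation level, with level 0 (the original
    network) prepended when absent.

    Returns a list of dicts (kind, level, mean_neighbors, mean_related,
    mean_ratio) ordered by level.
    """
    levels = list(levels)
    if 0 not in levels and 0.0 not in levels:
        levels = [0] + levels
    ensemble = make_ensemble(net, kind, levels, n, base_seed)
    acc: dict = {p: [] for p in levels}
    for spec, instance in ensemble:
        acc[spec.level].append(coverage(instance, seeds, related))
    out = []
    for p in levels:
        covs = acc[p]
        out.append(
            {
                "kind": kind,
                "level": p,
                "mean_neighbors": float(np.mean([c.n_neighbors for c in covs])),
                "mean_related": float(np.mean([c.n_related_in_neighborhood for c in covs])),
                "mean_ratio": float(np.mean([c.ratio for c in covs])),
            }
        )
    return out


def random_baseline(
    net: nx.Graph,
    seeds,
    set_size: int,
    n_sets: int = 100,
    rng_seed: int = 0,
    observed_ratio: float | None = None,
) -> dict:
    """Coverage-ratio distribution of random non-seed gene sets of a given size.

    Draws ``n_sets`` uniform sets from the non-seed nodes, computes each set's
    coverage ratio in the seed neighborhood, and reports mean, sd, the ratios,
    and (when ``observed_ratio`` is given) the empirical percentile of the
    observed value within the random distribution.
    """
    seeds = set(seeds)
    pool = sorted(set(net.nodes) - seeds)
    if set_size > len(pool):
        raise ValueError(f"set_size {set_size} exceeds {len(pool)} available non-seeds")
    rng = np.random.default_rng(rng_seed)
    ratios = []
    for _ in range(n_sets):
        random_set = {pool[i] for i in rng.choice(len(pool), size=set_size, replace=False)}
        ratios.append(coverage(net, seeds, random_set).ratio)
    ratios_arr = np.asarray(ratios)
    out = {
        "mean": float(ratios_arr.mean()),
        "sd": float(ratios_arr.std(ddof=1)) if n_sets > 1 else 0.0,
        "ratios": ratios,
    }
    if observed_ratio is not None:
        out["percentile"] = float(100.0 * np.mean(ratios_arr <= observed_ratio))
    return out
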