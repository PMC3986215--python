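"""GO-term enrichment, functional diversity, and semantic similarity.

Enrichment of a query gene set against a background is tested per term with
the hypergeometric upper tail and corrected across terms by
Benjamini-Hochberg; a term is significant at adjusted p <= 0.05.  "Seed GO
terms" of a phenotype are the terms enriched among its seeds, and the
functional-diversity ratio is their count divided by the seed count.

For redundancy filtering, term-term semantic similarity follows Wang's
DAG-based measure: each ancestor *a* of a term *t* carries an S-value
(max over DAG paths of the product of per-relation weights, is_a 0.8 /
part_of 0.6), and

    sim(t1, t2) = sum_{a in anc(t1) ∩ anc(t2)} (S_t1(a) + S_t2(a))
                  / (SV(t1) + SV(t2)),

with SV(t) the sum of t's S-values over all its ancestors (including t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class AnnotationSet:
    """Term -> gene-set annotation corpus with an optional term DAG.

    The DAG, when present, is a directed graph with child -> parent edges
    annotated by ``relation`` (is_a / part_of); each term optionally carries a
    namespace tag.
    """

    term_genes: dict
    dag: nx.DiGraph | None = None
    namespaces: dict = field(default_factory=dict)

    def genes(self) -> set:
        out: set = set()
        for gs in self.term_genes.values():
            out |= set(gs)
        return out


def read_gmt(path) -> AnnotationSet:
    """Read a GMT file (term, description, gene, gene, ...) into an AnnotationSet."""
    term_genes: dict = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line needs term, description and >=1 gene: {line!r}")
            term_genes[parts[0]] = set(g for g in parts[2:] if g)
    return AnnotationSet(term_genes=term_genes)


def read_dag(path) -> nx.DiGraph:
    """Read a 3-column (child, parent, relation) term DAG file."""
    dag = nx.DiGraph()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"DAG line needs child, parent, relation: {line!r}")
            dag.add_edge(parts[0], parts[1], relation=parts[2])
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("term graph contains a cycle")
    return dag


@dataclass
class EnrichmentResult:
    """One term's hypergeometric test: k of n query genes hit a term that
    annotates K of N background genes."""

    term: str
    k: int
    n: int
    K: int
    N: int
    p: float
    p_adj: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_adj <= 0.05


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Delegates to scipy's survival function, which works on log-gamma terms
    and is stable far into the tail.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if not 0 <= k <= min(n, K):
        raise ValueError("require 0 <= k <= min(n, K)")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query, annotations: AnnotationSet, background, alpha: float = 0.05) -> list:
    """Hypergeometric enrichment of *query* against *background*, BH-adjusted.

    Only terms with at least one query gene are tested; counts are restricted
    to background genes.  Results are sorted by adjusted then raw p-value.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if not query:
        return []
    N = len(background)
    results = []
    for term in sorted(annotations.term_genes):
        genes = set(annotations.term_genes[term]) & background
        k = len(genes & query)
        if k == 0:
            continue
        K = len(genes)
        p = hypergeom_upper_tail(N=N, K=K, n=len(query), k=k)
        results.append(EnrichmentResult(term=term, k=k, n=len(query), K=K, N=N, p=p))
    if results:
        _, p_adj, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, pa in zip(results, p_adj):
            r.p_adj = float(pa)
    results.sort(key=lambda r: (r.p_adj, r.p, r.term))
    _ = alpha  # significance threshold is read off via r.p_adj <= alpha
    return results


def significant_terms(results, alpha: float = 0.05) -> set:
    return {r.term for r in results if r.p_adj <= alpha}


def seed_go_terms(ph, annotations: AnnotationSet, background, alpha: float = 0.05) -> set:
    """Terms significantly enriched among a phenotype's seeds ("seed GO terms")."""
    seeds = set(ph.seeds) & set(background)
    if not ph.seeds:
        raise ValueError("phenotype has no seeds")
    return significant_terms(enrich(seeds, annotations, background, alpha), alpha)


def go_per_seed_ratio(ph, seed_terms) -> float:
    """Functional diversity: number of seed GO terms per seed gene."""
    if not ph.seeds:
        raise ValueError("phenotype has no seeds")
    return len(seed_terms) / len(ph.seeds)


def _svalues(term: str, dag: nx.DiGraph, weights: dict) -> dict:
    """Wang S-values of *term* for itself and all its ancestors."""
    if term not in dag:
        raise KeyError(f"term {term!r} not in DAG")
    s = {term: 1.0}
    # Relax upward in topological order restricted to ancestors of term.
    ancestors = nx.descendants(dag, term) | {term}  # child->parent edges point up
    sub = dag.subgraph(ancestors)
    for node in nx.topological_sort(sub):
        if node not in s:
            continue
        for _, parent, data in sub.out_edges(node, data=True):
            w = weights.get(data.get("relation", "is_a"), 0.0)
            cand = w * s[node]
            if cand > s.get(parent, 0.0):
                s[parent] = cand
    return s


def wang_similarity(t1: str, t2: str, dag: nx.DiGraph, weights: dict | None = None) -> float:
    """Wang semantic similarity between two terms of the DAG, in [0, 1]."""
    weights = DEFAULT_RELATION_WEIGHTS if weights is None else weights
    s1 = _svalues(t1, dag, weights)
    s2 = _svalues(t2, dag, weights)
    common = set(s1) & set(s2)
    denom = sum(s1.values()) + sum(s2.values())
    if denom == 0:
        return 0.0
    return sum(s1[a] + s2[a] for a in common) / denom


def _depth(term: str, dag: nx.DiGraph) -> int:
    """Distance from the namespace root (a term with no parents) down to *term*.

    With child->parent edges this is the shortest path length from the term up
    to a reachable root (minimum over roots when the DAG has several).
    """
    depths = [
        nx.shortest_path_length(dag, term, node)
        for node in nx.descendants(dag, term) | {term}
        if dag.out_degree(node) == 0  # a root
    ]
    return min(depths) if depths else 0


def remove_redundant_terms(
    terms, dag: nx.DiGraph, threshold: float = 0.9, weights: dict | None = None, rng_seed: int = 0
) -> set:
    """Collapse semantically redundant terms.

    Repeatedly finds a pair with similarity >= threshold and discards the
    member closer to the ontology root (smaller depth); depth ties are broken
    by a fixed-seed random draw.  The result contains no pair at or above the
    threshold.
    """
    kept = sorted(set(terms))
    for t in kept:
        if t not in dag:
            raise KeyError(f"term {t!r} not in DAG")
    rng = np.random.default_rng(rng_seed)
    sim = {}
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            sim[(a, b)] = wang_similarity(a, b, dag, weights)
    depth = {t: _depth(t, dag) for t in kept}
    alive = set(kept)
    changed = True
    while changed:
        changed = False
        for a, b in sorted(sim):
            if a not in alive or b not in alive or sim[(a, b)] < threshold:
                continue
            if depth[a] < depth[b]:
                drop = a
            elif depth[b] < depth[a]:
                drop = b
            else:
                drop = a if rng.random() < 0.5 else b
            alive.discard(drop)
            changed = True
    return alive


def jaccard_overlap(term_sets: dict) -> pd.DataFrame:
    """Pairwise Jaccard index of per-phenotype term sets (symmetric matrix).

    J(A, B) = |A ∩ B| / |A ∪ B|; defined as 0 when both sets are empty, so the
    diagonal is 1 exactly where the set is non-empty.
    """
    names = sorted(term_sets)
    if len(names) < 2:
        raise ValueError("need at least two phenotypes")
    mat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            A, B = set(term_sets[a]), set(term_sets[b])
            union = A | B
            mat[i, j] = len(A & B) / len(union) if union else 0.0
    return pd.DataFrame(mat, index=names, columns=names)


def enrichment_table(results) -> pd.DataFrame:
    """Enrichment results as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["term", "k", "n", "K", "N", "p", "p_adj", "significant"],
    )
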