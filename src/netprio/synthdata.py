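"""Synthetic interactomes, phenotypes, annotations and related-gene sets.

The generator emulates the statistical structure the robustness analysis
assumes about real data: a sparse, heavy-tailed interactome in which each
phenotype's seeds are a small fraction of all nodes (0.1-0.9%), seed pairs of
"tolerant-like" phenotypes are redundantly interconnected through multiple
short (<= 2 hop) paths while "non-tolerant-like" phenotypes hang together by
single paths, and seed sets differ in how many distinct enrichable functions
(annotation terms) cover them.

Two frozen presets, :data:`TOLERANT_LIKE` and :data:`NON_TOLERANT_LIKE`,
encode the two scenario classes at desk scale so the full pipeline (planting
-> prioritization -> perturbation sweep -> tolerance classification) can be
exercised end to end with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .enrichment import AnnotationSet
from .interactome import PhenotypeSeeds

ROOT_TERM = "T:root"


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    ``module_cohesion`` is the probability that a seed pair receives planted
    connectivity beyond the background graph; ``path_redundancy`` is the
    number of edge-disjoint paths of length <= 2 planted per connected pair
    (1 = a single two-hop path through one intermediate; r >= 2 = one direct
    edge plus r-1 two-hop paths).  ``functional_diversity`` is the number of
    distinct enrichable annotation terms covering a phenotype's seed set
    (0 = seeds carry only background annotation).
    """

    n_nodes: int = 4000
    mean_degree: float = 10.0
    degree_model: str = "configuration_powerlaw"
    n_phenotypes: int = 1
    seeds_per_phenotype: int = 30
    module_cohesion: float = 0.5
    path_redundancy: int = 3
    functional_diversity: int = 6
    #: size of a shared pool of non-seed "pathway partner" nodes used as
    #: two-hop intermediates (None = a fresh private intermediate per path).
    #: A shared pool concentrates the module: the same linkers carry many
    #: seed pairs, as pathway co-members do in real interactomes.
    intermediate_pool: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.degree_model not in ("configuration_powerlaw", "erdos_renyi"):
            raise ValueError(f"unknown degree model {self.degree_model!r}")
        if self.n_nodes < 100:
            raise ValueError("n_nodes must be >= 100")
        if not 0 <= self.module_cohesion <= 1:
            raise ValueError("module_cohesion must lie in [0, 1]")
        if self.path_redundancy < 1:
            raise ValueError("path_redundancy must be >= 1")
        if self.functional_diversity < 0:
            raise ValueError("functional_diversity must be >= 0")
        frac = self.seeds_per_phenotype / self.n_nodes
        if not 0.001 <= frac <= 0.009:
            raise ValueError(
                "seeds_per_phenotype / n_nodes must lie in [0.001, 0.009] "
                f"(got {frac:.4f}); seeds are a small fraction of the network"
            )


#: Redundantly wired disease module with diverse seed functions.
TOLERANT_LIKE = ScenarioSpec(
    module_cohesion=0.12, path_redundancy=3, functional_diversity=6
)

#: Seeds held together by single short paths, functionally narrow.
NON_TOLERANT_LIKE = ScenarioSpec(
    module_cohesion=0.07, path_redundancy=1, functional_diversity=2
)

PRESETS = {"tolerant_like": TOLERANT_LIKE, "non_tolerant_like": NON_TOLERANT_LIKE}


def preset(name: str, rng_seed: int = 0) -> ScenarioSpec:
    """A frozen preset with the run's seed substituted in."""
    return replace(PRESETS[name], rng_seed=rng_seed)


def _node_name(i: int) -> str:
    return f"g{i:05d}"


def generate_interactome(spec: ScenarioSpec) -> nx.Graph:
    """Background interactome with the requested size and mean degree.

    ``configuration_powerlaw`` draws expected degrees from a truncated
    power-law (exponent 2.5) rescaled to the requested mean and wires a
    Chung-Lu random graph (no self-loops); ``erdos_renyi`` uses G(n, p) with
    p = mean_degree / (n - 1).
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_nodes
    names = [_node_name(i) for i in range(n)]
    if spec.degree_model == "erdos_renyi":
        p = spec.mean_degree / (n - 1)
        g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    else:
        # Pareto(alpha=1.5) has tail exponent 2.5; rescale to the target mean
        # and cap at sqrt(total weight) so Chung-Lu probabilities stay exact.
        # Capping removes tail mass, so rescale and re-cap until stable.
        w = rng.pareto(1.5, size=n) + 1.0
        for _ in range(8):
            w *= spec.mean_degree / w.mean()
            w = np.minimum(w, np.sqrt(w.sum()))
        g = nx.expected_degree_graph(w.tolist(), seed=int(rng.integers(2**31)), selfloops=False)
    return nx.relabel_nodes(g, dict(enumerate(names)))


@dataclass
class PlantedPhenotype:
    """A planted disease module: augmented network, seeds, planted edges."""

    network: nx.Graph
    seeds: PhenotypeSeeds
    planted_edges: set = field(default_factory=set)


def plant_phenotype(
    net: nx.Graph, spec: ScenarioSpec, phenotype_id: str = "synthetic"
) -> PlantedPhenotype:
    """Plant one phenotype's seed module into a copy of *net*.

    Seeds are drawn uniformly; each seed pair is then "connected" with
    probability ``module_cohesion``.  A connected pair receives
    ``path_redundancy`` edge-disjoint paths of length <= 2: with redundancy 1
    a single two-hop path through a fresh non-seed intermediate (seeds rarely
    all bind each other directly), with redundancy r >= 2 one direct edge
    plus r-1 two-hop paths.

    Planting redirects connectivity instead of inflating it: every planted
    edge incident to a node consumes one of that node's surviving background
    edges (removed) while available, so the module is encoded in where edges
    point, not in the degree sequence — propagation methods reward hubs, and
    a degree artifact would both fake the signal and survive rewiring.  When
    a node's background edges are exhausted (very high cohesion), planting
    continues uncompensated.  Cohesion 0 leaves the network untouched
    (scattered seeds, no signal).
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, 1)))
    nodes = sorted(net.nodes)
    seed_idx = rng.choice(len(nodes), size=spec.seeds_per_phenotype, replace=False)
    seeds = {nodes[i] for i in seed_idx}
    out = net.copy()
    planted: set = set()
    non_seeds = [u for u in nodes if u not in seeds]
    if spec.intermediate_pool is not None:
        pool_idx = rng.choice(len(non_seeds), size=spec.intermediate_pool, replace=False)
        linker_pool = [non_seeds[i] for i in pool_idx]
    else:
        linker_pool = non_seeds
    seed_list = sorted(seeds)

    def consume_stub(node) -> None:
        # retire one surviving background edge of *node*, if any remain
        stubs = [
            nbr
            for nbr in out.neighbors(node)
            if tuple(sorted((node, nbr))) not in planted and net.has_edge(node, nbr)
        ]
        if stubs:
            out.remove_edge(node, sorted(stubs)[rng.integers(len(stubs))])

    def plant_edge(x, y) -> bool:
        if out.has_edge(x, y):
            return False
        out.add_edge(x, y)
        planted.add(tuple(sorted((x, y))))
        return True

    for a_i in range(len(seed_list)):
        for b_i in range(a_i + 1, len(seed_list)):
            if rng.random() >= spec.module_cohesion:
                continue
            u, v = seed_list[a_i], seed_list[b_i]
            n_two_hop = spec.path_redundancy - 1 if spec.path_redundancy >= 2 else 1
            if spec.path_redundancy >= 2 and plant_edge(u, v):
                consume_stub(u)
                consume_stub(v)
            hops = 0
            while hops < n_two_hop:
                w = linker_pool[rng.integers(len(linker_pool))]
                if out.has_edge(u, w) and out.has_edge(v, w):
                    hops += 1  # already a shared intermediate; counts toward redundancy
                    continue
                for x, y in ((u, w), (v, w)):
                    if plant_edge(x, y):
                        consume_stub(x)
                        consume_stub(y)
                hops += 1
    return PlantedPhenotype(
        network=out,
        seeds=PhenotypeSeeds(phenotype_id=phenotype_id, seeds=seeds),
        planted_edges=planted,
    )


def generate_annotations(
    net: nx.Graph,
    phenotypes,
    spec: ScenarioSpec,
    n_background_terms: int = 40,
    background_rate: float = 0.01,
) -> AnnotationSet:
    """Annotation corpus with tunable per-phenotype functional diversity.

    Builds a shallow term DAG (every term ``is_a`` a single root) with
    ``n_background_terms`` terms annotating random genes at
    ``background_rate``, plus ``functional_diversity`` dedicated terms per
    phenotype; each seed is assigned to exactly one of its phenotype's
    dedicated terms (round-robin), and those terms also pick up background
    genes, so recovering them requires a genuine enrichment test.
    With ``functional_diversity`` 0 the seeds carry background annotation
    only (a no-signal control).
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, 2)))
    nodes = sorted(net.nodes)
    dag = nx.DiGraph()
    term_genes: dict = {}
    namespaces: dict = {}
    dag.add_node(ROOT_TERM)
    namespaces[ROOT_TERM] = "biological_process"

    def add_term(name: str, genes: set) -> None:
        dag.add_edge(name, ROOT_TERM, relation="is_a")
        term_genes[name] = genes
        namespaces[name] = "biological_process"

    size = max(1, int(round(background_rate * len(nodes))))
    for t in range(n_background_terms):
        members = {nodes[i] for i in rng.choice(len(nodes), size=size, replace=False)}
        add_term(f"T:bg{t:03d}", members)
    for ph in phenotypes:
        seeds = sorted(ph.seeds)
        if spec.functional_diversity == 0:
            continue
        for d in range(spec.functional_diversity):
            assigned = set(seeds[d :: spec.functional_diversity])
            background = {
                nodes[i] for i in rng.choice(len(nodes), size=size, replace=False)
            } - set(seeds)
            add_term(f"T:{ph.phenotype_id}-{d:02d}", assigned | background)
    return AnnotationSet(term_genes=term_genes, dag=dag, namespaces=namespaces)


def generate_related_set(
    net: nx.Graph,
    ph: PhenotypeSeeds,
    overlap_adjacency: float,
    size: int,
    rng_seed: int = 0,
) -> set:
    """Independent "literature" gene set, disjoint from the seeds.

    Each member is drawn adjacent to at least one seed with probability
    ``overlap_adjacency`` and uniformly from the remaining non-seeds
    otherwise, emulating an independently curated disease gene list whose
    members tend to sit next to the known associations.  Adjacent draws
    sample a uniformly random seed-incident edge (so a gene wired to several
    seeds is proportionally more likely — curated disease genes tend to
    touch the module in more than one place).
    """
    if not 0 <= overlap_adjacency <= 1:
        raise ValueError("overlap_adjacency must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    seeds = set(ph.seeds)
    seed_edge_ends = sorted(
        v for s in sorted(seeds & set(net.nodes)) for v in net.neighbors(s) if v not in seeds
    )
    pool = sorted(set(net.nodes) - seeds)
    if size > len(pool):
        raise ValueError(f"cannot draw {size} related genes from {len(pool)} non-seeds")
    chosen: set = set()
    while len(chosen) < size:
        if seed_edge_ends and rng.random() < overlap_adjacency:
            cand = seed_edge_ends[rng.integers(len(seed_edge_ends))]
        else:
            cand = pool[rng.integers(len(pool))]
        chosen.add(cand)
    return chosen
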