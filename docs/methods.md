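# Methods

This note records the models, conventions and numerical choices behind
`netprio`, in the order data flows through the pipeline.

## Data model and conventions

The interactome is a simple undirected `networkx.Graph` over opaque string
identifiers; self-loops are dropped on input (propagation is defined on
simple graphs) and duplicate/reversed edge lines collapse. Gene↔protein
mapping is assumed done upstream: association files refer to the same
identifier universe as the network. A phenotype's seeds receive the initial
score 1.0 and every other node 0.01; genes absent from the network are kept
in the association object and dropped only at scoring time. Phenotypes
enter an analysis only with ≥ 25 mapped seeds (the inclusion rule for the
curated disease sets this pipeline mirrors). Edge-list files cannot
represent isolated nodes, so a network written and re-read keeps its edge
set but loses degree-0 nodes.

## Prioritization algorithms

All five methods consume `(graph, initial scores)` and return a score for
every node; outputs are rescaled to [0, 1] by dividing by the maximum when
scores are non-negative (zero is a meaningful floor) and by min-max
otherwise (z-scores). Evaluation is rank-based, so the rescaling is
evaluation-neutral. Node order never matters: all internal computation uses
the sorted node list, which makes runs deterministic and (for the four
deterministic methods) invariant under relabeling. NetZcore is deterministic
given its RNG seed, but its null ensemble is generated from the sorted node
list, so relabeling produces a statistically equivalent, not bit-identical,
ranking.

**NetScore.** The kernel entry for source `s` and node `u` is
`σ(s,u) / b^d(s,u)` for graph distance `d ≤ i` (σ = number of distinct
shortest paths, computed exactly by sparse BFS-layer products; `b` = mean
degree), and each row is normalized to sum 1, so one repetition replaces a
node's score by the weighted *mean* of the scores in its ≤ i-hop
neighborhood, itself included. The normalization matters: the raw summed
kernel applied repeatedly converges toward a hub-dominated eigenvector, and
by the default `r = 3` repetitions the seed signal is gone (planted-module
AUC falls from ≈ 0.97 to ≈ 0.53 on the synthetic scenarios). The averaging
form keeps repeated application a contraction toward neighborhood consensus
and leaves the defaults `r = 3`, `i = 2` functional. This kernel is frozen:
tests assert exact agreement with an independent per-source BFS
implementation.

**NetZcore.** At each of 5 iterations the raw score of `u` is the mean of
its neighbors' current scores, standardized against the same computation on
100 degree-preserving randomizations (double edge swaps, 10·|E| attempted
swaps per null, fixed per run from the RNG seed). Nodes with zero null
variance (regular structures; graphs too small to swap) get z = 0. The
z-scores feed the next iteration.

**NetShort.** Edge (u, v) gets length
`1 − (init(u) + init(v)) / (2·max_init) · (1 − ε)` with `ε = 1e−3`, so
seed-touching edges cost nearly nothing and paths through seeds dominate;
a node scores the sum of inverse Dijkstra distances to all seeds. With
uniform initial scores every edge costs exactly ε and the ranking reduces
to the closed form Σ 1/hop-distance, which the tests exploit as an oracle.

**Functional Flow.** Seeds are infinite reservoirs; each iteration (6 by
default) moves `min(1, R(u)/deg(u))` units across every edge from the
higher- to the lower-reservoir endpoint, synchronously. A node's score is
its accumulated inflow; seeds are pinned to the maximum accumulated inflow
so they rank at the top.

**PageRank with priors.** Power iteration of
`p ← (1−β)·W·p + β·q` with `W` the degree-normalized adjacency, `q` the
normalized initial scores, dangling mass redistributed to `q`; `β = 0.3`,
L1 tolerance 1e−6, ≤ 100 iterations (non-convergence is logged, the
iterate returned). The output is a probability distribution and is left on
that scale; a direct linear solve of the fixed point serves as the test
oracle.

## Perturbation ensembles

Three operators model input noise: **rewiring** (remove m = round(p%·|E|)
edges, add m uniformly drawn pairs that were *not* edges of the original
network — so exactly |E|−m originals survive and |E| is preserved),
**deletion** (remove m edges; isolated nodes stay), and **seed swapping**
(replace m = round(p%·|seeds|) seeds with uniform non-seeds). Rewiring is
deliberately not degree-preserving — degree-preserving shuffles are
reserved for NetZcore's null model. Rounding is half-away-from-zero.
An ensemble N(p, k) derives each instance's RNG seed deterministically from
(base seed, kind, p, k), so instances are independent streams and any
instance can be regenerated in isolation. The published protocol uses
levels 10–80% in steps of 10 with 100 replicates; the stated range yields
eight groups, and the unperturbed network serves as the natural ninth
(baseline) level. Desk-scale analyses here use 10–20 replicates; the
acceptance checks use 10.

## Evaluation

Hidden seeds are demoted to the non-seed score, not removed from the graph
("hiding the association", not the protein). For each fold, positives are
the hidden seeds and negatives all nodes that are seeds of neither set;
per-fold AUCs (scikit-learn's `roc_auc_score`, i.e. the normalized
Mann–Whitney statistic; an all-tied ranking scores 0.5) are averaged and a
normal-approximation 95% CI (mean ± 1.96·sd/√n) attached. One fold split is
reused across all instances of an ensemble so per-level variance reflects
the perturbation alone; seed-swap ensembles re-split per instance because
the seed set itself changes.

## Tolerance

`critical_auc = (auc_org + 0.5)/2`. A phenotype is tolerant when the
ensemble-mean AUC at the 50% level stays ≥ the critical AUC under both
rewiring and deletion; equality counts as tolerant (the floor has not been
*crossed*). Classification always uses unrounded values; the report renders
percentages to one decimal with half-up rounding in decimal arithmetic
(binary-float rounding would corrupt midpoints such as 64.15). The
tolerant/non-tolerant group comparison uses the Wilcoxon rank-sum test
(scipy's `mannwhitneyu`, exact null for small tie-free samples), α = 0.05.

## Differential networks

From the per-instance AUCs of a heavy-deletion ensemble (default level
80%), the two best and two worst instances are selected (ties broken by
replicate order) and the differential edge set is
`(E_best1 ∩ E_best2) \ (E_worst1 ∩ E_worst2)`. "Largest component" is
largest by node count, ties broken by lexicographically smallest member;
the report gives the fraction of the phenotype's seeds inside it.

## Enrichment and semantic similarity

Per-term hypergeometric upper tail `P(X ≥ k)` (scipy `hypergeom.sf`),
Benjamini–Hochberg across the tested terms (those with ≥ 1 query gene),
significance at adjusted p ≤ 0.05; the background is an explicit input (all
network genes in the pipeline). Seed GO terms are the significant terms of
the seed set, and functional diversity is their count per seed. Wang
similarity uses the standard S-value recursion with weights is_a 0.8 /
part_of 0.6; redundancy filtering repeatedly removes, from any pair with
similarity ≥ 0.9, the term closer to the ontology root (smaller minimum
root distance), breaking depth ties by a fixed-seed draw. With these
weights a plain parent–child chain approaches similarity 0.9 only
asymptotically; pairs exceed the threshold through shared multi-parent
structure, which the tests construct explicitly.

## Synthetic scenarios

The generator emulates what the analysis needs from real data, not the real
data itself. Interactomes are Chung–Lu graphs with Pareto(1.5) expected
degrees (tail exponent 2.5), iteratively rescaled and capped at √(Σw) so
the realized mean degree matches the target; an Erdős–Rényi option exists
for controls. Scenario invariants mirror the study conditions: ≥ 25 seeds
per phenotype, seeds 0.1–0.9% of nodes.

Planting draws seeds uniformly and connects each seed pair with probability
`module_cohesion`; a connected pair receives `path_redundancy` edge-disjoint
paths of length ≤ 2 (redundancy 1 = a single two-hop path through an
intermediate; r ≥ 2 = a direct edge plus r−1 two-hop paths). Two choices
are load-bearing:

- **Degree neutrality.** Every planted edge endpoint consumes one surviving
  background edge of that node while any remain. Additive planting turns
  seeds into hubs, and because propagation rewards degree — and rewiring
  preserves relative degree — a degree artifact both inflates AUC and
  erases the perturbation response entirely (measured: AUC flat at ≈ 0.99
  up to 75% rewiring). Redirecting edges encodes the module in *where*
  edges point.
- **Fragility is quadratic, robustness redundant.** A single two-hop path
  survives p% deletion with probability (1−p/100)², faster than the linear
  decay of direct edges, so low-cohesion/redundancy-1 modules collapse
  below the critical AUC at the 50% level while redundant modules
  (direct + 2 extra paths per pair) stay above it.

The frozen presets are `tolerant_like` (cohesion 0.12, redundancy 3,
functional diversity 6) and `non_tolerant_like` (cohesion 0.07, redundancy
1, diversity 2), both on 4000-node, mean-degree-10 networks with 30 seeds.
A cohesion-0 spec is the no-signal control (AUC ≈ 0.5). A scattered-seed
control cannot serve as the non-tolerant class: with no signal the original
AUC sits at chance, the critical floor collapses onto 0.5, and the label
becomes a coin flip — the non-tolerant scenario must have genuine but
fragile connectivity, as the real non-tolerant phenotypes do (original AUCs
0.56–0.86).

Annotations form a shallow DAG (all terms `is_a` one root): 40 background
terms annotate 1% of genes each; each phenotype's seeds are split
round-robin over `functional_diversity` dedicated terms that also pick up
background genes, so recovering them requires a real test. Related-gene
sets draw each member adjacent to ≥ 1 seed with probability
`overlap_adjacency` (sampling seed-incident edges, so multiply-connected
genes are proportionally likelier — curated disease genes touch the module
in several places) and uniformly otherwise.

An optional `intermediate_pool` routes all two-hop paths through a shared
pool of "pathway partner" nodes instead of fresh private intermediates.
The differential-network demonstration requires it: double-intersecting two
80%-deleted networks keeps ≈ 4% of edges, and a module wired through
private degree-2 linkers fragments completely (its largest component holds
≈ 0 seeds, no better than background percolation). A hub-rich pooled module
(cohesion 0.9, redundancy 8, pool 60 on a 2800-node mean-degree-5
background) reproduces the published regime, its largest surviving
component retaining 40–96% of seeds across generator seeds. The baseline for that comparison is a
uniform random node set of the component's size: the module's seeds are
hubs by construction and the synthetic background holds too few
equal-degree nodes for meaningful degree matching.

## Problem sizes and determinism

All simulations run at desk scale as the package's own study design:
4000-node scenarios, 10-instance ensembles, 10 generator replicates for the
end-to-end label-recovery check, 16-instance ensembles for the
differential-network analyses, 200 simulated corpora for the enrichment
false-positive check. Every random choice flows from one base seed through
`numpy.random.SeedSequence` derivations, so all tables and artifacts are
bit-reproducible; the pipeline writes the same bytes on re-run.

## Known limitations

- The synthetic interactome has no tandem-affinity artifacts, no
  correlated edge noise, and its modules are planted with a two-parameter
  mechanism; passing tests show the analysis machinery behaves as designed
  under those conditions, not that any particular real disease is tolerant.
- NetScore's kernel and NetZcore's inter-iteration handling follow this
  package's frozen definitions (documented above); other implementations of
  the same ideas differ in unpublished details, so agreement is validated
  by behavioral properties rather than formula identity.
- The 0.9 redundancy threshold for Wang similarity interacts with DAG
  depth; on the shallow synthetic ontology most term pairs fall well below
  it, and the filter only becomes active on richer DAG structure.
- Resampling-based multiple-testing adjustment (as in enrichment web
  services) is replaced by Benjamini–Hochberg for offline reproducibility.
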