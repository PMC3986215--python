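"""Network-based disease-gene prioritization algorithms.

Five rankers, all mapping an interactome plus initial node relevance scores to
a full ranking of the network:

``netscore``
    Propagates seed scores along multiple shortest paths: the contribution of
    a source *s* to a node *u* is ``init(s) * sigma(s,u) / b**d(s,u)``, where
    ``sigma`` is the number of distinct shortest paths of length ``d <= i``
    between them and ``b`` the mean degree (a branching normalizer).  The
    update is repeated ``r`` times, feeding each round's output in as the next
    round's input.
``netzcore``
    Neighbor-mean scoring standardized against an ensemble of
    degree-preserving randomizations of the network (z-scores), iterated.
``netshort``
    Shortens edges that touch high-scoring nodes and accumulates inverse
    weighted shortest-path distances to the seeds, so paths through seeds
    count more.
``functional_flow``
    Discrete simulation of "information flow" out of infinite seed
    reservoirs over unit-capacity edges.
``pagerank_priors``
    Random walk with restart towards the (normalized) initial scores.

All outputs are min-max rescaled to [0, 1]; the evaluation is rank-based
(ROC AUC), so any monotone rescaling is evaluation-neutral.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .interactome import NodeScores

logger = logging.getLogger(__name__)

_METHODS = ("netscore", "netzcore", "netshort", "functionalflow", "pagerank")


@dataclass
class PrioritizerConfig:
    """Parameters of one prioritization run.

    ``repetitions``/``iterations`` follow the usual propagation-framework
    defaults (NetScore r=3, i=2; NetZcore 5 iterations over 100 null
    networks; Functional Flow 6 iterations; restart probability 0.3).
    """

    method: str = "netscore"
    repetitions: int = 3
    iterations: int = 2
    n_null_networks: int = 100
    restart_beta: float = 0.3
    convergence_tol: float = 1e-6
    max_iter: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {_METHODS}")
        if self.repetitions < 1 or self.iterations < 0:
            raise ValueError("repetitions must be >= 1 and iterations >= 0")
        if not 0 < self.restart_beta <= 1:
            raise ValueError("restart_beta must be in (0, 1]")
        if self.n_null_networks < 1:
            raise ValueError("n_null_networks must be >= 1")


def prioritize(net: nx.Graph, init: NodeScores, config: PrioritizerConfig) -> NodeScores:
    """Dispatch to the configured algorithm."""
    m = config.method
    if m == "netscore":
        return netscore(net, init, r=config.repetitions, i=config.iterations)
    if m == "netzcore":
        return netzcore(
            net,
            init,
            iterations=max(config.iterations, 1),
            n_null=config.n_null_networks,
            rng_seed=config.rng_seed,
        )
    if m == "netshort":
        return netshort(net, init)
    if m == "functionalflow":
        return functional_flow(net, init, iterations=max(config.iterations, 1))
    return pagerank_priors(
        net,
        init,
        beta=config.restart_beta,
        tol=config.convergence_tol,
        max_iter=config.max_iter,
    )


def _node_order(net: nx.Graph) -> list:
    # Sorted order makes every method independent of node insertion order.
    return sorted(net.nodes)


def _vector(init: NodeScores, nodes: list) -> np.ndarray:
    try:
        return np.array([float(init[u]) for u in nodes])
    except KeyError as exc:
        raise ValueError(f"initial scores missing node {exc.args[0]!r}") from exc


def _rescale(x: np.ndarray) -> np.ndarray:
    """Rescale scores to [0, 1] (rank-preserving, so evaluation-neutral).

    Non-negative scores are divided by the maximum, keeping zero as the
    natural floor (a weakly-reached node stays positive instead of being
    clamped to 0).  Vectors with negative entries (z-scores) are min-max
    rescaled.  A constant vector maps to all ones.
    """
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.ones_like(x)
    if lo >= 0:
        return x / hi
    return (x - lo) / (hi - lo)


def _as_scores(nodes: list, x: np.ndarray) -> NodeScores:
    return {u: float(v) for u, v in zip(nodes, x)}


def shortest_path_count_matrices(A: sp.csr_array, max_len: int) -> list:
    """Shortest-path count matrices C_d for d = 0..max_len.

    ``C_d[s, u]`` is the number of distinct shortest paths of length exactly
    ``d`` from s to u (zero when the graph distance differs from d).  Built by
    the standard BFS recurrence: counts at distance d are counts at d-1
    extended by one edge, masked to nodes not reached earlier.
    """
    n = A.shape[0]
    C = sp.identity(n, format="csr", dtype=float)
    seen = sp.identity(n, format="csr", dtype=bool)
    mats = [C]
    for _ in range(max_len):
        C = (C @ A).tocsr()
        # zero out pairs already reached at a shorter distance
        overlap = C.multiply(seen)
        C = (C - overlap).tocsr()
        C.eliminate_zeros()
        seen = ((seen + (C != 0)) != 0).tocsr()
        mats.append(C)
    return mats


def netscore_kernel(net: nx.Graph, i: int = 2, nodes: list | None = None) -> sp.csr_array:
    """The NetScore propagation kernel (row-stochastic).

    Entry (u, s) weights source s by sigma(s,u) / b**d(s,u) — the number of
    shortest s-u paths attenuated by the mean degree b per hop — and each row
    is normalized to sum 1, so one application replaces a node's score by the
    weighted mean of the scores in its <= i-hop neighborhood (itself
    included).  The averaging form keeps repeated application a contraction
    toward the neighborhood consensus instead of amplifying hubs, which would
    drown the seed signal after a few repetitions.  Depends only on topology,
    so it can be reused across repetitions and cross-validation folds on the
    same network.
    """
    if nodes is None:
        nodes = _node_order(net)
    n = len(nodes)
    if net.number_of_edges() == 0 or i == 0:
        return sp.identity(n, format="csr", dtype=float)
    A = sp.csr_array(nx.to_scipy_sparse_array(net, nodelist=nodes, dtype=float))
    b = 2.0 * net.number_of_edges() / n
    mats = shortest_path_count_matrices(A, i)
    K = mats[0].copy()
    for d in range(1, i + 1):
        K = K + mats[d] / (b**d)
    K = K.tocsr()
    row_sums = np.asarray(K.sum(axis=1)).ravel()
    inv = np.divide(1.0, row_sums, out=np.ones_like(row_sums), where=row_sums > 0)
    return sp.csr_array(sp.diags(inv) @ K)


def netscore(
    net: nx.Graph,
    init: NodeScores,
    r: int = 3,
    i: int = 2,
    kernel: sp.csr_array | None = None,
) -> NodeScores:
    """Multiple-shortest-path propagation of seed scores (deterministic).

    Each of the ``r`` repetitions replaces every node's score by the summed
    contributions ``score(s) * sigma(s,u) / b**d(s,u)`` over all sources
    within ``i`` hops (including the node itself at d=0); the result is
    min-max rescaled to [0, 1].
    """
    nodes = _node_order(net)
    x = _vector(init, nodes)
    K = kernel if kernel is not None else netscore_kernel(net, i, nodes)
    for _ in range(r):
        x = K @ x
    return _as_scores(nodes, _rescale(x))


def _degree_preserving_null(net: nx.Graph, seed: int) -> nx.Graph:
    """One configuration-model shuffle: 10|E| attempted double edge swaps."""
    null = net.copy()
    n_edges = null.number_of_edges()
    if null.number_of_nodes() < 4 or n_edges < 2:
        return null  # too small to swap; identity randomization
    nswap = 10 * n_edges
    try:
        nx.double_edge_swap(null, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXAlgorithmError:
        # swap budget exhausted (very dense or rigid graphs, e.g. cliques);
        # keep however many swaps succeeded
        pass
    return null


def netzcore(
    net: nx.Graph,
    init: NodeScores,
    iterations: int = 5,
    n_null: int = 100,
    rng_seed: int = 0,
) -> NodeScores:
    """Neighbor-mean scoring standardized against degree-preserving nulls.

    At each iteration the raw score of *u* is the mean of its neighbors'
    current scores; it is converted to a z-score against the same computation
    on ``n_null`` degree-preserving randomizations of the network (fixed for
    the whole run), and the z-scores feed the next iteration.  Nodes whose
    null standard deviation is zero get z = 0.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if net.number_of_edges() < 1:
        raise ValueError("netzcore requires a network with at least one edge")
    nodes = _node_order(net)
    n = len(nodes)
    A = sp.csr_array(nx.to_scipy_sparse_array(net, nodelist=nodes, dtype=float))
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv_deg = np.divide(1.0, deg, out=np.zeros(n), where=deg > 0)

    child_seeds = np.random.SeedSequence(rng_seed).generate_state(n_null) % (2**31)
    nulls = [
        sp.csr_array(
            nx.to_scipy_sparse_array(
                _degree_preserving_null(net, int(s)), nodelist=nodes, dtype=float
            )
        )
        for s in child_seeds
    ]

    x = _vector(init, nodes)
    n_zero_sigma = 0
    for _ in range(iterations):
        raw = (A @ x) * inv_deg
        null_raw = np.stack([(An @ x) * inv_deg for An in nulls])
        mu = null_raw.mean(axis=0)
        sigma = null_raw.std(axis=0)
        z = np.zeros(n)
        ok = sigma > 0
        z[ok] = (raw[ok] - mu[ok]) / sigma[ok]
        n_zero_sigma += int(np.sum(~ok))
        x = z
    if n_zero_sigma:
        logger.debug("netzcore: %d node-iteration(s) had zero null variance", n_zero_sigma)
    return _as_scores(nodes, _rescale(x))


_NETSHORT_EPS = 1e-3


def netshort(net: nx.Graph, init: NodeScores) -> NodeScores:
    """Seed-aware shortest-path scoring (deterministic).

    Edge (u,v) gets length ``1 - (init(u)+init(v)) / (2*max_init) * (1-eps)``
    with eps=1e-3, so edges whose endpoints carry high scores are shorter and
    paths running through seeds dominate.  A node's score is the sum of
    inverse weighted distances to every seed (nodes carrying the maximal
    initial score); unreachable seeds contribute nothing.
    """
    nodes = _node_order(net)
    x = _vector(init, nodes)
    max_init = float(x.max())
    if max_init <= 0:
        raise ValueError("initial scores must contain a positive maximum")
    weighted = nx.Graph()
    weighted.add_nodes_from(nodes)
    for u, v in net.edges:
        w = 1.0 - (init[u] + init[v]) / (2.0 * max_init) * (1.0 - _NETSHORT_EPS)
        weighted.add_edge(u, v, weight=w)
    sources = [u for u in nodes if float(init[u]) == max_init]
    score = {u: 0.0 for u in nodes}
    for s in sources:
        dist = nx.single_source_dijkstra_path_length(weighted, s, weight="weight")
        for u, d in dist.items():
            if u != s and d > 0:
                score[u] += 1.0 / d
    arr = np.array([score[u] for u in nodes])
    return _as_scores(nodes, _rescale(arr))


def functional_flow(net: nx.Graph, init: NodeScores, iterations: int = 6) -> NodeScores:
    """Discrete flow simulation from infinite seed reservoirs.

    Seeds (nodes at the maximal initial score) hold an infinite reservoir; at
    each iteration, flow moves across every edge from the higher- to the
    lower-reservoir endpoint, at rate ``min(1, R(u)/deg(u))`` (unit edge
    capacities).  Updates are synchronous and seed reservoirs stay infinite.
    A node's score is its total accumulated inflow; seeds are then pinned to
    the maximum accumulated inflow so they rank at the top.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    nodes = _node_order(net)
    x = _vector(init, nodes)
    max_init = float(x.max())
    seeds = {u for u in nodes if float(init[u]) == max_init}
    R = {u: (math.inf if u in seeds else 0.0) for u in nodes}
    total_in = {u: 0.0 for u in nodes}
    deg = dict(net.degree)
    for _ in range(iterations):
        inflow = {u: 0.0 for u in nodes}
        outflow = {u: 0.0 for u in nodes}
        for u, v in net.edges:
            if R[u] > R[v]:
                src, dst = u, v
            elif R[v] > R[u]:
                src, dst = v, u
            else:
                continue
            f = min(1.0, R[src] / deg[src]) if not math.isinf(R[src]) else 1.0
            inflow[dst] += f
            outflow[src] += f
        for u in nodes:
            total_in[u] += inflow[u]
            if u not in seeds:
                R[u] += inflow[u] - outflow[u]
    peak = max(total_in.values(), default=0.0)
    for u in seeds:
        total_in[u] = peak
    arr = np.array([total_in[u] for u in nodes])
    return _as_scores(nodes, _rescale(arr))


def pagerank_priors(
    net: nx.Graph,
    init: NodeScores,
    beta: float = 0.3,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> NodeScores:
    """Random walk with restart toward the prior (PageRank with priors).

    Iterates ``p <- (1-beta) * W p + beta * q`` with W the column-normalized
    adjacency, q the initial scores normalized to sum 1, and the mass of
    dangling (isolated) nodes redistributed to the prior.  Stops when the L1
    change drops to ``tol`` or at ``max_iter`` (logged warning).  The output
    sums to 1 (not min-max rescaled: it is already a distribution).
    """
    nodes = _node_order(net)
    x = _vector(init, nodes)
    total = float(x.sum())
    if total <= 0:
        raise ValueError("initial scores must have a positive sum")
    q = x / total
    if beta >= 1.0:
        return _as_scores(nodes, q)
    n = len(nodes)
    A = sp.csr_array(nx.to_scipy_sparse_array(net, nodelist=nodes, dtype=float))
    deg = np.asarray(A.sum(axis=1)).ravel()
    dangling = deg == 0
    inv_deg = np.divide(1.0, deg, out=np.zeros(n), where=~dangling)
    p = q.copy()
    for _ in range(max_iter):
        walk = A @ (p * inv_deg)  # symmetric A: column normalization by degree
        walk += float(p[dangling].sum())* q
        p_new = (1.0 - beta) * walk + beta * q
        if float(np.abs(p_new - p).sum()) <= tol:
            p = p_new
            break
        p = p_new
    else:
        logger.warning("pagerank_priors: no convergence within %d iterations", max_iter)
    return _as_scores(nodes, p)


def top_fraction(scores: NodeScores, fraction: float = 0.05) -> set:
    """The ceil(fraction * n) highest-scoring nodes (the "high scoring subnetwork").

    Ties at the cutoff are broken by lexicographic node id so the selection is
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(scores))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return {u for u, _ in ranked[:k]}
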