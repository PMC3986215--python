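"""The five prioritization algorithms: frozen examples, oracles, invariances."""

import math

import networkx as nx
import numpy as np
import pytest

from netprio.prioritize import (
    PrioritizerConfig,
    functional_flow,
    netscore,
    netshort,
    netzcore,
    pagerank_priors,
    prioritize,
    top_fraction,
)

METHODS = ["netscore", "netzcore", "netshort", "functionalflow", "pagerank"]


def seeded_init(net, seeds):
    return {u: (1.0 if u in seeds else 0.01) for u in net.nodes}


def minmax(values):
    """Mirror of the package's rescaling rule (divide-by-max when >= 0)."""
    arr = np.asarray(values, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.ones_like(arr)
    return arr / hi if lo >= 0 else (arr - lo) / (hi - lo)


# --- independent NetScore oracle: per-source BFS with path counting ---------


def bfs_shortest_path_counts(g, source, max_len):
    """(distance, count) of shortest paths from source, BFS with counting."""
    dist = {source: 0}
    count = {source: 1}
    frontier = [source]
    d = 0
    while frontier and d < max_len:
        nxt = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = d + 1
                    count[v] = 0
                    nxt.append(v)
                if dist[v] == d + 1:
                    count[v] += count[u]
        frontier = nxt
        d += 1
    return dist, count


def oracle_netscore(g, init, r, i):
    """Reference NetScore: explicit kernel from per-source BFS, no sparse ops."""
    nodes = sorted(g.nodes)
    b = 2.0 * g.number_of_edges() / len(nodes)
    K = np.zeros((len(nodes), len(nodes)))
    index = {u: j for j, u in enumerate(nodes)}
    for s in nodes:
        dist, count = bfs_shortest_path_counts(g, s, i)
        for u, d in dist.items():
            K[index[u], index[s]] = count[u] / (b**d if d else 1.0)
    rows = K.sum(axis=1, keepdims=True)
    K = np.divide(K, rows, out=np.zeros_like(K), where=rows > 0)
    x = np.array([init[u] for u in nodes])
    for _ in range(r):
        x = K @ x
    return dict(zip(nodes, minmax(x)))


class TestNetScore:
    def test_matches_bfs_oracle_on_random_graphs(self):
        for seed in range(5):
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            g = nx.relabel_nodes(g, {k: f"n{k}" for k in g.nodes})
            if g.number_of_edges() == 0:
                continue
            init = seeded_init(g, {"n0", "n1"})
            got = netscore(g, init, r=3, i=2)
            want = oracle_netscore(g, init, r=3, i=2)
            for u in g.nodes:
                assert got[u] == pytest.approx(want[u], abs=1e-10)

    def test_closer_nodes_score_higher(self, path3):
        scores = netscore(path3, seeded_init(path3, {"s"}), r=1, i=2)
        assert scores["a"] > scores["b"] > 0

    def test_more_adjacent_seeds_score_higher(self):
        # u touches two seeds, v touches one; degrees kept symmetric
        g = nx.Graph()
        g.add_edges_from([("s1", "u"), ("s2", "u"), ("s3", "v"), ("f1", "v")])
        scores = netscore(g, seeded_init(g, {"s1", "s2", "s3"}), r=1, i=1)
        assert scores["u"] > scores["v"]

    def test_zero_hops_returns_rescaled_init(self, path3):
        init = seeded_init(path3, {"s"})
        scores = netscore(path3, init, r=2, i=0)
        expected = dict(zip(sorted(init), minmax([init[u] for u in sorted(init)])))
        assert scores == pytest.approx(expected)

    def test_unreachable_component_gets_minimum(self, path3):
        g = path3.copy()
        g.add_edge("x", "y")
        scores = netscore(g, seeded_init(g, {"s"}), r=3, i=2)
        assert scores["x"] == scores["y"] == min(scores.values())


class TestNetZcore:
    def test_complete_graph_has_zero_null_variance(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {k: f"n{k}" for k in g.nodes})
        scores = netzcore(g, seeded_init(g, {"n0"}), iterations=2, n_null=10, rng_seed=0)
        # every degree-preserving shuffle of K4 is K4: all z = 0, constant output
        assert set(scores.values()) == {1.0}

    def test_tiny_graph_identity_null_gives_zero_z(self, path3):
        # < 4 nodes cannot double-edge-swap: null ensemble is the identity
        scores = netzcore(path3, seeded_init(path3, {"s"}), iterations=1, n_null=1, rng_seed=0)
        assert set(scores.values()) == {1.0}

    def test_seed_adjacency_beats_distance(self):
        # star around the seed with a two-hop tail: the tail end should not
        # outrank the seed's own leaves (fixed null ensemble via rng_seed)
        g = nx.Graph()
        for leaf in "abcde":
            g.add_edge("s", leaf)
        g.add_edges_from([("e", "f"), ("f", "g"), ("b", "c")])
        scores = netzcore(g, seeded_init(g, {"s"}), iterations=2, n_null=30, rng_seed=7)
        for leaf in "abcde":
            assert scores[leaf] > scores["g"]

    def test_reproducible_given_seed(self, small_scenario):
        _, _, planted = small_scenario
        g = nx.subgraph(planted.network, sorted(planted.network.nodes)[:200]).copy()
        init = seeded_init(g, set(sorted(g.nodes)[:5]))
        a = netzcore(g, init, iterations=2, n_null=5, rng_seed=3)
        b = netzcore(g, init, iterations=2, n_null=5, rng_seed=3)
        assert a == b


class TestNetShort:
    def test_path_distance_ordering(self, path3):
        scores = netshort(path3, seeded_init(path3, {"s"}))
        assert scores["a"] > scores["b"]

    def test_seed_paths_are_shorter(self):
        # u reaches s directly through a non-seed hop; v reaches s through a
        # second seed s2: same hop count, but the seed-laden route is shorter.
        g = nx.Graph()
        g.add_edges_from([("u", "m"), ("m", "s"), ("v", "s2"), ("s2", "s")])
        scores = netshort(g, seeded_init(g, {"s", "s2"}))
        assert scores["v"] > scores["u"]

    def test_uniform_init_equals_inverse_hop_sum(self):
        for seed in range(4):
            g = nx.gnp_random_graph(8, 0.4, seed=seed)
            g = nx.relabel_nodes(g, {k: f"n{k}" for k in g.nodes})
            if g.number_of_edges() == 0:
                continue
            init = {u: 0.5 for u in g.nodes}
            got = netshort(g, init)
            closed = {}
            for u in g.nodes:
                hops = nx.single_source_shortest_path_length(g, u)
                closed[u] = sum(1.0 / d for v, d in hops.items() if v != u and d > 0)
            nodes = sorted(g.nodes)
            want = dict(zip(nodes, minmax([closed[u] for u in nodes])))
            for u in nodes:
                assert got[u] == pytest.approx(want[u], rel=1e-9)


class TestFunctionalFlow:
    def test_single_edge_capacity_limited(self):
        g = nx.Graph()
        g.add_edge("s", "a")
        g.add_node("idle")
        scores = functional_flow(g, seeded_init(g, {"s"}), iterations=1)
        assert scores["a"] == 1.0  # one unit over the unit-capacity edge
        assert scores["idle"] == 0.0

    def test_flow_is_local_in_one_iteration(self, path3):
        g = path3.copy()
        g.add_node("z")
        scores = functional_flow(g, seeded_init(g, {"s"}), iterations=1)
        assert scores["b"] == scores["z"] == 0.0
        assert scores["a"] > 0

    def test_flow_reaches_farther_with_more_iterations(self, path3):
        scores = functional_flow(path3, seeded_init(path3, {"s"}), iterations=3)
        assert scores["b"] > 0

    def test_isolated_node_scores_zero(self, triangle):
        g = triangle.copy()
        g.add_node("x")
        scores = functional_flow(g, seeded_init(g, {"a"}), iterations=6)
        assert scores["x"] == 0.0


class TestPageRankPriors:
    def test_beta_one_returns_normalized_prior(self, path3):
        init = seeded_init(path3, {"s"})
        scores = pagerank_priors(path3, init, beta=1.0)
        total = sum(init.values())
        assert scores == pytest.approx({u: v / total for u, v in init.items()})

    def test_symmetric_two_nodes_split_evenly(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        scores = pagerank_priors(g, {"a": 1.0, "b": 1.0}, beta=0.3)
        assert scores == pytest.approx({"a": 0.5, "b": 0.5})

    def test_matches_direct_linear_solve(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c")])
        init = {"a": 1.0, "b": 0.01, "c": 0.01}
        beta = 0.3
        nodes = sorted(g.nodes)
        A = nx.to_numpy_array(g, nodelist=nodes)
        W = A / A.sum(axis=0, keepdims=True)
        q = np.array([init[u] for u in nodes])
        q = q / q.sum()
        p_exact = np.linalg.solve(np.eye(3) - (1 - beta) * W, beta * q)
        scores = pagerank_priors(g, init, beta=beta, tol=1e-12, max_iter=10_000)
        assert [scores[u] for u in nodes] == pytest.approx(p_exact.tolist(), abs=1e-9)

    def test_output_is_a_distribution(self, small_scenario):
        _, _, planted = small_scenario
        g = planted.network
        scores = pagerank_priors(g, seeded_init(g, planted.seeds.seeds))
        assert sum(scores.values()) == pytest.approx(1.0)
        assert min(scores.values()) >= 0


class TestTopFraction:
    def test_five_percent_of_hundred(self):
        scores = {f"n{i:03d}": float(i) for i in range(100)}
        top = top_fraction(scores, 0.05)
        assert len(top) == 5
        assert top == {f"n{i:03d}" for i in range(95, 100)}

    def test_full_fraction_returns_all(self):
        scores = {"a": 1.0, "b": 0.5}
        assert top_fraction(scores, 1.0) == {"a", "b"}

    def test_cutoff_tie_broken_lexicographically(self):
        scores = {"a": 1.0, "c": 0.5, "b": 0.5, "d": 0.1}
        assert top_fraction(scores, 0.5) == {"a", "b"}


class TestCrossMethodInvariants:
    @pytest.mark.parametrize("method", METHODS)
    def test_defined_for_every_node_and_insertion_order_free(self, method):
        g1 = nx.Graph()
        g1.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("b", "e")])
        g2 = nx.Graph()
        g2.add_edges_from(reversed([("b", "e"), ("d", "a"), ("c", "d"), ("b", "c"), ("a", "b")]))
        cfg = PrioritizerConfig(method=method, n_null_networks=5, rng_seed=11)
        init = seeded_init(g1, {"a"})
        s1 = prioritize(g1, init, cfg)
        s2 = prioritize(g2, init, cfg)
        assert set(s1) == set(g1.nodes)
        assert s1 == s2

    @pytest.mark.parametrize("method", ["netscore", "netshort", "functionalflow", "pagerank"])
    def test_deterministic_methods_are_label_invariant(self, method):
        g = nx.gnp_random_graph(10, 0.35, seed=2)
        g = nx.relabel_nodes(g, {k: f"n{k}" for k in g.nodes})
        mapping = {u: f"z{hash(u) % 97}-{u}" for u in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        cfg = PrioritizerConfig(method=method)
        init = seeded_init(g, {"n0", "n3"})
        init_h = {mapping[u]: v for u, v in init.items()}
        s_g = prioritize(g, init, cfg)
        s_h = prioritize(h, init_h, cfg)
        for u in g.nodes:
            assert s_g[u] == pytest.approx(s_h[mapping[u]], abs=1e-12)

    @pytest.mark.parametrize("method", METHODS)
    def test_module_neighbors_beat_distant_control(self, method):
        # seeds form a clique; each seed has a non-seed neighbor; a control
        # node hangs far away off one of those neighbors
        g = nx.Graph()
        seeds = [f"s{i}" for i in range(4)]
        for i, u in enumerate(seeds):
            for v in seeds[i + 1 :]:
                g.add_edge(u, v)
            g.add_edge(u, f"n{i}")
        g.add_edges_from([("n0", "x1"), ("x1", "x2"), ("x2", "ctrl")])
        cfg = PrioritizerConfig(method=method, n_null_networks=30, rng_seed=5)
        scores = prioritize(g, seeded_init(g, set(seeds)), cfg)
        for i in range(4):
            assert scores[f"n{i}"] > scores["ctrl"]


def test_unknown_method_rejected():
    with pytest.raises(ValueError, match="unknown method"):
        PrioritizerConfig(method="mystery")


def test_netshort_requires_positive_scores(path3):
    with pytest.raises(ValueError):
        netshort(path3, {u: 0.0 for u in path3.nodes})


def test_functional_flow_requires_iterations(path3):
    with pytest.raises(ValueError):
        functional_flow(path3, seeded_init(path3, {"s"}), iterations=0)


def test_pagerank_requires_positive_prior(path3):
    with pytest.raises(ValueError):
        pagerank_priors(path3, {u: 0.0 for u in path3.nodes})
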