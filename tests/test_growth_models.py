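"""Seed constructors and the DMC/DMR/CG step operators."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from ppifam import (
    FOUniverse,
    GrowthParams,
    PPINetwork,
    anti_preferential_choice,
    build_cg_seed,
    build_duplication_seed,
    cg_step,
    detect_modules,
    dmc_step,
    dmr_step,
    grow,
    validate,
)
from ppifam.graph_core import EVENT_SEED


def edge_network(network_id: str = "N") -> PPINetwork:
    """Two annotated nodes joined by a single edge."""
    net = PPINetwork(network_id=network_id)
    fo = FOUniverse()
    a = net.new_node(fo.fresh(), None, EVENT_SEED)
    b = net.new_node(fo.fresh(), None, EVENT_SEED)
    net.add_edge(a, b)
    return net


class TestSeeds:
    def test_duplication_seed_structure(self):
        rng = np.random.default_rng(0)
        params = GrowthParams(seed_bridge_edges=5)
        net = build_duplication_seed(params, rng)
        assert net.n_nodes == 50
        assert len(set(net.annotation.values())) == 35
        # 10-clique (45) + 7-clique (21) + 5 bridges + 33 peripheral edges
        assert net.n_edges == 45 + 21 + 5 + 33
        assert validate(net) == []

    def test_duplication_seed_cliques_complete(self):
        rng = np.random.default_rng(1)
        net = build_duplication_seed(GrowthParams(), rng)
        by_label = net.fo_index()
        for label, size in (("F1", 10), ("F2", 7)):
            members = by_label[label]
            assert len(members) == size
            sub = net.graph.subgraph(members)
            assert sub.number_of_edges() == size * (size - 1) // 2

    def test_peripherals_attach_to_clique_nodes(self):
        rng = np.random.default_rng(2)
        net = build_duplication_seed(GrowthParams(), rng)
        clique = set(net.fo_index()["F1"]) | set(net.fo_index()["F2"])
        peripherals = [n for n in net.nodes_sorted() if n not in clique]
        assert len(peripherals) == 33
        for p in peripherals:
            neighbors = list(net.graph.neighbors(p))
            assert len(neighbors) == 1 and neighbors[0] in clique

    def test_cg_seed(self):
        rng = np.random.default_rng(0)
        net = build_cg_seed(rng)
        assert net.n_nodes == 4
        assert nx.is_connected(net.graph)
        assert len(set(net.annotation.values())) == 4


class TestDMCStep:
    def test_no_deletion_forced_connection_gives_triangle(self):
        net = edge_network()
        params = GrowthParams(dmc_q_del=0.0, dmc_q_con=1.0)
        v, u = dmc_step(net, params, np.random.default_rng(0))
        # duplicate keeps the copied edge, plus the original edge and u-v
        assert net.n_nodes == 3 and net.n_edges == 3

    def test_forced_single_deletion(self):
        net = edge_network()
        params = GrowthParams(dmc_q_del=1.0, dmc_q_con=0.0)
        dmc_step(net, params, np.random.default_rng(0))
        assert net.n_edges == 1

    def test_adds_one_node_per_step(self):
        net = edge_network()
        rng = np.random.default_rng(3)
        for i in range(10):
            dmc_step(net, GrowthParams(), rng)
        assert net.n_nodes == 12

    def test_monotone_when_no_deletion(self):
        rng = np.random.default_rng(5)
        net = build_duplication_seed(GrowthParams(), rng)
        params = GrowthParams(dmc_q_del=0.0, dmc_q_con=0.5)
        for _ in range(30):
            before = set(map(frozenset, net.graph.edges))
            dmc_step(net, params, rng)
            after = set(map(frozenset, net.graph.edges))
            assert before <= after

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            dmc_step(PPINetwork(network_id="E"), GrowthParams(), np.random.default_rng(0))


class TestDMRStep:
    def test_pure_duplication(self):
        net = edge_network()
        params = GrowthParams(model="DMR", dmr_q_del=0.0, dmr_q_new=0.0)
        v, u = dmr_step(net, params, np.random.default_rng(0))
        assert net.n_edges == 2 and net.graph.degree[v] == 1

    def test_full_deletion_isolates_duplicate(self):
        net = edge_network()
        params = GrowthParams(model="DMR", dmr_q_del=1.0, dmr_q_new=0.0)
        v, u = dmr_step(net, params, np.random.default_rng(0))
        assert net.n_edges == 1 and net.graph.degree[v] == 0

    def test_random_attachment_rate_matches_binomial(self):
        # duplicate an isolated node in a 100-node empty graph: each of the
        # 99 other existing nodes is attached with probability q_new / 100
        q_new = 0.24
        n_candidates, p = 99, q_new / 100
        expected = n_candidates * p
        se = np.sqrt(n_candidates * p * (1 - p))
        trials = 5000
        rng = np.random.default_rng(11)
        total = 0
        for _ in range(trials):
            net = PPINetwork(network_id="N")
            fo = FOUniverse()
            for _ in range(100):
                net.new_node(fo.fresh(), None, EVENT_SEED)
            v, _ = dmr_step(
                net, GrowthParams(model="DMR", dmr_q_del=0.0, dmr_q_new=q_new), rng
            )
            total += net.graph.degree[v]
        mean = total / trials
        assert abs(mean - expected) < 3 * se / np.sqrt(trials)


class TestAntiPreferential:
    def test_uniform_when_degrees_equal(self):
        net = edge_network()
        nodes = net.nodes_sorted()
        rng = np.random.default_rng(0)
        draws = [anti_preferential_choice(nodes, net, rng) for _ in range(10000)]
        counts = [draws.count(n) for n in nodes]
        chi2 = sps.chisquare(counts)
        assert chi2.pvalue > 0.01

    def test_degree_weighted_frequencies(self):
        # degrees {1, 3, 4} -> probabilities (1/2, 1/4, 1/5) normalized
        net = PPINetwork(network_id="N")
        fo = FOUniverse()
        hub = net.new_node(fo.fresh(), None, EVENT_SEED)
        mid = net.new_node(fo.fresh(), None, EVENT_SEED)
        low = net.new_node(fo.fresh(), None, EVENT_SEED)
        spokes = [net.new_node(fo.fresh(), None, EVENT_SEED) for _ in range(4)]
        for s in spokes:
            net.add_edge(hub, s)
        for s in spokes[:2]:
            net.add_edge(mid, s)
        net.add_edge(mid, low)
        assert (net.degree(low), net.degree(mid), net.degree(hub)) == (1, 3, 4)
        weights = np.array([1 / 2, 1 / 4, 1 / 5])
        probs = weights / weights.sum()
        trials = 20000
        rng = np.random.default_rng(1)
        candidates = [low, mid, hub]
        draws = [
            anti_preferential_choice(candidates, net, rng) for _ in range(trials)
        ]
        for node, p in zip(candidates, probs):
            freq = draws.count(node) / trials
            se = np.sqrt(p * (1 - p) / trials)
            assert abs(freq - p) < 3 * se

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            anti_preferential_choice([], edge_network(), np.random.default_rng(0))


def exhaustive_best_modularity(graph: nx.Graph) -> float:
    """Independent oracle: maximum modularity over all partitions (<= 7 nodes)."""
    nodes = list(graph.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    return max(
        nx.community.modularity(graph, [set(b) for b in part])
        for part in partitions(nodes)
    )


class TestDetectModules:
    def test_two_triangles_split(self):
        net = PPINetwork(network_id="N")
        fo = FOUniverse()
        nodes = [net.new_node(fo.fresh(), None, EVENT_SEED) for _ in range(6)]
        for tri in (nodes[:3], nodes[3:]):
            for u, v in itertools.combinations(tri, 2):
                net.add_edge(u, v)
        net.add_edge(nodes[0], nodes[3])
        modules = detect_modules(net)
        assert sorted(map(sorted, modules)) == [sorted(nodes[:3]), sorted(nodes[3:])]

    def test_complete_graph_single_module(self):
        net = PPINetwork(network_id="N")
        fo = FOUniverse()
        nodes = [net.new_node(fo.fresh(), None, EVENT_SEED) for _ in range(5)]
        for u, v in itertools.combinations(nodes, 2):
            net.add_edge(u, v)
        assert detect_modules(net) == [set(nodes)]

    def test_edgeless_graph_gives_singletons(self):
        net = PPINetwork(network_id="N")
        fo = FOUniverse()
        nodes = [net.new_node(fo.fresh(), None, EVENT_SEED) for _ in range(3)]
        assert detect_modules(net) == [{n} for n in nodes]

    def test_matches_exhaustive_search_on_small_fixtures(self):
        fixtures = []
        # two triangles + bridge
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (0, 3)])
        fixtures.append(g)
        fixtures.append(nx.complete_graph(5))
        fixtures.append(nx.star_graph(4))
        fixtures.append(nx.cycle_graph(7))
        # two disjoint triangles
        fixtures.append(nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]))
        # barbell: two K3 joined by a path node
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5), (5, 6), (4, 6)])
        fixtures.append(g)
        for graph in fixtures:
            net = PPINetwork(network_id="N")
            fo = FOUniverse()
            mapping = {x: net.new_node(fo.fresh(), None, EVENT_SEED) for x in graph.nodes}
            for u, v in graph.edges:
                net.add_edge(mapping[u], mapping[v])
            detected = detect_modules(net)
            q = nx.community.modularity(net.graph, detected)
            q_best = exhaustive_best_modularity(net.graph)
            assert q == pytest.approx(q_best, abs=1e-12)


class TestCGStep:
    def test_forced_new_module(self):
        net = build_cg_seed(np.random.default_rng(0))
        fo = FOUniverse(next_fresh=5)
        extra = net.new_node(fo.fresh(), None, EVENT_SEED)
        net.add_edge(extra, net.nodes_sorted()[0])
        modules = detect_modules(net)
        params = GrowthParams(model="CG", cg_p_new=1.0, cg_m=2)
        v, anchor, modules2 = cg_step(net, modules, params, np.random.default_rng(1))
        assert anchor is None
        assert net.graph.degree[v] == 2
        assert len(modules2) == len(modules) + 1

    def test_anchored_join_on_triangle(self):
        net = PPINetwork(network_id="N")
        fo = FOUniverse()
        nodes = [net.new_node(fo.fresh(), None, EVENT_SEED) for _ in range(3)]
        for u, v in itertools.combinations(nodes, 2):
            net.add_edge(u, v)
        params = GrowthParams(model="CG", cg_p_new=0.0, cg_m=2)
        v, anchor, modules2 = cg_step(
            net, [set(nodes)], params, np.random.default_rng(2)
        )
        assert anchor in nodes
        assert net.graph.degree[v] == 2
        assert net.graph.has_edge(v, anchor)
        assert v in set().union(*modules2)

    def test_always_adds_one_node(self):
        net = build_cg_seed(np.random.default_rng(3))
        modules = detect_modules(net)
        rng = np.random.default_rng(4)
        params = GrowthParams(model="CG")
        for i in range(10):
            before = net.n_nodes
            _, _, modules = cg_step(net, modules, params, rng)
            assert net.n_nodes == before + 1


class TestGrow:
    def test_zero_steps_is_identity(self):
        net = edge_network()
        log = grow(net, 0, GrowthParams(), np.random.default_rng(0), fo=FOUniverse())
        assert log == [] and net.n_nodes == 2

    def test_dmc_growth_counts(self):
        rng = np.random.default_rng(6)
        net = build_duplication_seed(GrowthParams(), rng)
        fo = FOUniverse(next_fresh=36)
        log = grow(net, 950, GrowthParams(), rng, fo=fo)
        assert net.n_nodes == 1000 and len(log) == 950

    def test_ancestral_policy_issues_fresh_groups(self):
        rng = np.random.default_rng(7)
        net = build_duplication_seed(GrowthParams(), rng)
        fo = FOUniverse(next_fresh=36)
        groups_before = len(set(net.annotation.values()))
        grow(net, 40, GrowthParams(), rng, fo=fo)
        assert len(set(net.annotation.values())) == groups_before + 40

    def test_negative_steps_rejected(self):
        with pytest.raises(ValueError):
            grow(edge_network(), -1, GrowthParams(), np.random.default_rng(0), fo=FOUniverse())


@pytest.mark.parametrize("model", ["DMC", "DMR", "CG"])
def test_step_operators_preserve_simple_graph_invariants(model):
    """Fuzz: every step adds exactly one node, no self-loops, no multi-edges."""
    rng = np.random.default_rng(42)
    for trial in range(8):
        params = GrowthParams(
            model=model,
            dmc_q_del=float(rng.random()),
            dmc_q_con=float(rng.random()),
            dmr_q_del=float(rng.random()),
            dmr_q_new=float(rng.random()),
            cg_p_new=float(rng.random()),
            cg_m=int(rng.integers(1, 4)),
        )
        net = (
            build_cg_seed(rng)
            if model == "CG"
            else build_duplication_seed(params, rng)
        )
        fo = FOUniverse(next_fresh=net.n_nodes + 2)
        before = net.n_nodes
        grow(net, 25, params, rng, fo=fo)
        assert net.n_nodes == before + 25
        assert validate(net) == []
        assert all(u != v for u, v in net.graph.edges)
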