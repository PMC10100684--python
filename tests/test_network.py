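import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from plankweb.network import (
    attack,
    filter_low_abundance,
    fragmentation,
    gatekeeper_table,
    infer_network,
    spearman_edges,
    topology,
)
from plankweb.simulate import CommunitySimSpec, simulate_block_network

from conftest import make_table


def brute_force_edges(table, r_min=0.8, p_max=0.01):
    """Independent per-pair Spearman screen: Pearson on average ranks with a
    two-sided t-approximation p-value."""
    data = table.counts.to_numpy().astype(float)
    n = data.shape[1]
    edges = set()
    for i, j in itertools.combinations(range(data.shape[0]), 2):
        x, y = data[i], data[j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        if not np.isfinite(r):
            continue
        if abs(r) < 1.0:
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * t_dist.sf(abs(t), n - 2)
        else:
            p = 0.0
        if abs(r) >= r_min and p < p_max:
            edges.add((table.taxon_ids[i], table.taxon_ids[j]))
    return edges


def brute_force_betweenness(graph):
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    nodes = list(graph.nodes)
    n = len(nodes)
    adj = {v: set(graph.neighbors(v)) for v in nodes}
    score = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        # BFS distance
        dist = {s: 0}
        frontier = [s]
        while frontier and t not in dist:
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            continue
        # enumerate all shortest paths by DFS along decreasing distance
        paths = []

        def extend(path):
            v = path[-1]
            if v == t:
                paths.append(path)
                return
            for w in adj[v]:
                if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                    extend(path + [w])

        extend([s])
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: score[v] / norm for v in nodes}


class TestFilter:
    def test_threshold_keeps_and_drops_hand_cases(self):
        # taxon means straddle the 0.01 % threshold
        counts = np.array([
            [50, 50],      # 0.5 %
            [1, 1],        # 0.01 %
            [1, 0],        # 0.005 %
            [0, 0],        # absent
            [9948, 9949],
        ])
        table = make_table(counts)
        kept = filter_low_abundance(table, 1e-4)
        assert kept.taxon_ids == ["t0", "t1", "t4"]

    def test_all_dropped_is_error(self):
        table = make_table([[1, 1], [1, 1], [9998, 9998]])
        with pytest.raises(ValueError, match="every OTU"):
            filter_low_abundance(table, 0.9999)


class TestInferNetwork:
    def test_comonotone_pair_gets_perfect_edge(self):
        x = np.arange(1, 21)
        table = make_table(np.vstack([x, x * 3 + 2, np.full(20, 7)]))
        graph = infer_network(table)
        assert set(graph.edges) == {("t0", "t1")}
        assert graph.edges["t0", "t1"]["r"] == pytest.approx(1.0)

    def test_constant_taxon_has_no_edges(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 100, (6, 15))
        counts[2] = 5
        graph = infer_network(make_table(counts), r_min=0.0, p_max=0.999)
        assert "t2" not in graph.nodes

    @pytest.mark.parametrize("seed", range(10))
    def test_edge_set_matches_brute_force_oracle(self, seed):
        spec = CommunitySimSpec(
            n_taxa=8, n_samples=15, reads_per_sample=300,
            regime="block_network", n_modules=2, factor_loading=1.0, seed=seed,
        )
        table, _ = simulate_block_network(spec)
        graph = infer_network(table)
        assert set(map(tuple, map(sorted, graph.edges))) == set(
            map(tuple, map(sorted, brute_force_edges(table)))
        )

    def test_edges_invariant_to_monotone_transform_and_sample_order(self):
        spec = CommunitySimSpec(
            n_taxa=15, n_samples=20, reads_per_sample=2000,
            regime="block_network", n_modules=3, seed=1,
        )
        table, _ = simulate_block_network(spec)
        base = set(map(tuple, map(sorted, infer_network(table).edges)))
        squared = make_table(
            (table.counts.to_numpy() ** 2), table.taxon_ids, table.sample_ids
        )
        assert set(map(tuple, map(sorted, infer_network(squared).edges))) == base
        rng = np.random.default_rng(0)
        order = rng.permutation(table.n_samples)
        shuffled = table.select_samples([table.sample_ids[i] for i in order])
        assert set(map(tuple, map(sorted, infer_network(shuffled).edges))) == base

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="5 samples"):
            infer_network(make_table(np.ones((3, 4), dtype=int)))


class TestTopology:
    def test_complete_graph(self):
        g = nx.complete_graph(4)
        rep = topology(g)
        assert rep.graph_density == 1.0
        assert rep.average_clustering_coefficient == 1.0
        assert rep.average_path_length == 1.0
        assert rep.diameter == 1
        assert rep.n_components == 1
        assert rep.average_degree == pytest.approx(3.0)

    def test_path_graph(self):
        rep = topology(nx.path_graph(4))
        assert rep.diameter == 3
        assert rep.average_clustering_coefficient == 0.0

    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        rep = topology(g, seed=0)
        assert rep.n_components == 2
        # closed form: two equal disconnected cliques have modularity 1/2
        assert rep.modularity == pytest.approx(0.5, abs=1e-9)
        assert rep.modularity >= 0.4


class TestFragmentation:
    def test_connected_graph_zero(self):
        assert fragmentation(nx.path_graph(7)) == 0.0

    def test_fully_atomised_one(self):
        assert fragmentation(nx.empty_graph(9)) == pytest.approx(1.0)

    def test_two_components_of_ten(self):
        g = nx.disjoint_union(nx.path_graph(6), nx.path_graph(4))
        assert fragmentation(g) == pytest.approx(np.log(2) / np.log(10))

    def test_base_invariance(self):
        g = nx.disjoint_union(nx.path_graph(5), nx.path_graph(8))
        f = fragmentation(g)
        assert f == pytest.approx(np.log2(2) / np.log2(13))
        assert f == pytest.approx(np.log10(2) / np.log10(13))

    def test_single_node_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            fragmentation(nx.empty_graph(1))


class TestAttack:
    def test_star_hub_removal_atomises(self):
        g = nx.star_graph(5)  # hub 0 + 5 leaves
        traj = attack(g, strategy="betweenness", k=1)
        assert traj.removed_nodes == [0]
        assert traj.f_values == [0.0, 1.0]
        assert traj.n_remaining == [6, 5]

    def test_zero_removals_is_baseline_only(self):
        g = nx.complete_graph(5)
        traj = attack(g, strategy="degree", k=0)
        assert traj.f_values == [0.0]
        assert traj.removed_nodes == []

    def test_bridge_node_removal_hand_value(self):
        # two K5s joined through one extra bridge node: removing it leaves
        # two components among the 10 remaining nodes
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edges_from([(0, 10), (5, 10)])
        traj = attack(g, strategy="betweenness", k=1)
        assert traj.removed_nodes == [10]
        assert traj.f_values[1] == pytest.approx(np.log(2) / np.log(10))

    def test_too_many_removals_rejected(self):
        with pytest.raises(ValueError):
            attack(nx.complete_graph(4), k=3)

    def test_random_strategy_seeded(self):
        g = nx.complete_graph(8)
        a = attack(g, strategy="random", k=3, seed=4)
        b = attack(g, strategy="random", k=3, seed=4)
        assert a.removed_nodes == b.removed_nodes

    def test_adaptive_reranks(self):
        # path: static betweenness picks the two central nodes up front;
        # adaptive re-ranks and picks the centre of the surviving pieces
        g = nx.path_graph(7)
        static = attack(g, strategy="betweenness", k=2, adaptive=False)
        adaptive = attack(g, strategy="betweenness", k=2, adaptive=True)
        assert static.removed_nodes[0] == adaptive.removed_nodes[0] == 3
        assert static.removed_nodes != adaptive.removed_nodes


class TestGatekeepers:
    def test_star_hub_tops_betweenness_and_degree(self):
        g = nx.star_graph(6)
        tables = gatekeeper_table(g, top_k=3)
        assert tables["rankings"]["betweenness"].iloc[0]["taxon_id"] == 0
        assert tables["rankings"]["degree"].iloc[0]["taxon_id"] == 0

    def test_path_middle_node_max_betweenness(self):
        tables = gatekeeper_table(nx.path_graph(5), top_k=1)
        assert tables["rankings"]["betweenness"].iloc[0]["taxon_id"] == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_betweenness_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(1 << 16)))
        expected = brute_force_betweenness(g)
        observed = nx.betweenness_centrality(g, normalized=True)
        for v in g.nodes:
            assert observed[v] == pytest.approx(expected[v], abs=1e-9)


class TestDomainSubnetworks:
    def test_domain_subnetwork_equals_restricted_recomputation(self):
        from plankweb.otu import PROKARYOTE, MICROEUKARYOTE

        spec = CommunitySimSpec(
            n_taxa=23, n_samples=25, reads_per_sample=20000,
            regime="block_network", n_modules=3, seed=5,
        )
        table, _ = simulate_block_network(spec)
        domain = [PROKARYOTE if i % 2 else MICROEUKARYOTE for i in range(table.n_taxa)]
        table.domain = __import__("pandas").Series(domain, index=table.counts.index)
        full = infer_network(table)
        prok_table = table.select_domain(PROKARYOTE)
        sub = infer_network(prok_table)
        prok_nodes = {v for v in full.nodes if full.nodes[v]["domain"] == PROKARYOTE}
        induced = full.subgraph(prok_nodes)
        # same code path, restricted input: edge sets coincide
        assert set(map(tuple, map(sorted, sub.edges))) == set(
            map(tuple, map(sorted, induced.edges))
        )
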