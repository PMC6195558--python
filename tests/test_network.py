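"""Dynamical network analysis: correlations, contact graphs, paths,
communities and critical edges."""

import networkx as nx
import numpy as np
import pytest

from alloscope import network
from alloscope.structure import ResidueSelection
from _utils import (
    brute_force_edge_betweenness,
    brute_force_shortest,
    exhaustive_best_modularity,
    full_selection,
    make_topology,
    make_trajectory,
    weighted_modularity,
)


def ca_topology(n, chain="A", start=1):
    return make_topology([("CA", "C", chain, start + i, "ALA") for i in range(n)])


class TestCorrelationMatrix:
    def test_identical_and_antiphase_motion(self):
        topo = ca_topology(3)
        t = np.linspace(0, 4 * np.pi, 50)
        disp = np.sin(t)
        frames = np.zeros((50, 3, 3))
        frames[:, 0, 0] = disp          # node 0
        frames[:, 1, 0] = disp          # node 1: identical motion
        frames[:, 2, 0] = -disp         # node 2: anti-phase
        frames[:, :, 1] = np.array([0.0, 10.0, 20.0])[None, :]
        traj = make_trajectory(topo, frames)
        corr = network.correlation_matrix(traj, full_selection(topo))
        assert corr.matrix[0, 1] == pytest.approx(1.0)
        assert corr.matrix[0, 2] == pytest.approx(-1.0)

    def test_planted_blocks_recovered(self, four_block_system):
        topo, traj, truth = four_block_system
        corr = network.correlation_matrix(traj, full_selection(topo))
        assert np.max(np.abs(corr.matrix - truth.bead_correlation)) <= 0.02

    def test_symmetric_unit_diagonal_psd(self, four_block_system):
        topo, traj, truth = four_block_system
        corr = network.correlation_matrix(traj, full_selection(topo))
        np.testing.assert_array_equal(corr.matrix, corr.matrix.T)
        np.testing.assert_array_equal(np.diag(corr.matrix), 1.0)
        assert np.linalg.eigvalsh(corr.matrix).min() >= -1e-8

    def test_static_node_flagged_and_unlinked(self, rng):
        topo = ca_topology(3)
        frames = rng.normal(size=(30, 3, 3)) + np.array(
            [[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]]
        )
        frames[:, 2, :] = [8.0, 0.0, 0.0]  # node 2 static
        traj = make_trajectory(topo, frames)
        corr = network.correlation_matrix(traj, full_selection(topo))
        assert not corr.valid[2]
        adjacency = network.ContactAdjacency(
            corr.node_ids, ~np.eye(3, dtype=bool), np.ones((3, 3))
        )
        graph = network.build_network(adjacency, corr)
        assert graph.degree["A:3"] == 0


class TestContactAdjacency:
    def constant_distance_system(self, d01, n_frames=20):
        topo = ca_topology(3)
        coords = np.array([[0.0, 0, 0], [d01, 0, 0], [100.0, 0, 0]])
        frames = np.repeat(coords[None], n_frames, axis=0)
        return make_trajectory(topo, frames), topo

    def test_persistent_contact_is_edge(self):
        traj, topo = self.constant_distance_system(4.0)
        adj = network.contact_adjacency(
            traj, full_selection(topo), cutoff=4.5, min_fraction=0.75,
            neighbor_exclusion=0,
        )
        assert adj.adjacency[0, 1]

    def test_half_time_contact_is_no_edge(self):
        topo = ca_topology(2)
        frames = np.zeros((20, 2, 3))
        frames[:10, 1, 0] = 4.0   # in contact half the time
        frames[10:, 1, 0] = 20.0
        traj = make_trajectory(topo, frames)
        adj = network.contact_adjacency(
            traj, full_selection(topo), cutoff=4.5, min_fraction=0.75,
            neighbor_exclusion=0,
        )
        assert not adj.adjacency[0, 1]
        assert adj.contact_fraction[0, 1] == pytest.approx(0.5)

    def test_sequence_neighbors_excluded(self):
        traj, topo = self.constant_distance_system(4.0)
        adj = network.contact_adjacency(
            traj, full_selection(topo), cutoff=4.5, min_fraction=0.75,
            neighbor_exclusion=1,
        )
        assert not adj.adjacency[0, 1]  # residues 1 and 2 on the same chain


class TestEdgeWeights:
    def build(self, c):
        ids = ["A:1", "A:2"]
        corr = network.CorrelationMatrix(
            ids, np.array([[1.0, c], [c, 1.0]]), np.array([True, True])
        )
        adj = network.ContactAdjacency(
            ids, np.array([[False, True], [True, False]]), np.ones((2, 2))
        )
        return network.build_network(adj, corr)

    def test_perfect_correlation_zero_weight(self):
        graph = self.build(1.0)
        assert graph["A:1"]["A:2"]["weight"] == 0.0

    def test_half_correlation_log_two(self):
        graph = self.build(0.5)
        assert graph["A:1"]["A:2"]["weight"] == pytest.approx(np.log(2.0))

    def test_zero_correlation_clamped_finite(self):
        graph = self.build(0.0)
        assert graph["A:1"]["A:2"]["weight"] == pytest.approx(-np.log(1e-8))


def random_weighted_graph(rng, n=8, p=0.45):
    graph = nx.Graph()
    graph.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < p:
                c = rng.uniform(0.05, 1.0)
                graph.add_edge(
                    f"n{i}", f"n{j}", weight=-np.log(c), affinity=c, correlation=c
                )
    return graph


class TestOptimalPath:
    def test_single_edge(self):
        graph = nx.Graph()
        graph.add_edge("A", "B", weight=1.0, affinity=0.5)
        path = network.optimal_path(graph, "A", "B")
        assert path.nodes == ["A", "B"]
        assert path.total_weight == 1.0

    def test_triangle_prefers_two_cheap_hops(self):
        graph = nx.Graph()
        graph.add_edge("A", "B", weight=1.0)
        graph.add_edge("B", "C", weight=1.0)
        graph.add_edge("A", "C", weight=3.0)
        path = network.optimal_path(graph, "A", "C")
        assert path.nodes == ["A", "B", "C"]
        assert path.total_weight == pytest.approx(2.0)

    def test_matches_brute_force_on_random_graphs(self, rng):
        hits = 0
        for _ in range(100):
            graph = random_weighted_graph(rng)
            nodes = sorted(graph.nodes)
            s, t = nodes[0], nodes[-1]
            oracle_w, oracle_paths = brute_force_shortest(graph, s, t)
            result = network.optimal_path(graph, s, t)
            if not np.isfinite(oracle_w):
                assert not result.connected
                continue
            hits += 1
            assert result.total_weight == pytest.approx(oracle_w, abs=1e-9)
            assert result.nodes in oracle_paths
        assert hits > 50  # most random graphs connect source and target

    def test_disconnected_reports_no_path(self):
        graph = nx.Graph()
        graph.add_nodes_from(["A", "B"])
        result = network.optimal_path(graph, "A", "B")
        assert not result.connected
        assert np.isinf(result.total_weight)

    def test_missing_node_is_key_error(self):
        graph = nx.Graph()
        graph.add_edge("A", "B", weight=1.0)
        with pytest.raises(KeyError):
            network.optimal_path(graph, "A", "Z")


def clique_pair_graph(k=4, bridge_weight=2.0):
    """Two k-cliques joined by one bridge edge."""
    graph = nx.Graph()
    left = [f"L{i}" for i in range(k)]
    right = [f"R{i}" for i in range(k)]
    for group in (left, right):
        for i, u in enumerate(group):
            for v in group[i + 1 :]:
                graph.add_edge(u, v, weight=0.2, affinity=0.8)
    graph.add_edge(left[0], right[0], weight=bridge_weight, affinity=np.exp(-bridge_weight))
    return graph, left, right


class TestGirvanNewman:
    def test_two_cliques_split_at_bridge(self):
        graph, left, right = clique_pair_graph()
        partition = network.girvan_newman_communities(graph)
        communities = partition.communities()
        assert len(communities) == 2
        assert {frozenset(c) for c in communities} == {
            frozenset(left),
            frozenset(right),
        }

    def test_modularity_equals_exhaustive_search(self):
        """GN attains the global modularity optimum on small graphs."""
        graphs = [
            clique_pair_graph()[0],                       # 8 nodes, 2 blocks
            clique_pair_graph(k=3, bridge_weight=3.0)[0], # 6 nodes
        ]
        # three triangles in a ring (9 nodes)
        ring = nx.Graph()
        for b in range(3):
            nodes = [f"t{b}{i}" for i in range(3)]
            for i, u in enumerate(nodes):
                for v in nodes[i + 1 :]:
                    ring.add_edge(u, v, weight=0.2, affinity=0.8)
        for b in range(3):
            ring.add_edge(f"t{b}0", f"t{(b + 1) % 3}1", weight=3.0, affinity=0.05)
        graphs.append(ring)
        for graph in graphs:
            partition = network.girvan_newman_communities(graph)
            best_q, _ = exhaustive_best_modularity(graph)
            assert partition.modularity == pytest.approx(best_q, abs=1e-9)

    def test_uniform_clique_stays_one_community(self):
        graph = nx.complete_graph(5)
        graph = nx.relabel_nodes(graph, {i: f"n{i}" for i in range(5)})
        nx.set_edge_attributes(graph, 0.5, "affinity")
        nx.set_edge_attributes(graph, np.log(2.0), "weight")
        partition = network.girvan_newman_communities(graph)
        assert partition.n_communities == 1

    def test_edgeless_graph_singletons(self):
        graph = nx.Graph()
        graph.add_nodes_from(["A", "B", "C"])
        partition = network.girvan_newman_communities(graph)
        assert partition.n_communities == 3
        assert partition.modularity == 0.0

    def test_modularity_selection_matches_oracle_formula(self):
        graph, left, right = clique_pair_graph()
        partition = network.girvan_newman_communities(graph)
        oracle = weighted_modularity(graph, [set(left), set(right)])
        assert partition.modularity == pytest.approx(oracle, abs=1e-12)

    def test_planted_four_blocks_recovered(self, four_block_system):
        topo, traj, truth = four_block_system
        from sklearn.metrics import adjusted_rand_score

        nodes = full_selection(topo)
        corr = network.correlation_matrix(traj, nodes)
        adj = network.contact_adjacency(
            traj, nodes, cutoff=truth.annotations["contact_cutoff_A"],
            min_fraction=0.75,
        )
        graph = network.build_network(adj, corr)
        partition = network.girvan_newman_communities(graph)
        predicted = [partition.assignment[n] for n in truth.node_ids]
        planted = [truth.partition[n] for n in truth.node_ids]
        assert adjusted_rand_score(planted, predicted) == 1.0
        assert partition.n_communities == 4


class TestBetweennessOracle:
    def test_networkx_betweenness_matches_brute_force(self, rng):
        """The weighted edge betweenness our pipeline relies on agrees with
        an all-pairs path-enumeration oracle on small graphs."""
        for _ in range(10):
            graph = random_weighted_graph(rng, n=7, p=0.5)
            if graph.number_of_edges() == 0:
                continue
            oracle = brute_force_edge_betweenness(graph)
            result = nx.edge_betweenness_centrality(
                graph, weight="weight", normalized=False
            )
            for edge, value in result.items():
                assert value == pytest.approx(oracle[tuple(sorted(edge))], abs=1e-9)


class TestCriticalEdges:
    def test_bridge_is_unique_critical_edge(self):
        graph, left, right = clique_pair_graph()
        partition = network.girvan_newman_communities(graph)
        report = network.critical_edges(graph, partition)
        top = report.top_edges()
        assert len(top) == 1
        assert {top[0].node_a, top[0].node_b} == {"L0", "R0"}

    def test_parallel_edges_ranked_by_betweenness(self):
        """Of two parallel inter-community edges the lower-weight (cheaper,
        higher-traffic) one ranks first."""
        graph = nx.Graph()
        for i, u in enumerate(["L0", "L1", "L2"]):
            for v in ["L0", "L1", "L2"][i + 1 :]:
                graph.add_edge(u, v, weight=0.2, affinity=0.8)
        for i, u in enumerate(["R0", "R1", "R2"]):
            for v in ["R0", "R1", "R2"][i + 1 :]:
                graph.add_edge(u, v, weight=0.2, affinity=0.8)
        graph.add_edge("L0", "R0", weight=0.3, affinity=np.exp(-0.3))
        graph.add_edge("L1", "R1", weight=2.0, affinity=np.exp(-2.0))
        partition = network.CommunityPartition(
            {n: 0 if n.startswith("L") else 1 for n in graph.nodes}, 0.3
        )
        report = network.critical_edges(graph, partition)
        top = report.top_edges()[0]
        assert {top.node_a, top.node_b} == {"L0", "R0"}
        bt = brute_force_edge_betweenness(graph)
        assert bt[("L0", "R0")] > bt[("L1", "R1")]

    def test_single_community_empty_report(self):
        graph = nx.complete_graph(4)
        graph = nx.relabel_nodes(graph, {i: f"n{i}" for i in range(4)})
        nx.set_edge_attributes(graph, 1.0, "weight")
        partition = network.CommunityPartition({n: 0 for n in graph.nodes}, 0.0)
        report = network.critical_edges(graph, partition)
        assert report.edges == []


class TestPathCompare:
    def test_identical_graphs_equal(self):
        graph, _, _ = clique_pair_graph()
        cmp = network.path_length_compare(graph, graph, "L1", "R1")
        assert cmp.verdict == "equal"
        assert cmp.weight_difference == 0.0

    def test_edge_deletion_never_shortens(self, rng):
        for _ in range(20):
            graph = random_weighted_graph(rng)
            nodes = sorted(graph.nodes)
            s, t = nodes[0], nodes[-1]
            base = network.optimal_path(graph, s, t)
            if not base.connected or graph.number_of_edges() == 0:
                continue
            pruned = graph.copy()
            edge = sorted(pruned.edges)[int(rng.integers(pruned.number_of_edges()))]
            pruned.remove_edge(*edge)
            cmp = network.path_length_compare(graph, pruned, s, t)
            assert cmp.path_b.total_weight >= base.total_weight - 1e-12

    def test_detachment_severs_communication(self, preset_system, preset_map):
        """Post-detachment window: the interface contacts vanish and the
        545 -> R358 communication path lengthens (here: disconnects)."""
        from alloscope.structure import select_domain

        topo, traj, truth = preset_system
        idx = np.unique(
            np.concatenate(
                [
                    select_domain(topo, preset_map, n, "CA").atom_indices
                    for n in ("nSH2", "helical")
                ]
            )
        )
        nodes = ResidueSelection(idx, "interface", np.unique(topo.atom_resindex[idx]))
        cutoff = truth.annotations["contact_cutoff_A"]

        def graph_for(window):
            corr = network.correlation_matrix(traj, nodes, window)
            adj = network.contact_adjacency(
                traj, nodes, cutoff=cutoff, min_fraction=0.75, window=window
            )
            return network.build_network(adj, corr)

        closed = graph_for((100, 450))
        open_ = graph_for((800, 1000))
        cmp = network.path_length_compare(closed, open_, "A:545", "B:358")
        assert cmp.path_a.connected
        assert cmp.verdict == "longer"
        assert cmp.path_b.total_weight > cmp.path_a.total_weight
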