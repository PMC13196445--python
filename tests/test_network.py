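"""Co-occurrence networks, metrics, modularity and Louvain clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

from multimorb import (
    LouvainCommunities,
    build_network,
    louvain,
    modularity,
    network_metrics,
    sensitivity_sweep,
)
from multimorb.network import (
    CoOccurrenceNetwork,
    EmptyNetworkError,
    UndefinedModularityError,
    best_partition_exhaustive,
)


def two_cliques(k: int, bridge: float = 0.0) -> np.ndarray:
    n = 2 * k
    A = np.zeros((n, n))
    for i, j in itertools.combinations(range(k), 2):
        A[i, j] = A[j, i] = 1.0
        A[i + k, j + k] = A[j + k, i + k] = 1.0
    if bridge:
        A[0, k] = A[k, 0] = bridge
    return A


def random_weighted(rng, n, p=0.3):
    A = np.triu((rng.random((n, n)) < p) * rng.random((n, n)), 1)
    return A + A.T


class TestBuildNetwork:
    def hand_panel(self):
        # 10 participants, 3 conditions, hand-countable overlaps
        return pd.DataFrame(
            {
                "a": [1, 1, 1, 1, 0, 0, 0, 0, 1, np.nan],
                "b": [1, 1, 0, 0, 1, 0, 0, 0, np.nan, 1],
                "c": [0, 1, 0, 1, 0, 1, 0, 0, 1, 1],
            }
        )

    def test_joint_prevalence_weights_hand_counted(self):
        net = build_network(self.hand_panel(), min_node_prevalence=0.0, conditions=["a", "b", "c"])
        w = {(i, j): wt for i, j, wt in net.edges}
        assert w[("a", "b")] == pytest.approx(2 / 8)  # both observed in 8
        assert w[("a", "c")] == pytest.approx(3 / 9)
        assert w[("b", "c")] == pytest.approx(2 / 9)

    def test_jaccard_weights_hand_counted(self):
        net = build_network(self.hand_panel(), "jaccard", 0.0, conditions=["a", "b", "c"])
        w = {(i, j): wt for i, j, wt in net.edges}
        assert w[("a", "b")] == pytest.approx(2 / 5)  # |both|=2, |either among both-obs|=5
        assert w[("a", "c")] == pytest.approx(3 / 6)  # |both|=3, |either|=6

    def test_single_participant_jaccard_is_one(self):
        panel = pd.DataFrame({"a": [1.0], "b": [1.0]})
        net = build_network(panel, "jaccard", 0.0, conditions=["a", "b"])
        assert net.edges == (("a", "b", 1.0),)

    def test_nine_node_complete(self, designed_complete_panel):
        net = build_network(
            designed_complete_panel, min_node_prevalence=0.0,
            conditions=list(designed_complete_panel.columns),
        )
        assert len(net.nodes) == 9 and len(net.edges) == 36

    def test_prevalence_filter(self):
        panel = pd.DataFrame({"a": [1.0] * 9 + [0.0], "b": [1.0] + [0.0] * 9, "c": [1.0] * 10})
        net = build_network(panel, min_node_prevalence=0.2, conditions=["a", "b", "c"])
        assert net.nodes == ("a", "c")

    def test_empty_after_filter(self):
        panel = pd.DataFrame({"a": [0.0, 1.0]})
        with pytest.raises(EmptyNetworkError):
            build_network(panel, min_node_prevalence=0.9, conditions=["a"])

    def test_sub_threshold_edge_dropped(self):
        # 5 conditions; (d,e) co-occur in 1 of 200 participants -> 0.5% < 1%
        rows = []
        for _ in range(160):
            rows.append([1, 1, 1, 0, 0])
        for _ in range(39):
            rows.append([0, 0, 0, 1, 0])
        rows.append([0, 0, 0, 1, 1])
        panel = pd.DataFrame(rows, columns=list("abcde"), dtype=float)
        net0 = build_network(panel, min_node_prevalence=0.0, edge_threshold=0.0,
                             conditions=list("abcde"))
        net1 = build_network(panel, min_node_prevalence=0.0, edge_threshold=0.01,
                             conditions=list("abcde"))
        pairs0 = {(i, j) for i, j, _ in net0.edges}
        pairs1 = {(i, j) for i, j, _ in net1.edges}
        assert ("d", "e") in pairs0 and ("d", "e") not in pairs1

    def test_invariant_under_permutations(self, designed_complete_panel):
        panel = designed_complete_panel
        rng = np.random.default_rng(0)
        shuffled = panel.sample(frac=1.0, random_state=1)
        cols = list(panel.columns)
        rng.shuffle(cols)
        net_a = build_network(panel, min_node_prevalence=0.0, conditions=sorted(cols))
        net_b = build_network(shuffled[cols], min_node_prevalence=0.0, conditions=sorted(cols))
        assert set(net_a.edges) == set(net_b.edges)

    @given(hst.integers(0, 2**31 - 1))
    def test_joint_weight_bounded_by_marginals(self, seed):
        rng = np.random.default_rng(seed)
        panel = pd.DataFrame(
            rng.choice([0.0, 1.0, np.nan], size=(30, 4), p=[0.5, 0.4, 0.1]),
            columns=list("abcd"),
        )
        try:
            net = build_network(panel, min_node_prevalence=0.0, conditions=list("abcd"))
        except EmptyNetworkError:
            return
        # joint prevalence cannot exceed either pairwise-complete marginal
        M = panel.to_numpy()
        for i, j, w in net.edges:
            ci, cj = panel.columns.get_loc(i), panel.columns.get_loc(j)
            both = ~np.isnan(M[:, ci]) & ~np.isnan(M[:, cj])
            assert w <= min(np.nanmean(M[both, ci]), np.nanmean(M[both, cj])) + 1e-12


class TestMetrics:
    def test_complete_network(self, designed_complete_panel):
        net = build_network(designed_complete_panel, min_node_prevalence=0.0,
                            conditions=list(designed_complete_panel.columns))
        m = network_metrics(net)
        assert (m.n_nodes, m.n_edges, m.density, m.clustering_coefficient, m.diameter) == (
            9, 36, 1.0, 1.0, 1,
        )

    def test_three_node_path(self):
        net = CoOccurrenceNetwork(("a", "b", "c"), (("a", "b", 0.5), ("b", "c", 0.2)))
        m = network_metrics(net)
        assert m.density == pytest.approx(2 / 3)
        assert m.clustering_coefficient == 0.0
        assert m.diameter == 2

    def test_disconnected_reports_largest_component(self):
        net = CoOccurrenceNetwork(
            ("a", "b", "c", "d", "e"),
            (("a", "b", 1.0), ("b", "c", 1.0), ("d", "e", 1.0)),
        )
        m = network_metrics(net)
        assert not m.connected and m.diameter == 2

    def test_matches_networkx_on_random_graphs(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        for _ in range(25):
            A = random_weighted(rng, 12, 0.35)
            nodes = tuple(f"n{i}" for i in range(12))
            edges = tuple(
                (nodes[i], nodes[j], float(A[i, j]))
                for i, j in itertools.combinations(range(12), 2)
                if A[i, j] > 0
            )
            if not edges:
                continue
            net = CoOccurrenceNetwork(nodes, edges)
            m = network_metrics(net)
            G = net.to_networkx()
            assert m.density == pytest.approx(nx.density(G), abs=1e-12)
            assert m.clustering_coefficient == pytest.approx(nx.transitivity(G), abs=1e-12)
            if nx.is_connected(G):
                assert m.diameter == nx.diameter(G)
            else:
                comp = max(nx.connected_components(G), key=len)
                assert m.diameter == nx.diameter(G.subgraph(comp))


class TestModularity:
    def test_single_community_is_zero(self):
        rng = np.random.default_rng(1)
        A = random_weighted(rng, 8, 0.5)
        assert modularity(A, {i: 0 for i in range(8)}) == pytest.approx(0.0, abs=1e-12)

    def test_two_k3_cliques_half(self):
        A = two_cliques(3)
        part = {i: 0 if i < 3 else 1 for i in range(6)}
        assert modularity(A, part) == pytest.approx(0.5, abs=1e-12)

    def test_matches_library_oracles(self):
        import igraph as ig
        import networkx as nx

        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(4, 20))
            A = random_weighted(rng, n)
            if A.sum() == 0:
                continue
            labels = rng.integers(0, max(2, n // 3), n)
            mine = modularity(A, {i: int(c) for i, c in enumerate(labels)})
            G = nx.from_numpy_array(A)
            comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
            assert mine == pytest.approx(
                nx.community.modularity(G, comms, weight="weight"), abs=1e-10
            )
            g = ig.Graph.Weighted_Adjacency(A.tolist(), mode="undirected", attr="weight")
            assert mine == pytest.approx(
                g.modularity(list(labels), weights="weight"), abs=1e-10
            )

    def test_zero_weight_graph(self):
        with pytest.raises(UndefinedModularityError):
            modularity(np.zeros((3, 3)), {0: 0, 1: 0, 2: 0})


class TestLouvain:
    def test_two_disjoint_cliques_recovered(self):
        part = louvain(two_cliques(4), seed=0)
        assert part.n_communities == 2
        comms = {frozenset(range(4)), frozenset(range(4, 8))}
        assert set(part.communities()) == comms
        assert part.modularity == pytest.approx(0.5, abs=1e-12)

    def test_never_below_singleton_partition(self):
        rng = np.random.default_rng(6)
        for _ in range(15):
            A = random_weighted(rng, 12)
            if A.sum() == 0:
                continue
            singleton_q = modularity(A, {i: i for i in range(12)})
            assert louvain(A, seed=1).modularity >= singleton_q - 1e-12

    def test_matches_exhaustive_on_small_planted_graphs(self):
        fixtures = [two_cliques(3), two_cliques(4), two_cliques(3, 0.5), two_cliques(4, 0.2)]
        A = np.full((8, 8), 0.05)
        A[:4, :4] = 0.6
        A[4:, 4:] = 0.7
        np.fill_diagonal(A, 0)
        fixtures.append(A)
        for A in fixtures:
            _, best_q = best_partition_exhaustive(A)
            got = louvain(A, seed=3)
            assert got.modularity == pytest.approx(best_q, abs=1e-12)
            assert got.modularity >= modularity(A, {i: 0 for i in range(len(A))})

    def test_estimator_wrapper(self):
        est = LouvainCommunities(seed=5)
        labels = est.fit_predict(two_cliques(3))
        assert est.get_params() == {"resolution": 1.0, "seed": 5}
        assert len(set(labels)) == 2
        assert est.modularity_ == pytest.approx(0.5, abs=1e-12)

    def test_planted_block_recovery_stable(self):
        """Two planted condition blocks recovered identically over 20 seeds."""
        from multimorb import CohortSpec, generate_cohort_frame
        from multimorb.conditions import classify_cohort

        cohort = generate_cohort_frame(CohortSpec(n_participants=4000, seed=17))
        panel = classify_cohort(cohort)
        net = build_network(panel, min_node_prevalence=0.04)
        expected = {
            frozenset({"hypertension", "diabetes", "anaemia", "heart_disease", "ckd"}),
            frozenset({"resp_disease", "arthritis", "depression", "anxiety"}),
        }
        for seed in range(20):
            part = louvain(net, seed=seed)
            assert set(part.communities()) == expected


class TestSensitivitySweep:
    def test_edges_monotone_in_threshold(self, designed_complete_panel):
        sweep = sensitivity_sweep(
            designed_complete_panel,
            min_node_prevalence=0.0,
            conditions=list(designed_complete_panel.columns),
        )
        jp = sweep[sweep["scheme"] == "joint_prevalence"].sort_values("edge_threshold")
        assert (np.diff(jp["n_edges"].to_numpy()) <= 0).all()

    def test_jaccard_agrees_on_planted_blocks(self):
        from multimorb import CohortSpec, generate_cohort_frame
        from multimorb.conditions import classify_cohort

        cohort = generate_cohort_frame(CohortSpec(n_participants=4000, seed=17))
        panel = classify_cohort(cohort)
        sweep = sensitivity_sweep(panel, min_node_prevalence=0.04)
        jac = sweep[(sweep["scheme"] == "jaccard") & (sweep["edge_threshold"] == 0.0)]
        assert jac["ari_vs_primary"].iloc[0] == pytest.approx(1.0)
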