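"""Complex discovery: frozen outcomes on hand-analysable graphs, predicate
checks against exhaustive subgraph enumeration, determinism, equivariance,
and planted-clique recovery."""

import networkx as nx
import pytest

from netfactor import (
    Clustering,
    DPClusParams,
    IPCAParams,
    SyntheticSpec,
    cluster_stats,
    coach,
    dpclus,
    generate_planted_network,
    ipca,
    match_score,
    mcode,
    neighbourhood_affinity,
)
from netfactor.complexes import (
    ALGORITHMS,
    _mcode_vertex_weights,
    density,
)

from conftest import connected_subsets, subgraph_density


def member_sets(clustering):
    return [set(m) for m in clustering.member_sets()]


class TestMCODE:
    def test_unique_dense_component_is_the_k5(self, k5_with_isolates):
        assert member_sets(mcode(k5_with_isolates)) == [
            {"A0", "A1", "A2", "A3", "A4"}
        ]

    def test_edgeless_graph_gives_empty_clustering(self):
        g = nx.empty_graph(4)
        assert len(mcode(g)) == 0

    def test_bridged_k4s_contain_every_maximal_dense_subgraph(
            self, bridged_k4s):
        """All vertices of two bridged K4s share the same k-core weight, so
        seeded growth crosses the bridge; the emitted clustering must still
        cover every maximal >=0.9-density subgraph found by exhaustive
        enumeration (here: the two K4s)."""
        dense = [s for s in connected_subsets(bridged_k4s, min_size=3)
                 if subgraph_density(bridged_k4s, s) >= 0.9]
        maximal = [s for s in dense
                   if not any(s < t for t in dense)]
        assert sorted(map(sorted, maximal)) == [
            ["a0", "a1", "a2", "a3"], ["b0", "b1", "b2", "b3"]]
        clusters = member_sets(mcode(bridged_k4s))
        assert clusters == [set(bridged_k4s.nodes)]
        for m in maximal:
            assert any(m <= c for c in clusters)

    def test_haircut_leaves_no_degree_one_members(self, k4_with_pendants):
        for _, members in mcode(k4_with_pendants):
            sub = k4_with_pendants.subgraph(members)
            assert min(dict(sub.degree).values()) >= 2


class TestDPClus:
    def test_triangle_is_one_cluster(self):
        g = nx.Graph([("x", "y"), ("y", "z"), ("x", "z")])
        assert member_sets(dpclus(g)) == [{"x", "y", "z"}]

    def test_shared_vertex_k4s_both_recovered_with_overlap(
            self, shared_vertex_k4s):
        clusters = member_sets(dpclus(shared_vertex_k4s))
        assert {"a", "b", "c", "s"} in clusters
        assert {"d", "e", "f", "s"} in clusters
        in_both = [c for c in clusters if "s" in c]
        assert len(in_both) >= 2  # the shared vertex overlaps

    def test_star_has_no_cluster_of_size_three(self, star6):
        """Exhaustive enumeration: no connected subgraph of a star with >= 3
        nodes has density >= 0.9, so emitted clusters are all pairs."""
        assert not [
            s for s in connected_subsets(star6, min_size=3)
            if subgraph_density(star6, s) >= 0.9
        ]
        clusters = member_sets(dpclus(star6))
        assert clusters and all(len(c) == 2 for c in clusters)

    def test_bridged_k4s_recovered(self, bridged_k4s):
        clusters = member_sets(dpclus(bridged_k4s))
        assert {"a0", "a1", "a2", "a3"} in clusters
        assert {"b0", "b1", "b2", "b3"} in clusters

    def test_partition_mode_yields_disjoint_clusters(self, shared_vertex_k4s):
        clusters = member_sets(
            dpclus(shared_vertex_k4s, DPClusParams(mode="partition"))
        )
        seen = set()
        for c in clusters:
            assert not (c & seen)
            seen |= c


class TestIPCA:
    def test_k4_alone_is_one_cluster(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"k{i}" for i in g})
        assert {"k0", "k1", "k2", "k3"} in member_sets(ipca(g))

    def test_path_has_no_size4_cluster(self, path8):
        """Brute force: every connected P8 subgraph of >= 4 nodes fails the
        IP >= 0.5 growth rule, so nothing of size >= 4 is emitted."""
        assert member_sets(ipca(path8, IPCAParams(min_size=4))) == []

    def test_bridged_k5s_recovered_and_diameter_bounded(self, bridged_k5s):
        clusters = member_sets(ipca(bridged_k5s))
        assert {"g0", "g1", "g2", "g3", "g4"} in clusters
        assert {"g5", "g6", "g7", "g8", "g9"} in clusters
        for c in clusters:
            assert nx.diameter(bridged_k5s.subgraph(c)) <= 2


class TestCOACH:
    def test_k6_single_complex_all_core(self):
        g = nx.relabel_nodes(nx.complete_graph(6),
                             {i: f"k{i}" for i in range(6)})
        clustering = coach(g)
        assert member_sets(clustering) == [set(g.nodes)]
        assert clustering.meta["coach_1"]["core"] == frozenset(g.nodes)

    def test_pendants_attached_to_k4_core(self, k4_with_pendants):
        """Each pendant touches 3 of the core's nodes, 3 > 0.5*|core|, so the
        complex is all 6 nodes (rule evaluated directly as the oracle)."""
        clustering = coach(k4_with_pendants)
        assert len(clustering) == 1
        name, members = clustering.clusters[0]
        core = clustering.meta[name]["core"]
        # direct independent evaluation of the attachment rule
        expected = set(core)
        for u in set(k4_with_pendants) - set(core):
            if len(set(k4_with_pendants[u]) & set(core)) > 0.5 * len(core):
                expected.add(u)
        assert set(members) == expected == set(k4_with_pendants.nodes)

    def test_edgeless_graph_gives_empty_clustering(self):
        assert len(coach(nx.empty_graph(5))) == 0


ALL_FIXTURES = ["k5_with_isolates", "bridged_k4s", "bridged_k5s",
                "shared_vertex_k4s", "star6", "path8", "k4_with_pendants"]


class TestAlgorithmInvariants:
    @pytest.mark.parametrize("fixture", ALL_FIXTURES)
    @pytest.mark.parametrize("algo", sorted(ALGORITHMS))
    def test_emitted_clusters_satisfy_predicates(self, fixture, algo, request):
        """Every emitted cluster is connected, meets its algorithm's size
        minimum and density/diameter constraint, as cross-checked by
        exhaustive enumeration of connected subgraphs."""
        graph = request.getfixturevalue(fixture)
        clustering = ALGORITHMS[algo](graph)
        min_size = clustering.params["min_size"]
        admissible = set(connected_subsets(graph, min_size=min_size))
        weights = _mcode_vertex_weights(graph) if algo == "mcode" else None
        for name, members in clustering:
            assert frozenset(members) in admissible  # connected, big enough
            if algo == "dpclus":
                assert (subgraph_density(graph, members)
                        >= clustering.params["d_min"])
            elif algo == "ipca":
                assert (nx.diameter(graph.subgraph(members))
                        <= clustering.params["d_max"])
            elif algo == "coach":
                core = clustering.meta[name]["core"]
                assert (subgraph_density(graph, core)
                        >= clustering.params["core_density"])
            elif algo == "mcode":
                top = max(weights[v] for v in members)
                threshold = (1 - clustering.params["vwp"]) * top
                assert all(weights[v] >= threshold for v in members)

    @pytest.mark.parametrize("fixture", ALL_FIXTURES)
    @pytest.mark.parametrize("algo", sorted(ALGORITHMS))
    def test_deterministic_across_runs(self, fixture, algo, request):
        graph = request.getfixturevalue(fixture)
        a = ALGORITHMS[algo](graph)
        b = ALGORITHMS[algo](graph)
        assert a.names == b.names
        assert a.member_sets() == b.member_sets()

    @pytest.mark.parametrize("fixture", ALL_FIXTURES)
    @pytest.mark.parametrize("algo", sorted(ALGORITHMS))
    def test_order_preserving_relabel_equivariance(self, fixture, algo,
                                                   request):
        """Prefixing every identifier preserves the documented id-order
        tie-break, so clustering commutes with the relabeling."""
        graph = request.getfixturevalue(fixture)
        relabeled = nx.relabel_nodes(graph, {v: f"z{v}" for v in graph})
        direct = ALGORITHMS[algo](relabeled).member_sets()
        mapped = [frozenset(f"z{v}" for v in m)
                  for m in ALGORITHMS[algo](graph).member_sets()]
        assert direct == mapped

    @pytest.mark.parametrize("algo", sorted(ALGORITHMS))
    def test_planted_cliques_all_recovered(self, algo):
        """On disjoint planted cliques (p_in=1, p_out=0) every algorithm
        recovers every planted complex with NA >= 0.9."""
        spec = SyntheticSpec(
            n_genes=120, n_complexes=6, complex_size_range=(4, 8),
            overlap_fraction=0.0, p_in=1.0, p_out=0.0, seed=5,
        )
        graph, truth = generate_planted_network(spec)
        found = ALGORITHMS[algo](graph).member_sets()
        for planted in truth.member_sets():
            assert any(
                neighbourhood_affinity(planted, c) >= 0.9 for c in found
            ), f"{algo} missed planted complex of size {len(planted)}"


class TestClusterStats:
    def test_small_example_counts(self):
        clustering = Clustering(
            clusters=[("c1", {"a", "b", "c"}),
                      ("c2", {"d", "e", "f", "g", "h"})]
        )
        stats = cluster_stats(clustering)
        assert (stats.n_clusters, stats.max_size, stats.min_size,
                stats.mean_size) == (2, 5, 3, 4.0)

    def test_empty_clustering_reports_zeros(self):
        stats = cluster_stats(Clustering(clusters=[]))
        assert (stats.n_clusters, stats.max_size, stats.min_size,
                stats.mean_size) == (0, 0, 0, 0.0)


class TestMatchScore:
    def test_identical_clusterings_score_one(self):
        c = Clustering(clusters=[("a", {"x", "y"}), ("b", {"z", "w"})])
        assert match_score(c, c, omega=0.9) == (1.0, 1.0, 1.0)

    def test_disjoint_clusterings_score_zero(self):
        a = Clustering(clusters=[("a", {"x", "y"})])
        b = Clustering(clusters=[("b", {"z", "w"})])
        assert match_score(a, b, omega=0.25) == (0.0, 0.0, 0.0)

    def test_empty_reference_errors(self):
        a = Clustering(clusters=[("a", {"x"})])
        with pytest.raises(ValueError, match="reference"):
            match_score(a, Clustering(clusters=[]))

    def test_matches_all_pairs_bruteforce(self, rng):
        universe = [f"n{i}" for i in range(20)]
        def random_clustering(tag, n):
            return Clustering(clusters=[
                (f"{tag}{i}",
                 frozenset(rng.choice(universe,
                                      size=rng.integers(2, 6),
                                      replace=False)))
                for i in range(n)
            ])
        pred, ref = random_clustering("p", 6), random_clustering("r", 4)
        omega = 0.3
        # brute-force all-pairs NA oracle
        def na(a, b):
            return len(a & b) ** 2 / (len(a) * len(b))
        pm = sum(any(na(p, r) >= omega for r in ref.member_sets())
                 for p in pred.member_sets())
        rm = sum(any(na(p, r) >= omega for p in pred.member_sets())
                 for r in ref.member_sets())
        precision, recall, f = match_score(pred, ref, omega=omega)
        assert precision == pm / 6 and recall == rm / 4
        expected_f = (0.0 if precision + recall == 0
                      else 2 * precision * recall / (precision + recall))
        assert f == pytest.approx(expected_f)


def test_density_convention_single_node():
    g = nx.empty_graph(1)
    assert density(g) == 1.0
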