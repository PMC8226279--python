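import itertools

import networkx as nx
import numpy as np
import pytest

from tenet import ssn
from tenet.model import AlignmentHit, TECopy
from tests.conftest import make_copy


def hit(q, s, bits, evalue=1e-40):
    return AlignmentHit(q, s, 95.0, 400, 1, 400, 1, 400, evalue, bits)


@pytest.fixture
def three_copies():
    return [make_copy("a"), make_copy("b"), make_copy("c", family="famB")]


class TestBuildSSN:
    def test_bidirectional_hits_symmetrised_by_max(self, three_copies):
        net = ssn.build_ssn([hit("a", "b", 200.0), hit("b", "a", 180.0)],
                            three_copies)
        assert net.number_of_edges() == 1
        assert net["a"]["b"]["weight"] == 200.0

    def test_repeat_hits_collapse_to_max(self, three_copies):
        net = ssn.build_ssn([hit("a", "b", 50.0), hit("a", "b", 90.0),
                             hit("a", "b", 70.0)], three_copies)
        assert net["a"]["b"]["weight"] == 90.0

    def test_length_filter_removes_node(self):
        copies = [make_copy("short", length=400), make_copy("long", length=600)]
        net = ssn.build_ssn([hit("short", "long", 100.0)], copies,
                            min_copy_length=500)
        assert set(net.nodes) == {"long"}
        assert net.number_of_edges() == 0

    def test_evalue_filter(self, three_copies):
        net = ssn.build_ssn([hit("a", "b", 100.0, evalue=1e-10)], three_copies,
                            max_evalue=1e-30)
        assert net.number_of_edges() == 0

    def test_isolated_copies_kept_as_degree_zero_nodes(self, three_copies):
        net = ssn.build_ssn([hit("a", "b", 100.0)], three_copies)
        assert "c" in net.nodes and net.degree("c") == 0

    def test_unknown_copy_reference_is_error(self, three_copies):
        with pytest.raises(ValueError, match="ghost"):
            ssn.build_ssn([hit("a", "ghost", 100.0)], three_copies)

    def test_edge_count_bounded_by_distinct_pairs(self, ssn_copies, ssn_hitset):
        net = ssn.build_ssn(ssn_hitset.hits, ssn_copies)
        pairs = {frozenset((h.query_id, h.subject_id)) for h in ssn_hitset.hits}
        assert net.number_of_edges() <= len(pairs)

    def test_node_attributes_set_everywhere(self, ssn_copies, ssn_hitset):
        net = ssn.build_ssn(ssn_hitset.hits, ssn_copies)
        for _, data in net.nodes(data=True):
            assert {"genome_id", "family", "superfamily", "has_dde3",
                    "cryptic_hit"} <= set(data)


def two_cliques(k=6, bridge_weight=1.0, clique_weight=10.0):
    net = nx.Graph()
    left = [f"L{i}" for i in range(k)]
    right = [f"R{i}" for i in range(k)]
    for group in (left, right):
        for a, b in itertools.combinations(group, 2):
            net.add_edge(a, b, weight=clique_weight)
    net.add_edge(left[0], right[0], weight=bridge_weight)
    return net, left, right


def best_bipartition_modularity(net):
    """Oracle: exhaustively score every 2-part (and the 1-part) partition."""
    nodes = sorted(net.nodes)
    best, best_parts = -1.0, None
    for mask in range(2 ** (len(nodes) - 1)):  # fix node 0 in part A
        a = {nodes[0]}
        b = set()
        for i, node in enumerate(nodes[1:]):
            (a if (mask >> i) & 1 else b).add(node)
        parts = [p for p in (a, b) if p]
        q = nx.community.modularity(net, parts, weight="weight")
        if q > best:
            best, best_parts = q, parts
    return best, best_parts


class TestLouvain:
    def test_recovers_planted_cliques_and_maximises_bipartition_modularity(self):
        net, left, right = two_cliques()
        part = ssn.louvain_partition(net, seed=0)
        clusters = sorted(part.clusters().values(), key=lambda s: sorted(s)[0])
        assert clusters == [set(left), set(right)]
        oracle_q, oracle_parts = best_bipartition_modularity(net)
        assert part.modularity == pytest.approx(oracle_q)
        assert sorted(map(sorted, oracle_parts)) == sorted(map(sorted, clusters))

    def test_edgeless_network_gives_singletons(self):
        net = nx.Graph()
        net.add_nodes_from("abcde")
        part = ssn.louvain_partition(net)
        assert part.n_clusters == 5

    def test_empty_network(self):
        assert len(ssn.louvain_partition(nx.Graph())) == 0

    def test_deterministic_for_fixed_seed(self, ssn_copies, ssn_hitset):
        net = ssn.build_ssn(ssn_hitset.hits, ssn_copies)
        p1 = ssn.louvain_partition(net, seed=3)
        p2 = ssn.louvain_partition(net, seed=3)
        assert p1.mapping == p2.mapping and p1.modularity == p2.modularity

    def test_modularity_nonnegative_on_planted_graph(self):
        net, _, _ = two_cliques()
        assert ssn.louvain_partition(net).modularity >= 0

    def test_each_cluster_within_one_component(self, ssn_copies, ssn_hitset):
        net = ssn.build_ssn(ssn_hitset.hits, ssn_copies)
        louvain = ssn.louvain_partition(net, seed=0)
        comps = ssn.component_partition(net)
        for members in louvain.clusters().values():
            assert len({comps.mapping[n] for n in members}) == 1


def components_oracle(net):
    """Brute-force transitive closure on an adjacency matrix."""
    nodes = sorted(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    reach = np.eye(len(nodes), dtype=bool)
    for a, b in net.edges:
        reach[index[a], index[b]] = reach[index[b], index[a]] = True
    for _ in range(len(nodes)):
        reach = reach | (reach @ reach)
    return len({tuple(row) for row in reach})


class TestComponents:
    def test_two_disjoint_triangles(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                        ("x", "y"), ("y", "z"), ("x", "z")])
        assert ssn.component_partition(net).n_clusters == 2

    def test_path_is_one_component(self):
        net = nx.Graph([("a", "b"), ("b", "c")])
        assert ssn.component_partition(net).n_clusters == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        net = nx.gnp_random_graph(40, 0.05, seed=seed)
        assert ssn.component_partition(net).n_clusters == components_oracle(net)

    def test_refines_no_edges(self, ssn_copies, ssn_hitset):
        net = ssn.build_ssn(ssn_hitset.hits, ssn_copies)
        part = ssn.component_partition(net)
        for a, b in net.edges:
            assert part.mapping[a] == part.mapping[b]


def rand_oracle(p1, p2):
    nodes = sorted(p1.mapping)
    agree = total = 0
    for a, b in itertools.combinations(nodes, 2):
        total += 1
        same1 = p1.mapping[a] == p1.mapping[b]
        same2 = p2.mapping[a] == p2.mapping[b]
        agree += same1 == same2
    return agree / total


def make_partition(assignment, method="test"):
    return ssn.Partition(mapping=assignment, method=method)


class TestRandIndex:
    def test_identical_partitions(self):
        p = make_partition({"a": 0, "b": 0, "c": 1})
        assert ssn.rand_index(p, p) == 1.0

    def test_textbook_half_agreement(self):
        p1 = make_partition({"a": 0, "b": 0, "c": 1, "d": 1})
        p2 = make_partition({"a": 0, "b": 1, "c": 1, "d": 1})
        assert ssn.rand_index(p1, p2) == pytest.approx(0.5)
        assert rand_oracle(p1, p2) == pytest.approx(0.5)

    def test_mismatched_node_sets_rejected(self):
        p1 = make_partition({"a": 0, "b": 0})
        p2 = make_partition({"a": 0, "c": 0})
        with pytest.raises(ValueError):
            ssn.rand_index(p1, p2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_enumeration_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(60)]
        p1 = make_partition({n: int(rng.integers(0, 5)) for n in nodes})
        p2 = make_partition({n: int(rng.integers(0, 4)) for n in nodes})
        expected = rand_oracle(p1, p2)
        assert ssn.rand_index(p1, p2) == pytest.approx(expected)
        assert ssn.rand_index(p2, p1) == pytest.approx(expected)  # symmetry
        from sklearn.metrics import rand_score
        labels1 = [p1.mapping[n] for n in nodes]
        labels2 = [p2.mapping[n] for n in nodes]
        assert ssn.rand_index(p1, p2) == pytest.approx(rand_score(labels1, labels2))

    def test_one_iff_identical(self):
        rng = np.random.default_rng(9)
        nodes = [f"n{i}" for i in range(30)]
        p1 = make_partition({n: int(rng.integers(0, 3)) for n in nodes})
        p2 = make_partition(dict(p1.mapping))
        assert ssn.rand_index(p1, p2) == 1.0
        changed = dict(p1.mapping)
        changed[nodes[0]] = max(changed.values()) + 1
        assert ssn.rand_index(p1, make_partition(changed)) < 1.0


class TestConnectivityByFlag:
    def test_clique_vs_isolated(self):
        copies = [make_copy(f"c{i}") for i in range(20)] + \
            [make_copy(f"iso{i}") for i in range(5)]
        hits = [hit(f"c{i}", f"c{j}", 100.0)
                for i, j in itertools.combinations(range(20), 2)]
        net = ssn.build_ssn(hits, copies)
        ssn.flag_nodes(net, "has_dde3", [f"c{i}" for i in range(20)])
        flagged, unflagged, result = ssn.connectivity_by_flag(net, "has_dde3")
        assert set(flagged) == {19} and set(unflagged) == {0}
        assert result.p_value < 0.05

    def test_identical_distributions_p_one(self):
        copies = [make_copy(f"c{i}") for i in range(4)]
        net = ssn.build_ssn([hit("c0", "c1", 50.0), hit("c2", "c3", 50.0)],
                            copies)
        ssn.flag_nodes(net, "has_dde3", ["c0", "c1"])
        _, _, result = ssn.connectivity_by_flag(net, "has_dde3")
        assert result.p_value == 1.0

    def test_empty_group_rejected(self):
        copies = [make_copy("c0"), make_copy("c1")]
        net = ssn.build_ssn([hit("c0", "c1", 50.0)], copies)
        ssn.flag_nodes(net, "has_dde3", ["c0", "c1"])
        with pytest.raises(ValueError):
            ssn.connectivity_by_flag(net, "has_dde3")

    def test_weighted_degree_option(self):
        copies = [make_copy(f"c{i}") for i in range(4)]
        net = ssn.build_ssn([hit("c0", "c1", 200.0), hit("c2", "c3", 50.0)],
                            copies)
        ssn.flag_nodes(net, "has_dde3", ["c0", "c1"])
        flagged, unflagged, _ = ssn.connectivity_by_flag(net, "has_dde3",
                                                         weighted=True)
        assert set(flagged) == {200.0} and set(unflagged) == {50.0}


class TestClusterComposition:
    def test_mixed_flag(self):
        copies = [make_copy(f"t{i}", family="Tc1") for i in range(3)] + \
            [make_copy(f"f{i}", family="Fot1") for i in range(3)] + \
            [make_copy(f"o{i}", family="Other") for i in range(2)]
        hits = [hit(a, b, 100.0) for a, b in
                itertools.combinations([c.copy_id for c in copies[:6]], 2)]
        hits.append(hit("o0", "o1", 100.0))
        net = ssn.build_ssn(hits, copies)
        part = ssn.component_partition(net)
        table = ssn.cluster_composition(net, part)
        assert list(table.n_nodes) == sorted(table.n_nodes, reverse=True)
        top = table.iloc[0]
        assert top.n_nodes == 6 and top.n_subfamilies == 2 and top.mixed
        assert not table.iloc[1].mixed

    def test_histogram_matches_brute_force(self, ssn_copies, ssn_hitset):
        net = ssn.build_ssn(ssn_hitset.hits, ssn_copies)
        part = ssn.louvain_partition(net, seed=0)
        table = ssn.cluster_composition(net, part)
        fam_of = {c.copy_id: c.family for c in ssn_copies}
        for row in table.itertuples():
            members = part.clusters()[row.cluster_id]
            assert row.n_subfamilies == len({fam_of[m] for m in members})
            assert row.n_nodes == len(members)


class TestCrypticHitEnrichment:
    def build(self):
        copies = [make_copy(f"in{i}") for i in range(10)] + \
            [make_copy(f"out{i}", family="famB") for i in range(20)]
        hits = [hit(a, b, 100.0) for a, b in
                itertools.combinations([f"in{i}" for i in range(10)], 2)]
        hits += [hit(a, b, 100.0) for a, b in
                 itertools.combinations([f"out{i}" for i in range(20)], 2)]
        net = ssn.build_ssn(hits, copies)
        return net, ssn.component_partition(net)

    def test_proportions_and_significance(self):
        net, part = self.build()
        cluster_of_in = part.mapping["in0"]
        flagged = [f"in{i}" for i in range(8)] + ["out0"]
        ssn.flag_nodes(net, "cryptic_hit", flagged)
        result = ssn.cryptic_hit_enrichment(net, part, cluster_of_in)
        assert result["in_cluster_proportion"] == pytest.approx(8 / 10)
        assert result["out_cluster_proportion"] == pytest.approx(1 / 20)
        assert result["test"].p_value < 0.001

    def test_all_flagged_gives_p_one(self):
        net, part = self.build()
        ssn.flag_nodes(net, "cryptic_hit", list(net.nodes))
        result = ssn.cryptic_hit_enrichment(net, part, part.mapping["in0"])
        assert result["in_cluster_proportion"] == 1.0
        assert result["out_cluster_proportion"] == 1.0
        assert result["test"].p_value == 1.0

    def test_unknown_cluster_rejected(self):
        net, part = self.build()
        with pytest.raises(ValueError):
            ssn.cryptic_hit_enrichment(net, part, 999)


class TestClusterPersistence:
    def test_identical_partitions(self):
        p = make_partition({"a": 0, "b": 0, "c": 1})
        result = ssn.cluster_persistence(p, p, 0)
        assert result["jaccard"] == 1.0 and result["persists"]

    def test_even_split_gives_half(self):
        before = make_partition({c: 0 for c in "abcd"})
        after = make_partition({"a": 0, "b": 0, "c": 1, "d": 1})
        result = ssn.cluster_persistence(before, after, 0)
        assert result["jaccard"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_best_overlap(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(40)]
        before = make_partition({n: int(rng.integers(0, 4)) for n in nodes})
        after = make_partition({n: int(rng.integers(0, 5)) for n in nodes})
        target = before.clusters()[0]
        best = max(len(target & members) / len(target | members)
                   for members in after.clusters().values())
        assert ssn.cluster_persistence(before, after, 0)["jaccard"] == \
            pytest.approx(best)
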