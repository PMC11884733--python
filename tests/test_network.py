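import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrnp import (
    Clone,
    Repertoire,
    build_network,
    cluster_properties,
    find_clusters,
    levenshtein,
    read_repertoire,
    repertoire_properties,
    simulate_toy_repertoire,
)
from tcrnp.network import RepertoireFormatError


def dp_levenshtein(a, b):
    """Independent full-table dynamic-programming oracle."""
    d = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
    d[:, 0] = np.arange(len(a) + 1)
    d[0, :] = np.arange(len(b) + 1)
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            d[i, j] = min(
                d[i - 1, j] + 1,
                d[i, j - 1] + 1,
                d[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(d[-1, -1])


seqs = st.text(alphabet="ACDG", min_size=0, max_size=8)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ("CASS", "CASS", 0),
            ("CAT", "CAST", 1),
            ("kitten", "sitting", 3),
            ("", "AC", 2),
            ("A", "", 1),
        ],
    )
    def test_examples(self, a, b, expect):
        assert levenshtein(a, b) == expect

    @settings(max_examples=150, derandomize=True)
    @given(a=seqs, b=seqs, c=seqs)
    def test_metric_axioms_and_oracle(self, a, b, c):
        d = levenshtein(a, b)
        assert d == dp_levenshtein(a, b)
        assert d == levenshtein(b, a)
        assert (d == 0) == (a == b)
        assert d <= levenshtein(a, c) + levenshtein(c, b)


class TestBuildNetwork:
    def test_simple_edges_and_components(self):
        rep = Repertoire("p", [Clone("CASS"), Clone("CASA"), Clone("WWWW")])
        net = build_network(rep)
        assert set(map(frozenset, net.edges)) == {frozenset({"CASS", "CASA"})}
        comps = find_clusters(net, min_size=1)
        assert {frozenset(c) for c in comps} == {
            frozenset({"CASS", "CASA"}),
            frozenset({"WWWW"}),
        }

    def test_single_sequence(self):
        net = build_network(Repertoire("p", [Clone("CASS")]))
        assert len(net.nodes) == 1 and len(net.edges) == 0

    @pytest.mark.parametrize("max_dist", [1, 2])
    def test_matches_exhaustive_oracle(self, rng, max_dist):
        rep = simulate_toy_repertoire(50, seq_length=8, mutation_rate=0.5, rng=rng)
        net = build_network(rep, max_dist=max_dist)
        seqs = [c.sequence for c in rep.clones]
        expected = {
            frozenset({a, b})
            for i, a in enumerate(seqs)
            for b in seqs[i + 1 :]
            if dp_levenshtein(a, b) <= max_dist
        }
        assert set(map(frozenset, net.edges)) == expected

    def test_node_order_invariance(self, path_repertoire):
        t1 = repertoire_properties(path_repertoire)
        rev = Repertoire(path_repertoire.patient_id, path_repertoire.clones[::-1])
        t2 = repertoire_properties(rev)
        f1, f2 = t1.to_frame(), t2.to_frame()
        assert f1.equals(f2)


class TestFindClusters:
    def test_discards_singletons(self, path_repertoire):
        net = build_network(path_repertoire)
        clusters = find_clusters(net)  # min_size=2
        assert len(clusters) == 1
        assert clusters[0] == {"CASSA", "CASSB", "CBSSB"}

    def test_fully_disconnected(self):
        rep = Repertoire("p", [Clone(s) for s in ("AAAA", "CCCC", "DDDD", "GGGG", "HHHH")])
        net = build_network(rep)
        assert find_clusters(net, min_size=2) == []
        assert len(find_clusters(net, min_size=1)) == 5

    def test_stable_order(self, rng):
        rep = simulate_toy_repertoire(60, mutation_rate=0.6, rng=rng)
        net = build_network(rep)
        clusters = find_clusters(net)
        sizes = [len(c) for c in clusters]
        assert sizes == sorted(sizes, reverse=True)


class TestClusterProperties:
    def test_two_node_na_rule(self):
        rep = Repertoire("p", [Clone("CASS", 5, 1), Clone("CASA", 3, 2)])
        net = build_network(rep)
        rec = cluster_properties({"CASS", "CASA"}, net, rep)
        assert math.isnan(rec.assortativity)
        assert math.isnan(rec.transitivity)
        assert math.isnan(rec.closeness_centralization)
        assert math.isnan(rec.central_eigen)
        # the remaining properties are all defined
        assert rec.density == 1.0
        assert rec.degree_centralization == 0.0
        assert rec.diameter_length == 1.0
        assert rec.count_baseline == 8 and rec.count_post == 3

    def test_triangle(self):
        rep = Repertoire("p", [Clone("CASA"), Clone("CASC"), Clone("CASD")])
        net = build_network(rep)
        rec = cluster_properties({"CASA", "CASC", "CASD"}, net, rep)
        assert rec.density == 1.0
        assert rec.transitivity == 1.0
        assert rec.diameter_length == 1.0
        assert rec.degree_centralization == 0.0
        # leading eigenvalue of K3 is 2
        assert rec.eigen_centrality_value == pytest.approx(2.0)

    def test_path_graph_hand_values(self, path_repertoire):
        net = build_network(path_repertoire)
        rec = cluster_properties({"CASSA", "CASSB", "CBSSB"}, net, path_repertoire)
        assert rec.density == pytest.approx(2 / 3)
        assert rec.diameter_length == 2.0
        assert rec.transitivity == 0.0
        # degree pairs over directed edges: (1,2),(2,1),(2,1),(1,2) -> r = -1
        assert rec.assortativity == pytest.approx(-1.0)
        # Freeman: sum(2 - d_i) / ((n-1)(n-2)) = 2/2
        assert rec.degree_centralization == pytest.approx(1.0)
        # leading eigenvalue of the 3-path is sqrt(2)
        assert rec.eigen_centrality_value == pytest.approx(math.sqrt(2))
        # P3 attains both the closeness and eigenvector star maxima at n=3
        assert rec.closeness_centralization == pytest.approx(1.0)
        assert rec.central_eigen == pytest.approx(1.0)

    def test_complete_graph_leading_eigenvalue(self, rng):
        # same-length single-substitution ball: all pairwise distance <= 2
        base = "CASSLG"
        seqs = [base] + [base[:2] + c + base[3:] for c in "ADEF"]
        rep = Repertoire("p", [Clone(s) for s in seqs])
        net = build_network(rep, max_dist=2)
        rec = cluster_properties(set(seqs), net, rep)
        n = len(seqs)
        assert rec.density == 1.0
        assert rec.eigen_centrality_value == pytest.approx(n - 1)

    def test_disconnected_input_rejected(self, path_repertoire):
        net = build_network(path_repertoire)
        with pytest.raises(ValueError):
            cluster_properties({"CASSA", "WWWWWWWW"}, net, path_repertoire)

    def test_invariant_bounds(self, rng):
        rep = simulate_toy_repertoire(80, mutation_rate=0.7, rng=rng)
        table = repertoire_properties(rep)
        for rec in table.records:
            assert 0 < rec.density <= 1
            assert math.isnan(rec.transitivity) or 0 <= rec.transitivity <= 1
            assert rec.diameter_length <= rec.node_count - 1


class TestReadRepertoire:
    def test_row_count_preserved(self, tmp_path):
        f = tmp_path / "rep.csv"
        f.write_text("junction_aa,duplicate_count\nCASSL,5\nCASSQ,2\nCARSL,9\n")
        rep = read_repertoire(f)
        assert len(rep) == 3
        assert rep.patient_id == "rep"

    def test_merge_by_sum(self, tmp_path):
        f = tmp_path / "rep.csv"
        f.write_text("junction_aa,duplicate_count\nCASSL,5\nCASSL,3\n")
        rep = read_repertoire(f)
        assert len(rep) == 1
        assert rep.clones[0].count_baseline == 8

    def test_missing_sequence_column(self, tmp_path):
        f = tmp_path / "rep.csv"
        f.write_text("foo,bar\n1,2\n")
        with pytest.raises(RepertoireFormatError):
            read_repertoire(f)

    def test_negative_count(self, tmp_path):
        f = tmp_path / "rep.csv"
        f.write_text("junction_aa,duplicate_count\nCASSL,-1\n")
        with pytest.raises(ValueError):
            read_repertoire(f)

    def test_missing_post_column_defaults_to_zero(self, tmp_path):
        f = tmp_path / "rep.tsv"
        f.write_text("junction_aa\tcount_baseline\nCASSL\t5\n")
        rep = read_repertoire(f)
        assert rep.clones[0].count_post == 0

    def test_explicit_column_map(self, tmp_path):
        f = tmp_path / "rep.csv"
        f.write_text("cdr3,pre,post\nCASSL,5,7\n")
        rep = read_repertoire(
            f, column_map={"sequence": "cdr3", "count_baseline": "pre",
                           "count_post": "post"}
        )
        assert rep.clones[0].count_post == 7
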