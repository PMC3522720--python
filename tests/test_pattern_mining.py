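"""Closed frequent subgraph mining, isomorphism, and the random-graph null."""

import numpy as np
import pytest

from _oracles import (brute_force_closed_frequent, exhaustive_monomorphic,
                      label_graph, permutation_isomorphic, random_graph_db)
from midomain.pattern_mining import (GraphDB, NullTestResult, canonical_code,
                                     count_isomorphic_pairs, db_label_frequencies,
                                     is_isomorphic, mine_closed_frequent,
                                     random_null_pvalue, subgraph_occurs,
                                     support_threshold)


@pytest.mark.parametrize("n,expected", [(10, 2), (7, 2), (100, 20), (1, 2), (20, 4)])
def test_support_threshold(n, expected):
    assert support_threshold(n) == expected


class TestSubgraphOccurs:
    def test_single_node(self):
        host = label_graph({0: "A", 1: "B"}, [(0, 1)])
        assert subgraph_occurs(label_graph({0: "A"}, []), host)
        assert not subgraph_occurs(label_graph({0: "W"}, []), host)

    def test_path_into_triangle(self):
        path = label_graph({0: "A", 1: "B", 2: "C"}, [(0, 1), (1, 2)])
        tri = label_graph({0: "A", 1: "B", 2: "C"}, [(0, 1), (1, 2), (0, 2)])
        assert subgraph_occurs(path, tri)

    def test_path_not_in_star(self):
        path = label_graph({0: "A", 1: "B", 2: "C"}, [(0, 1), (1, 2)])
        star = label_graph({0: "A", 1: "B", 2: "C"}, [(0, 1), (0, 2)])
        assert not subgraph_occurs(path, star)
        assert not exhaustive_monomorphic(path, star)  # oracle agrees

    def test_agrees_with_exhaustive_mapping(self, rng):
        for _ in range(50):
            graphs = random_graph_db(rng, n_graphs_max=2, n_nodes_max=5)
            pattern, host = graphs[0], graphs[-1]
            assert subgraph_occurs(pattern, host) == exhaustive_monomorphic(pattern, host)


class TestIsomorphism:
    def test_relabeled_copy_isomorphic(self):
        g1 = label_graph({0: "A", 1: "B", 2: "C"}, [(0, 1), (1, 2)])
        g2 = label_graph({7: "C", 8: "B", 9: "A"}, [(7, 8), (8, 9)])
        assert is_isomorphic(g1, g2)
        assert canonical_code(g1) == canonical_code(g2)

    def test_changed_label_breaks_isomorphism(self):
        g1 = label_graph({0: "A", 1: "B", 2: "C"}, [(0, 1), (1, 2)])
        g2 = label_graph({0: "A", 1: "B", 2: "A"}, [(0, 1), (1, 2)])
        assert not is_isomorphic(g1, g2)
        assert canonical_code(g1) != canonical_code(g2)

    def test_code_equality_iff_permutation_oracle(self, rng):
        # canonical code is isomorphism-invariant on small labeled graphs
        for _ in range(100):
            graphs = random_graph_db(rng, n_graphs_max=2, n_nodes_max=5,
                                     alphabet="AB")
            g1, g2 = graphs[0], graphs[-1]
            want = permutation_isomorphic(g1, g2)
            assert is_isomorphic(g1, g2) == want
            assert (canonical_code(g1) == canonical_code(g2)) == want


class TestMiner:
    def test_worked_example_closed_set(self):
        g1 = label_graph({0: "A", 1: "B", 2: "C"}, [(0, 1), (1, 2)])
        g2 = label_graph({0: "A", 1: "B", 2: "C"}, [(0, 1), (1, 2)])
        g3 = label_graph({0: "A", 1: "B"}, [(0, 1)])
        for i, g in enumerate((g1, g2, g3)):
            g.graph["graph_id"] = f"G{i + 1}"
        fps = mine_closed_frequent(GraphDB([g1, g2, g3], support_threshold=2))
        got = {(f.canonical_code, f.support) for f in fps}
        ab = canonical_code(label_graph({0: "A", 1: "B"}, [(0, 1)]))
        abc = canonical_code(g1)
        bc = canonical_code(label_graph({0: "B", 1: "C"}, [(0, 1)]))
        assert got == {(ab, 3), (abc, 2)}
        assert bc not in {c for c, _ in got}  # frequent but not closed

    def test_identical_graphs_collapse_to_full_common_graph(self):
        graphs = [label_graph({0: "A", 1: "B", 2: "C"}, [(0, 1), (1, 2)])
                  for _ in range(4)]
        fps = mine_closed_frequent(GraphDB(graphs, support_threshold=4))
        assert len(fps) == 1
        assert fps[0].support == 4
        assert is_isomorphic(fps[0].pattern, graphs[0])

    def test_equals_brute_force_on_random_dbs(self, rng):
        for _ in range(25):
            graphs = random_graph_db(rng)
            t = int(rng.integers(2, len(graphs) + 1))
            mined = mine_closed_frequent(GraphDB(graphs, support_threshold=t))
            oracle = brute_force_closed_frequent(graphs, t)
            got = sorted((f.canonical_code, f.support) for f in mined)
            want = sorted((canonical_code(p), s) for s, p in oracle.values())
            assert got == want

    def test_deterministic_output_order(self):
        graphs = [label_graph({0: "A", 1: "B", 2: "A"}, [(0, 1), (1, 2)])
                  for _ in range(3)]
        db = GraphDB(graphs, support_threshold=2)
        out1 = [(f.fingerprint_id, f.canonical_code) for f in mine_closed_frequent(db)]
        out2 = [(f.fingerprint_id, f.canonical_code) for f in mine_closed_frequent(db)]
        assert out1 == out2

    def test_planted_motif_recovered(self):
        from midomain.synthetic_data import GraphDBSpec, generate_graph_db

        motif = label_graph({0: "W", 1: "Y", 2: "F"}, [(0, 1), (1, 2), (0, 2)])
        graphs, truth = generate_graph_db(GraphDBSpec(
            n_graphs=10, nodes_per_graph=(8, 10),
            planted_motifs=((motif, 0.6),), seed=3))
        n_planted = truth["motifs"][0]["n_planted"]
        fps = mine_closed_frequent(GraphDB(graphs, support_threshold=2))
        hits = [f for f in fps
                if subgraph_occurs(motif, f.pattern) and f.support >= n_planted]
        assert hits, "planted motif not contained in any closed fingerprint"

    def test_support_is_per_graph_not_per_embedding(self):
        # two embeddings in one host must count once
        host = label_graph({0: "A", 1: "B", 2: "A"}, [(0, 1), (1, 2)])
        host2 = label_graph({0: "A", 1: "B"}, [(0, 1)])
        fps = mine_closed_frequent(GraphDB([host, host2], support_threshold=2))
        ab = [f for f in fps if f.n_nodes == 2]
        assert ab and ab[0].support == 2


class TestPairCounts:
    def _fps(self, *graphs):
        from midomain.pattern_mining import Fingerprint

        return [Fingerprint(pattern=g, support=1, occurrences=frozenset(),
                            canonical_code=canonical_code(g)) for g in graphs]

    def test_disjoint_topologies(self):
        a = self._fps(label_graph({0: "A", 1: "B"}, [(0, 1)]))
        b = self._fps(label_graph({0: "C", 1: "D"}, [(0, 1)]))
        assert count_isomorphic_pairs(a, b) == 0

    def test_identical_sets(self):
        g = label_graph({0: "A", 1: "B"}, [(0, 1)])
        a = self._fps(g, label_graph({0: "C"}, []))
        assert count_isomorphic_pairs(a, a) == len(a)

    def test_single_shared_pattern_counted_on_smaller_side(self):
        shared = label_graph({0: "A", 1: "B"}, [(0, 1)])
        a = self._fps(shared)
        b = self._fps(label_graph({5: "B", 6: "A"}, [(5, 6)]),
                      label_graph({0: "C", 1: "D"}, [(0, 1)]),
                      label_graph({0: "E"}, []))
        assert count_isomorphic_pairs(a, b) == 1
        assert count_isomorphic_pairs(b, a) == 1


class TestNullModel:
    def test_observed_zero_gives_p_one(self):
        r = random_null_pvalue([(2, 1)], [(2, 1)], {"A": 1.0}, observed=0,
                               n_reps=200, seed=0)
        assert r.p_value == 1.0

    def test_impossible_count_reported_as_bound(self):
        r = random_null_pvalue([(2, 1)], [(2, 1)], {"A": 0.5, "C": 0.5},
                               observed=99, n_reps=100, seed=0)
        assert r.is_upper_bound
        assert r.p_value == pytest.approx(1 / 100)
        assert r.formatted.startswith("<")

    def test_monotone_nonincreasing_in_observed(self):
        ps = [random_null_pvalue([(2, 1), (3, 2)], [(2, 1), (3, 2)],
                                 {"A": 0.5, "C": 0.5}, observed=k,
                                 n_reps=300, seed=5).exceed_count
              for k in range(0, 3)]
        assert ps == sorted(ps, reverse=True)

    def test_two_single_node_closed_form(self):
        # one single-node fingerprint vs two, uniform 2-letter alphabet:
        # P(at least one label matches) = 1 - (1/2)(1/2) = 3/4
        r = random_null_pvalue([(1, 0)], [(1, 0), (1, 0)],
                               {"A": 0.5, "C": 0.5}, observed=1,
                               n_reps=2000, seed=11)
        se = (0.75 * 0.25 / 2000) ** 0.5
        assert abs(r.p_value - 0.75) < 3 * se

    def test_impossible_graph_size_rejected(self):
        with pytest.raises(ValueError):
            random_null_pvalue([(3, 1)], [(2, 1)], {"A": 1.0}, observed=0)

    def test_reproducible_given_seed(self):
        args = ([(3, 2)], [(3, 2)], {"A": 0.5, "C": 0.5})
        r1 = random_null_pvalue(*args, observed=1, n_reps=100, seed=9)
        r2 = random_null_pvalue(*args, observed=1, n_reps=100, seed=9)
        assert r1.exceed_count == r2.exceed_count


def test_db_label_frequencies_sum_to_one():
    g = label_graph({0: "A", 1: "A", 2: "C"}, [(0, 1)])
    freqs = db_label_frequencies(GraphDB([g], support_threshold=1))
    assert freqs == {"A": pytest.approx(2 / 3), "C": pytest.approx(1 / 3)}
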