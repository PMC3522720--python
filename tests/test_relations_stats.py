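"""Itemsets, cooperative/distinctive relations, assortativity statistics."""

import networkx as nx
import numpy as np
import pytest

from _oracles import brute_force_closed_itemsets, label_graph
from midomain.pattern_mining import Fingerprint, canonical_code
from midomain.relations_stats import (build_transactions, compare_domains,
                                      cooperative_pairs, degree_assortativity,
                                      distinctive_fingerprints,
                                      function_association, label_assortativity,
                                      mine_closed_itemsets, subsample_disparity)


def fp(g, fid="f", site=None):
    return Fingerprint(pattern=g, support=1, occurrences=frozenset(),
                       canonical_code=canonical_code(g), fingerprint_id=fid,
                       site_id=site)


class TestClosedItemsets:
    def test_worked_example(self):
        tx = [frozenset("abc"), frozenset("ab"), frozenset("ac")]
        got = dict(mine_closed_itemsets(tx, minsup=2))
        assert got == {frozenset("a"): 3, frozenset("ab"): 2, frozenset("ac"): 2}

    def test_identical_transactions_give_single_closed_set(self):
        tx = [frozenset("xyz")] * 4
        assert mine_closed_itemsets(tx, 2) == [(frozenset("xyz"), 4)]

    def test_minsup_above_db_size_empty(self):
        assert mine_closed_itemsets([frozenset("ab")], 2) == []

    def test_equals_power_set_brute_force(self, rng):
        items = list("abcdefghij")
        for _ in range(30):
            n_tx = int(rng.integers(2, 8))
            tx = [frozenset(rng.choice(items, size=rng.integers(1, 6), replace=False))
                  for _ in range(n_tx)]
            minsup = int(rng.integers(1, n_tx + 1))
            got = dict(mine_closed_itemsets(tx, minsup))
            want = brute_force_closed_itemsets(tx, minsup)
            assert got == want


class TestTransactions:
    def test_occurrence_matrix_reproduced(self):
        ga = label_graph({0: "A", 1: "B"}, [(0, 1)])
        gb = label_graph({0: "A", 1: "B", 2: "C"}, [(0, 1), (1, 2)])
        gc = label_graph({0: "C", 1: "D"}, [(0, 1)])
        fps = [fp(label_graph({0: "A", 1: "B"}, [(0, 1)]), "ab"),
               fp(label_graph({0: "C"}, []), "c")]
        tdb = build_transactions(fps, {"ia": ga, "ib": gb, "ic": gc})
        rows = {t.fingerprint_id: t.items for t in tdb.transactions}
        assert rows == {"ab": frozenset({"ia", "ib"}),
                        "c": frozenset({"ib", "ic"})}


class TestCooperative:
    def test_pair_present_in_all_proteins(self):
        pa = label_graph({0: "A", 1: "B"}, [(0, 1)])
        pb = label_graph({0: "C", 1: "D"}, [(0, 1)])
        fps = {0: [fp(pa, "fa", 0)], 1: [fp(pb, "fb", 1)]}
        proteins = {f"p{i}": {0: pa.copy(), 1: pb.copy()} for i in range(3)}
        pairs = cooperative_pairs(fps, proteins, min_co_fraction=0.2)
        assert len(pairs) == 1
        assert pairs[0].co_fraction == 1.0
        assert pairs[0].co_support <= 3

    def test_two_thirds_co_occurrence(self):
        pa = label_graph({0: "A", 1: "B"}, [(0, 1)])
        pb = label_graph({0: "C", 1: "D"}, [(0, 1)])
        other = label_graph({0: "E", 1: "F"}, [(0, 1)])
        fps = {0: [fp(pa, "fa", 0)], 1: [fp(pb, "fb", 1)]}
        proteins = {"p0": {0: pa.copy(), 1: pb.copy()},
                    "p1": {0: pa.copy(), 1: pb.copy()},
                    "p2": {0: pa.copy(), 1: other.copy()}}
        pairs = cooperative_pairs(fps, proteins, min_co_fraction=0.2)
        assert pairs[0].co_fraction == pytest.approx(2 / 3)

    def test_disjoint_occurrences_not_reported_and_warning_without_shared_sites(self):
        pa = label_graph({0: "A", 1: "B"}, [(0, 1)])
        pb = label_graph({0: "C", 1: "D"}, [(0, 1)])
        fps = {0: [fp(pa, "fa", 0)], 1: [fp(pb, "fb", 1)]}
        proteins = {"p0": {0: pa.copy(), 1: pa.copy()}}  # fb never occurs
        assert cooperative_pairs(fps, proteins, 0.2) == []
        with pytest.warns(UserWarning):
            assert cooperative_pairs(fps, {"p0": {0: pa.copy()}}, 0.2) == []


class TestDistinctive:
    def test_isomorphic_counterpart_excluded(self):
        shared = label_graph({0: "A", 1: "B"}, [(0, 1)])
        unique = label_graph({0: "W", 1: "Y"}, [(0, 1)])
        fps = {0: [fp(shared, "s0"), fp(unique, "u0")],
               1: [fp(shared.copy(), "s1")]}
        graphs = {0: [nx.compose(shared, unique)], 1: [shared.copy()]}
        out = distinctive_fingerprints(0, fps, graphs)
        assert [f.fingerprint_id for f in out] == ["u0"]

    def test_identical_sites_have_empty_distinctive_sets(self):
        g = label_graph({0: "A", 1: "B"}, [(0, 1)])
        fps = {0: [fp(g, "a")], 1: [fp(g.copy(), "b")]}
        graphs = {0: [g.copy()], 1: [g.copy()]}
        assert distinctive_fingerprints(0, fps, graphs) == []
        assert distinctive_fingerprints(1, fps, graphs) == []

    def test_distinctive_and_shared_partition_site_fingerprints(self):
        shared = label_graph({0: "A", 1: "B"}, [(0, 1)])
        unique = label_graph({0: "W", 1: "Y"}, [(0, 1)])
        fps = {0: [fp(shared, "s"), fp(unique, "u")], 1: [fp(shared.copy(), "s1")]}
        graphs = {0: [nx.compose(shared, unique)], 1: [shared.copy()]}
        distinct = {f.fingerprint_id for f in distinctive_fingerprints(0, fps, graphs)}
        all_ids = {f.fingerprint_id for f in fps[0]}
        assert distinct < all_ids and distinct  # proper nonempty subset here


def test_function_association_counts():
    shared = label_graph({0: "A", 1: "B"}, [(0, 1)])
    unique = label_graph({0: "W", 1: "Y"}, [(0, 1)])
    fps = {0: [fp(shared, "s0"), fp(unique, "u0")], 1: [fp(shared.copy(), "s1")]}
    graphs = {0: [nx.compose(shared, unique)], 1: [shared.copy()]}
    rows = {r["function"]: r for r in function_association(
        {0: "antigen binding", 1: None}, fps, graphs)}
    assert rows["antigen binding"]["n_fingerprints"] == 2
    assert rows["antigen binding"]["n_shared"] == 1
    assert rows["unannotated"]["n_shared"] == 1


class TestAssortativity:
    def test_star_degree_assortativity_is_minus_one(self):
        star = nx.star_graph(3)
        nx.set_node_attributes(star, {i: "ACDE"[i] for i in star}, "aa")
        assert degree_assortativity(star) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self):
        cyc = nx.cycle_graph(4)
        nx.set_node_attributes(cyc, {i: "ACDE"[i] for i in cyc}, "aa")
        assert degree_assortativity(cyc) is None

    def test_path4_matches_hand_pearson(self):
        path = nx.path_graph(4)
        nx.set_node_attributes(path, {i: "ACDE"[i] for i in path}, "aa")
        # directed endpoint degree pairs: (1,2),(2,1),(2,2),(2,2),(2,1),(1,2)
        x = np.array([1, 2, 2, 2, 2, 1])
        y = np.array([2, 1, 2, 2, 1, 2])
        want = np.corrcoef(x, y)[0, 1]
        assert degree_assortativity(path) == pytest.approx(want)

    def test_label_assortativity_extremes(self):
        within = label_graph({0: "A", 1: "A", 2: "C", 3: "C"}, [(0, 1), (2, 3)])
        assert label_assortativity(within) == pytest.approx(1.0)
        # perfect two-label bipartite mixing: e = [[0,.5],[.5,0]] -> -1
        bip = label_graph({0: "A", 1: "C", 2: "A", 3: "C"}, [(0, 1), (2, 3)])
        assert label_assortativity(bip) == pytest.approx(-1.0)
        mono = label_graph({0: "A", 1: "A"}, [(0, 1)])
        assert label_assortativity(mono) is None

    def test_edgeless_graph_rejected(self):
        g = label_graph({0: "A"}, [])
        with pytest.raises(ValueError):
            degree_assortativity(g)
        with pytest.raises(ValueError):
            label_assortativity(g)

    def test_defined_values_bounded(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 8))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            for v in g.nodes:
                g.nodes[v]["aa"] = str(rng.choice(list("AC")))
            for f in (degree_assortativity, label_assortativity):
                r = f(g)
                assert r is None or -1.0 - 1e-9 <= r <= 1.0 + 1e-9


def _mixed_fps(sizes, labels="ACDEFG"):
    out = []
    for i, n in enumerate(sizes):
        g = nx.path_graph(n) if i % 2 == 0 else nx.star_graph(n - 1)
        for v in g.nodes:
            g.nodes[v]["aa"] = labels[v % len(labels)]
        out.append(fp(g, f"m{i}"))
    return out


class TestCompareDomains:
    def test_identical_samples_give_p_one(self):
        fps = _mixed_fps([4, 5, 6, 4, 5])
        res = compare_domains(fps, list(fps))
        assert res.p_degree == pytest.approx(1.0)
        assert res.p_label == pytest.approx(1.0)

    def test_shifted_distributions_detected(self):
        # stars (degree assortativity -1) vs paths (> -1): strong separation
        stars = []
        for i, n in enumerate([4, 5, 6, 7] * 6):
            g = nx.star_graph(n - 1)
            for v in g.nodes:
                g.nodes[v]["aa"] = "ACDEFGH"[v % 7]
            stars.append(fp(g, f"s{i}"))
        paths = []
        for i, n in enumerate([5, 6, 7, 8] * 6):
            g = nx.path_graph(n)
            for v in g.nodes:
                g.nodes[v]["aa"] = "ACDEFGH"[v % 7]
            paths.append(fp(g, f"p{i}"))
        res = compare_domains(stars, paths)
        assert res.p_degree < 0.01

    def test_too_few_defined_values_rejected(self):
        with pytest.raises(ValueError):
            compare_domains(_mixed_fps([4]), _mixed_fps([4, 5, 6]))


class TestSubsampleDisparity:
    def _set(self, codes_labels):
        out = []
        for i, lab in enumerate(codes_labels):
            g = label_graph({0: lab, 1: lab}, [(0, 1)])
            out.append(fp(g, f"{lab}{i}"))
        return out

    def test_identical_sets_give_p_near_one(self):
        a = self._set(list("ACDEFG") * 3)
        res = subsample_disparity(a, list(a), k=10, n_reps=200, seed=3)
        assert res.p_value > 0.5

    def test_disjoint_sets_give_extreme_p(self):
        a = self._set(list("ACDEF") * 4)
        b = self._set(list("GHIKL") * 4)
        res = subsample_disparity(a, b, k=10, n_reps=200, seed=3)
        assert res.p_value == pytest.approx(1 / 200)

    def test_set_smaller_than_k_rejected(self):
        a = self._set(list("AC"))
        with pytest.raises(ValueError):
            subsample_disparity(a, a, k=50)

    def test_reproducible_under_seed(self):
        a = self._set(list("ACDEFGHIK") * 2)
        b = self._set(list("ACDXYZWVU") * 2)
        r1 = subsample_disparity(a, b, k=8, n_reps=100, seed=5)
        r2 = subsample_disparity(a, b, k=8, n_reps=100, seed=5)
        assert r1.p_value == r2.p_value
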