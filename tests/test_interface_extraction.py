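"""Interface detection, MSA mapping, de-duplication, preference, domains."""

import pytest

from conftest import make_chain, make_complex
from midomain.interface_extraction import (DomainRange, InterfaceInstance,
                                           assign_domains, build_msa,
                                           classify_interaction,
                                           cluster_binding_sites,
                                           compute_preference, dedup_interfaces,
                                           detect_interfaces,
                                           interface_count_histogram,
                                           interface_similarity, jaccard_overlap)


def inst(residues, host="E:A", partner="E:B", resolution=2.0, entry="E"):
    return InterfaceInstance(host_chain=host, partner_chain=partner,
                             entry_id=entry, resolution=resolution,
                             residues=frozenset(residues))


class TestDetect:
    def test_cutoff_is_inclusive_at_five_angstrom(self):
        a = make_chain("A", [(0, 0, 0), (3.8, 0, 0)])
        b49 = make_chain("B", [(0, 4.9, 0), (3.8, 4.9, 0)])
        cx = make_complex([a, b49])
        found = {(i.host_chain, tuple(i.positions)) for i in detect_interfaces(cx)}
        assert found == {("TST1:A", (0, 1)), ("TST1:B", (0, 1))}
        b51 = make_chain("B", [(0, 5.1, 0), (3.8, 5.1, 0)])
        assert detect_interfaces(make_complex([a, b51])) == []

    def test_chains_in_different_bio_units_never_interface(self):
        a = make_chain("A", [(0, 0, 0)], bio_unit=1)
        b = make_chain("B", [(0, 3.0, 0)], bio_unit=2)
        assert detect_interfaces(make_complex([a, b])) == []


class TestMsa:
    def test_identical_sequences_map_to_identical_columns(self):
        seqs = {f"c{i}": "ACDEFGH" for i in range(3)}
        msa = build_msa(seqs)
        assert all(msa.columns[c] == {i: i for i in range(7)} for c in seqs)

    def test_deletion_skips_a_column(self):
        seqs = {"full": "ACDEFGHIKLMNPQRSTVWY" * 2,
                "del": ("ACDEFGHIKLMNPQRSTVWY" * 2)[:17]
                       + ("ACDEFGHIKLMNPQRSTVWY" * 2)[18:]}
        msa = build_msa(seqs)
        full_cols = set(msa.columns["full"].values())
        del_cols = set(msa.columns["del"].values())
        assert len(full_cols - del_cols) == 1
        # injective per chain
        for c in seqs:
            vals = list(msa.columns[c].values())
            assert len(vals) == len(set(vals))


class TestSimilarity:
    def test_identity_is_one(self):
        i1 = inst({(3, "A"), (5, "G")})
        assert interface_similarity(i1, i1, None) == 1.0

    def test_shared_over_smaller_set(self):
        i1 = inst({(3, "A"), (5, "G"), (9, "K")})
        i2 = inst({(3, "A"), (5, "G"), (12, "R")})
        assert interface_similarity(i1, i2, None) == pytest.approx(2 / 3)

    def test_same_column_different_aa_does_not_match(self):
        assert interface_similarity(inst({(3, "A")}), inst({(3, "V")}), None) == 0.0

    def test_symmetry_and_empty_error(self):
        i1 = inst({(1, "A"), (2, "C")})
        i2 = inst({(2, "C")})
        assert interface_similarity(i1, i2, None) == interface_similarity(i2, i1, None)
        with pytest.raises(ValueError):
            interface_similarity(inst(set()), i1, None)

    def test_jaccard(self):
        assert jaccard_overlap(inst({(1, "A")}), inst({(2, "A")}), None) == 0.0
        i1 = inst({(1, "A"), (2, "A"), (3, "A")})
        i2 = inst({(3, "A"), (4, "A"), (5, "A")})
        assert jaccard_overlap(i1, i2, None) == pytest.approx(0.2)
        assert jaccard_overlap(i1, i1, None) == 1.0


class FakeMsa:
    def map_interface(self, inst):
        return inst.residues


class TestDedup:
    def test_best_resolution_wins(self):
        shared = {(1, "A"), (2, "C"), (3, "D")}
        insts = [inst(shared, host=f"E{i}:A", resolution=r, entry=f"E{i}")
                 for i, r in enumerate([2.0, 1.5, 2.5])]
        reps = dedup_interfaces(insts, FakeMsa())
        assert len(reps) == 1
        assert reps[0].resolution == 1.5
        # all representatives remapped onto the best-resolution chain
        assert reps[0].representative_host == "E1:A"

    def test_resolution_tie_keeps_first_encountered(self):
        shared = {(1, "A"), (2, "C")}
        insts = [inst(shared, host="E0:A", resolution=1.8, entry="E0"),
                 inst(shared, host="E1:A", resolution=1.8, entry="E1")]
        reps = dedup_interfaces(insts, FakeMsa())
        assert reps[0].entry_id == "E0"

    def test_disjoint_interfaces_both_kept_and_count_never_grows(self):
        insts = [inst({(1, "A"), (2, "C")}), inst({(10, "K"), (11, "R")})]
        reps = dedup_interfaces(insts, FakeMsa())
        assert len(reps) == 2
        assert len(reps) <= len(insts)


class TestSites:
    def test_overlapping_representatives_share_a_site(self):
        i1 = inst({(i, "A") for i in range(10)})
        i2 = inst({(i, "A") for i in range(1, 11)})
        sites = cluster_binding_sites([i1, i2], FakeMsa(), site_threshold=0.5)
        assert len(sites) == 1

    def test_disjoint_representatives_get_distinct_sites(self):
        i1 = inst({(i, "A") for i in range(5)})
        i2 = inst({(i, "A") for i in range(20, 25)})
        sites = cluster_binding_sites([i1, i2], FakeMsa(), site_threshold=0.5)
        assert len(sites) == 2
        assert i1.site_id != i2.site_id


class TestClassify:
    def test_homo_vs_hetero_and_permanence(self):
        clusters = {"E:A": 0, "E:B": 0, "E:C": 1}
        homo = inst(set(), host="E:A", partner="E:B")
        het = inst(set(), host="E:A", partner="E:C")
        perm = {homo.interface_id: "permanent", het.interface_id: "transient"}
        assert classify_interaction(homo, clusters, perm) == "homo-oligomer"
        assert classify_interaction(het, clusters, perm) == "hetero-complex"
        assert classify_interaction(homo, clusters, {}) == "unknown"


class TestPreference:
    COUNTS = {"homo-oligomer": (647, 127), "homo-complex": (13, 3),
              "hetero-oligomer": (38, 4), "hetero-complex": (6695, 890)}

    def test_published_interaction_counts_reproduce_preferences(self):
        pref = compute_preference(self.COUNTS)
        rounded = {k: round(v, 2) for k, v in pref.items()}
        assert rounded == {"homo-oligomer": 1.42, "homo-complex": 1.67,
                           "hetero-oligomer": 0.76, "hetero-complex": 0.96}

    def test_count_weighted_preference_sums_to_total(self):
        # identity: sum_t n_all_t * pref_t == sum_t n_all_t (exact in full
        # precision; < 0.5% residual survives 2-decimal rounding)
        pref = compute_preference(self.COUNTS)
        tot = sum(a for a, _ in self.COUNTS.values())
        assert sum(a * pref[t] for t, (a, _) in self.COUNTS.items()) == pytest.approx(tot)
        rounded = sum(a * round(pref[t], 2) for t, (a, _) in self.COUNTS.items())
        assert abs(rounded - tot) / tot < 0.005

    def test_degenerate_cases(self):
        assert compute_preference({"only": (10, 4)})["only"] == pytest.approx(1.0)
        both = compute_preference({"a": (10, 1), "b": (10, 1)})
        assert both["a"] == both["b"] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            compute_preference({"a": (0, 0)})


class TestDomains:
    DOMS = [DomainRange("A", ("a", "f", "s", "fam"), 1, 50),
            DomainRange("B", ("a", "f", "s", "fam"), 51, 100)]

    def _inst(self, seq_nums):
        from midomain.structure_model import ResidueRef

        raws = [ResidueRef("A", n, "", "A", []) for n in seq_nums]
        return InterfaceInstance(host_chain="E:A", partner_chain="E:B",
                                 entry_id="E", resolution=2.0, raw_residues=raws)

    def test_single_domain(self):
        assert assign_domains(self._inst(range(10, 21)), self.DOMS) == {"A"}

    def test_cross_domain(self):
        assert assign_domains(self._inst(range(40, 61)), self.DOMS) == {"A", "B"}

    def test_unassigned(self):
        assert assign_domains(self._inst([120]), self.DOMS) == {"unassigned"}

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            DomainRange("X", ("a", "f", "s", "fam"), 10, 5)


def test_interface_histogram_excludes_single_site_proteins():
    assert interface_count_histogram([2, 2, 3]) == {2: 2, 3: 1}
    assert interface_count_histogram([1, 1, 2]) == {2: 1}
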