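"""Haplotype collapsing and minimum spanning networks vs the
union-of-all-MSTs oracle."""

from itertools import combinations

import numpy as np
import pytest

import rdnavar as rv
from rdnavar.network import HaplotypeMember, msn_edge_indices

from oracles import mst_union


def _mem(i, source="PacBio", n=1):
    return HaplotypeMember(f"seq{i}", source, n if source == "PacBio" else None)


class TestCollapse:
    def test_identical_rows_collapse(self):
        haps = rv.collapse_haplotypes(["AAA"] * 5, [_mem(i) for i in range(5)])
        assert len(haps) == 1 and haps[0].frequency == 5

    def test_two_variants(self):
        haps = rv.collapse_haplotypes(["AAA", "AAA", "AAT"],
                                      [_mem(i) for i in range(3)])
        assert [h.frequency for h in haps] == [2, 1]
        assert [h.name for h in haps] == ["Hap 1", "Hap 2"]

    def test_frequency_tie_orders_by_first_seen(self):
        haps = rv.collapse_haplotypes(["AAT", "AAA"], [_mem(0), _mem(1)])
        assert haps[0].row == "AAT"

    def test_simulated_error_free_variants_collapse_to_truth(self, rng):
        panel = rv.build_species_panel(1, seed=21)
        from rdnavar.sim import make_strain
        strain = make_strain(panel[0], "S", [0.05, 0.08], [10, 3, 2], rng)
        seqs = [h for h, _ in strain.haplotypes]
        rows = [s[:200] for s in seqs]  # equal-length ITS-like slice
        haps = rv.collapse_haplotypes(rows, [_mem(i) for i in range(3)])
        assert len(haps) == len(set(rows))

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            rv.collapse_haplotypes([], [])


class TestMutationalDistance:
    def test_identical(self):
        assert rv.mutational_distance("AAAA", "AAAA") == 0

    def test_single_difference(self):
        assert rv.mutational_distance("AAAA", "AATA") == 1

    def test_gap_columns_are_unscored(self):
        assert rv.mutational_distance("AA-CG", "AATCC") == 1
        assert rv.mutational_distance("A-A", "A-T") == 1


class TestBuildMsn:
    def _net(self, rows, epsilon=0):
        haps = rv.collapse_haplotypes(rows, [_mem(i) for i in range(len(rows))])
        return rv.build_msn(haps, epsilon)

    def test_single_haplotype(self):
        net = self._net(["AAAA"])
        assert len(net.haplotypes) == 1 and net.edges == []

    def test_chain_topology(self):
        # d(A,B)=1, d(B,C)=1, d(A,C)=2: the A-C edge is in no MST
        net = self._net(["AAAA", "AATA", "AATT"])
        pairs = {frozenset((a, b)) for a, b, _ in net.edges}
        names = {h.row: h.name for h in net.haplotypes}
        assert pairs == {frozenset((names["AAAA"], names["AATA"])),
                         frozenset((names["AATA"], names["AATT"]))}

    def test_tie_class_keeps_all_mst_edges(self):
        # four haplotypes at mutual distance 1 via distinct symbols in
        # one column: every edge is in some MST
        rows = ["AAAA", "AAAC", "AAAG", "AAAT"]
        net = self._net(rows)
        assert len(net.edges) == 6

    def test_connected_with_at_least_n_minus_1_edges(self, rng):
        rows = list({"".join(rng.choice(list("ACGT"), size=12))
                     for _ in range(6)})
        net = self._net(rows)
        assert len(net.edges) >= len(rows) - 1
        # connectivity by union-find over names
        parent = {h.name: h.name for h in net.haplotypes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b, _ in net.edges:
            parent[find(a)] = find(b)
        assert len({find(h.name) for h in net.haplotypes}) == 1

    def test_epsilon_growth_is_monotone(self, rng):
        rows = list({"".join(rng.choice(list("ACGT"), size=10))
                     for _ in range(7)})
        prev = set()
        for eps in range(0, 6):
            net = self._net(rows, epsilon=eps)
            cur = {frozenset((a, b)) for a, b, _ in net.edges}
            assert prev <= cur
            prev = cur

    def test_edge_steps_equal_endpoint_distance(self, rng):
        rows = list({"".join(rng.choice(list("ACGT"), size=15))
                     for _ in range(6)})
        net = self._net(rows)
        row_of = {h.name: h.row for h in net.haplotypes}
        for a, b, d in net.edges:
            assert d == rv.mutational_distance(row_of[a], row_of[b])


def test_msn_equals_mst_union_oracle_on_random_instances(rng):
    """epsilon=0 edge set == union of all minimum spanning trees."""
    for _ in range(40):
        n = int(rng.integers(2, 8))
        dist = {(i, j): int(rng.integers(1, 5))
                for i, j in combinations(range(n), 2)}
        got = {frozenset((i, j)) for i, j, _ in msn_edge_indices(n, dist, 0)}
        assert got == mst_union(n, dist)


class TestNetworkReport:
    def test_member_formatting_and_source_classes(self):
        rows = ["AAAA", "AAAA", "AATT", "CCCC"]
        members = [HaplotypeMember("MY4953", "SAN"),
                   HaplotypeMember("MY4953-C1", "PacBio", 341),
                   HaplotypeMember("MY4953-C2", "PacBio", 2),
                   HaplotypeMember("MY3233", "SAN")]
        haps = rv.collapse_haplotypes(rows, members)
        hap_df, edge_df = rv.network_report(rv.build_msn(haps))
        top = hap_df.iloc[0]
        assert top["sequences"] == "MY4953 (SAN); MY4953-C1 (341)"
        assert top["source_class"] == "both"
        classes = dict(zip(hap_df["sequences"], hap_df["source_class"]))
        assert classes["MY4953-C2 (2)"] == "pacbio_only"
        assert classes["MY3233 (SAN)"] == "sanger_only"
        assert set(edge_df.columns) == {"hap_a", "hap_b", "steps"}
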