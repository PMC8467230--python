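"""Quality filter, barcode matching, demultiplexing, length filter."""

import numpy as np
import pytest

import rdnavar as rv
from rdnavar.readprep import BarcodePair, barcode_pairs_from_frame, hamming
from rdnavar.records import revcomp
from rdnavar.sim import generate_barcode_pairs


def _read(seq, np_=10, rq=0.999, id_="r"):
    return rv.SequenceRecord(id_, seq, n_subreads=np_, read_quality=rq)


class TestCcsFilter:
    def test_boundary_values_are_inclusive(self):
        kept, disc = rv.ccs_filter([_read("ACGT", np_=5, rq=0.99)], 5, 0.99)
        assert len(kept) == 1 and not disc

    @pytest.mark.parametrize("np_,rq", [(4, 0.999), (5, 0.9899), (4, 0.98)])
    def test_below_threshold_discarded(self, np_, rq):
        kept, disc = rv.ccs_filter([_read("ACGT", np_=np_, rq=rq)], 5, 0.99)
        assert not kept and len(disc) == 1

    def test_missing_metadata_fails_filter(self):
        kept, disc = rv.ccs_filter([rv.SequenceRecord("r", "ACGT")], 5, 0.99)
        assert not kept and len(disc) == 1

    def test_empty_input(self):
        assert rv.ccs_filter([], 5, 0.99) == ([], [])


class TestMatchBarcode:
    def test_exact_match(self):
        ok, mm = rv.match_barcode("AAAACCCCGGGGTTTTACGT", "AAAACCCC", 3)
        assert ok and mm == 0

    def test_three_mismatches_allowed_four_rejected(self):
        bc = "AAAAAAAA"
        seq3 = "TTTAAAAA" + "ACGT" * 4
        seq4 = "TTTTAAAA" + "ACGT" * 4
        assert rv.match_barcode(seq3, bc, 3) == (True, 3)
        assert rv.match_barcode(seq4, bc, 3) == (False, 4)

    def test_three_prime_end(self):
        ok, mm = rv.match_barcode("ACGT" * 4 + "GGGG", "GGGG", 0, end="3p")
        assert ok and mm == 0


def _tagged(insert, pair, errors_fwd=0):
    fwd = list(pair.fwd)
    for i in range(errors_fwd):
        fwd[i] = "A" if fwd[i] != "A" else "C"
    return "".join(fwd) + insert + revcomp(pair.rev)


class TestDemultiplex:
    @pytest.fixture
    def pairs(self, rng):
        raw = generate_barcode_pairs(4, rng)
        return [BarcodePair(f"S{i}", f, r) for i, (f, r) in enumerate(raw)]

    def test_clean_reads_assigned_and_trimmed(self, pairs, rng):
        insert = "".join(rng.choice(list("ACGT"), size=100))
        reads = [_read(_tagged(insert, pairs[1]), id_="r1")]
        res = rv.demultiplex(reads, pairs, 3)
        assert [r.id for r in res.assigned["S1"]] == ["r1"]
        assert res.assigned["S1"][0].seq == insert
        assert res.assigned["S1"][0].sample == "S1"

    def test_orientation_invariance(self, pairs, rng):
        insert = "".join(rng.choice(list("ACGT"), size=100))
        fwd_read = _read(_tagged(insert, pairs[2]), id_="a")
        rev_read = _read(revcomp(_tagged(insert, pairs[2])), id_="b")
        res = rv.demultiplex([fwd_read, rev_read], pairs, 3)
        assert {r.id for r in res.assigned["S2"]} == {"a", "b"}
        assert all(r.seq == insert for r in res.assigned["S2"])

    def test_too_many_mismatches_unassigned(self, pairs, rng):
        insert = "".join(rng.choice(list("ACGT"), size=100))
        reads = [_read(_tagged(insert, pairs[0], errors_fwd=4), id_="x")]
        res = rv.demultiplex(reads, pairs, 3)
        assert res.unassigned == ["x"] and res.n_assigned() == 0

    def test_ambiguous_read_discarded(self, rng):
        # two samples sharing barcodes within the mismatch budget
        p1 = BarcodePair("S1", "A" * 16, "C" * 16)
        p2 = BarcodePair("S2", "A" * 15 + "T", "C" * 16)
        insert = "".join(rng.choice(list("ACGT"), size=100))
        reads = [_read(_tagged(insert, p1), id_="amb")]
        res = rv.demultiplex(reads, [p1, p2], 3)
        assert res.ambiguous == ["amb"] and res.n_assigned() == 0

    def test_partition_property(self, pairs, rng):
        insert = "".join(rng.choice(list("ACGT"), size=100))
        reads = [_read(_tagged(insert, pairs[i % 4]), id_=f"r{i}")
                 for i in range(20)]
        reads.append(_read("T" * 130, id_="junk"))
        res = rv.demultiplex(reads, pairs, 3)
        total = res.n_assigned() + len(res.unassigned) + len(res.ambiguous)
        assert total == len(reads)

    def test_stress_errors_within_budget_all_correct(self, rng):
        """500 reads, <=3 errors injected per barcode, separated pairs:
        every read must come back under its own sample."""
        raw = generate_barcode_pairs(5, rng, length=16, min_dist=8)
        pairs = [BarcodePair(f"S{i}", f, r) for i, (f, r) in enumerate(raw)]
        reads, want = [], []
        for i in range(500):
            k = int(rng.integers(5))
            insert = "".join(rng.choice(list("ACGT"), size=80))
            fwd = list(pairs[k].fwd)
            rev = list(pairs[k].rev)
            for arr in (fwd, rev):
                pos = rng.choice(16, size=int(rng.integers(4)), replace=False)
                for p in pos:
                    arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
            seq = "".join(fwd) + insert + revcomp("".join(rev))
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(_read(seq, id_=f"r{i}"))
            want.append(f"S{k}")
        res = rv.demultiplex(reads, pairs, 3)
        got = {r.id: s for s, recs in res.assigned.items() for r in recs}
        assert len(got) == 500
        assert all(got[f"r{i}"] == want[i] for i in range(500))


class TestLengthFilter:
    @pytest.mark.parametrize("n,kept", [(999, False), (1000, True),
                                        (1500, True), (2000, True),
                                        (2001, False)])
    def test_inclusive_bounds(self, n, kept):
        k, d = rv.length_filter([_read("A" * n)], 1000, 2000)
        assert bool(k) is kept and bool(d) is (not kept)


def test_barcode_frame_validation(small_study):
    pairs = barcode_pairs_from_frame(small_study.barcode_map)
    assert len(pairs) == len(small_study.barcode_map)
    assert hamming("AAAA", "AATT") == 2
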