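"""Nearest-reference classification and the NJ QC tree."""

import numpy as np
import pytest

import rdnavar as rv
from rdnavar.io import ReferenceRecord


def _refs(species_seqs, region="ITS"):
    return [ReferenceRecord(f"ACC{i}", sp, region, seq)
            for i, (sp, seq) in enumerate(species_seqs)]


class TestClassify:
    def test_identical_to_reference(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = rv.mutate_haplotype(a, 0.15, rng)
        refs = _refs([("SpA", a), ("SpB", b)])
        res = rv.classify("q", a, "ITS", refs, origin="SpA")
        assert res.assigned == "SpA" and res.distance == 0.0
        assert res.flag == "concordant" and res.margin > 0

    def test_cross_species_minor_variant_is_outlier(self, rng):
        spa = "".join(rng.choice(list("ACGT"), size=300))
        spb = rv.mutate_haplotype(spa, 0.10, rng)
        # a minor variant of an SpA strain that drifted toward SpB
        minor = rv.mutate_haplotype(spb, 0.02, rng)
        refs = _refs([("SpA", spa), ("SpB", spb)])
        res = rv.classify("minor", minor, "ITS", refs, origin="SpA")
        assert res.assigned == "SpB" and res.flag == "outlier"

    def test_empty_reference_region_is_error(self):
        with pytest.raises(ValueError):
            rv.classify("q", "ACGT", "ITS", _refs([("SpA", "ACGT")], "LSU"))

    def test_reference_order_invariance(self, rng):
        seqs = [(f"Sp{i}", "".join(rng.choice(list("ACGT"), size=200)))
                for i in range(4)]
        refs = _refs(seqs)
        q = rv.mutate_haplotype(seqs[2][1], 0.03, rng)
        a = rv.classify("q", q, "ITS", refs)
        b = rv.classify("q", q, "ITS", list(reversed(refs)))
        assert a.assigned == b.assigned == "Sp2"

    def test_max_read_consensus_concordant_on_study(self, small_pipeline):
        flags = small_pipeline.classification["flag"]
        assert (flags == "concordant").all()


class TestClassifyCombined:
    def test_both_regions_identical(self, rng):
        its = "".join(rng.choice(list("ACGT"), size=200))
        lsu = "".join(rng.choice(list("ACGT"), size=300))
        refs = (_refs([("SpA", its)], "ITS") + _refs([("SpA", lsu)], "LSU")
                + _refs([("SpB", rv.mutate_haplotype(its, 0.1, rng))], "ITS")
                + _refs([("SpB", rv.mutate_haplotype(lsu, 0.1, rng))], "LSU"))
        res = rv.classify_combined("q", its, lsu, refs, origin="SpA")
        assert res.assigned == "SpA" and res.distance == 0.0

    def test_disagreeing_regions_resolved_by_length_weighting(self):
        # ITS (100 bp) says SpA, LSU (300 bp) says SpB; LSU carries 3x weight
        its_a, lsu_a = "A" * 100, "C" * 300
        its_b = "T" * 10 + "A" * 90       # d=0.10 from query ITS
        lsu_b = "G" * 6 + "C" * 294       # d=0.02 from query LSU
        refs = (_refs([("SpA", its_b)], "ITS") + _refs([("SpA", lsu_a)], "LSU")
                + _refs([("SpB", its_a)], "ITS") + _refs([("SpB", lsu_b)], "LSU"))
        # SpA: (100*0.10 + 300*0) / 400 = 0.025
        # SpB: (100*0 + 300*0.02) / 400 = 0.015 -> SpB wins
        res = rv.classify_combined("q", its_a, lsu_a, refs)
        assert res.assigned == "SpB"
        assert res.distance == pytest.approx(0.015)
        assert res.margin == pytest.approx(0.010)

    def test_missing_region_falls_back_to_single(self, rng):
        its = "".join(rng.choice(list("ACGT"), size=200))
        refs = _refs([("SpA", its)], "ITS")
        res = rv.classify_combined("q", its, None, refs)
        assert res.assigned == "SpA"

    def test_combined_accuracy_at_least_single_region(self):
        """Over seeded replicates, two-region classification is never
        worse than either single region."""
        for seed in range(8):
            study = rv.simulate_study(rv.StudyConfig(
                n_species=3, strains_per_species=1,
                dominant_reads_range=(5, 8), minor_count_range=(0, 0),
                seed=seed))
            refs = study.references
            accs = {"ITS": [], "LSU": [], "combined": []}
            for strain in study.strains:
                truth = study.truths[strain.strain_id]
                its, lsu = truth.expected_its[0], truth.expected_lsu[0]
                origin = study.species_of[strain.strain_id]
                accs["ITS"].append(
                    rv.classify("q", its, "ITS", refs, origin).flag
                    == "concordant")
                accs["LSU"].append(
                    rv.classify("q", lsu, "LSU", refs, origin).flag
                    == "concordant")
                accs["combined"].append(
                    rv.classify_combined("q", its, lsu, refs, origin).flag
                    == "concordant")
            assert np.mean(accs["combined"]) >= max(np.mean(accs["ITS"]),
                                                    np.mean(accs["LSU"]))


class TestNjTree:
    def test_three_taxa_unique_topology(self):
        dm = rv.p_distance_matrix(["a", "b", "c"],
                                  ["A" * 50, "A" * 45 + "T" * 5,
                                   "A" * 40 + "T" * 10])
        newick = rv.nj_tree(dm)
        assert newick.endswith(";")
        import skbio
        tree = skbio.TreeNode.read([newick])
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}

    def test_additive_distances_recover_topology(self):
        import skbio
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        data = np.array([[0, 3, 5, 6],
                         [3, 0, 6, 7],
                         [5, 6, 0, 7],
                         [6, 7, 7, 0]], dtype=float)
        dm = skbio.DistanceMatrix(data, ids=list("ABCD"))
        tree = skbio.TreeNode.read([rv.nj_tree(dm)])
        # A and B must be sisters: their path crosses one internal node
        dist_ab = tree.find("A").distance(tree.find("B"))
        assert dist_ab == pytest.approx(3.0)
        expected = skbio.TreeNode.read(["((A,B),(C,D));"])
        assert tree.compare_rfd(expected) == 0.0

    def test_fewer_than_three_labels_is_error(self):
        import skbio
        dm = skbio.DistanceMatrix(np.array([[0, 1.], [1, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            rv.nj_tree(dm)
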