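"""Group taxonomy: rule order, hairpin gating, novel discovery, naming."""

import numpy as np
import pytest

from mirpipe.annotate import Annotator, map_to_genome
from mirpipe.io import MatureRecord, ReferenceBundle, revcomp


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="module")
def mini_bundle():
    """Hand-built bundle covering every classification branch."""
    rng = np.random.default_rng(99)

    spec_mature = "TGACCGTTAGCATCAGGTACC"
    spec_arm = "GGATC" + spec_mature + "CTAG"
    spec_prec = spec_arm + "AGTTTCAA" + revcomp(spec_arm)

    sel1_mature = "CAGGTTCAAGTCGATCCAGTT"   # precursor planted in the genome -> 1b
    sel1_arm = "TCCAA" + sel1_mature + "GTCA"
    sel1_prec = sel1_arm + "TCCGGATA" + revcomp(sel1_arm)

    sel2_mature = "GTACCAGTTAACGTCTTGCAA"   # mature inside a genomic hairpin -> 2a
    sel2_prec = "AAGGC" + sel2_mature + "TTGA" + "CATGCATG" + "TTTTTGGGGGCCCCCAAAAACGTACG"

    sel3_mature = "ATCGGATTCACGCTAAGGTCC"   # mature flat in the genome -> 2b
    sel3_prec = "CCTGA" + sel3_mature + "ACGT" + "GGGGAAAA" + "TACGTACGTACGTACGGCATTTAACC"

    sel4_mature = "TTGCAACCGGTTAACCAGGTC"   # nowhere in the genome -> 3b
    sel4_prec = "AATCG" + sel4_mature + "CTGA" + "CCCCAAAA" + "ACGGTTTACGGATCCAGTACGGAATTCC"

    novel_mature = "CCATTGCGTAACGGTCAGGTA"
    novel_arm = "ATGCC" + novel_mature + "GTCA"
    novel_prec = novel_arm + "TTCAGGAA" + revcomp(novel_arm)

    sel2_hairpin_arm = "AAGGC" + sel2_mature + "TTGA"
    sel2_genomic = sel2_hairpin_arm + "CATGCATG" + revcomp(sel2_hairpin_arm)

    contig1 = (
        _random_seq(rng, 400) + spec_prec + _random_seq(rng, 400)
        + sel1_prec + _random_seq(rng, 400)
    )
    contig2 = (
        _random_seq(rng, 400) + sel2_genomic + _random_seq(rng, 400)
        # flat copy in an unpairable poly-A context: no hairpin can form
        + "A" * 150 + sel3_mature + "A" * 150 + _random_seq(rng, 400)
        + revcomp(novel_prec) + _random_seq(rng, 400)
    )
    bundle = ReferenceBundle(
        specific_precursors={"stu-MIR100": spec_prec},
        specific_matures={"stu-miR100-5p": MatureRecord("stu-miR100-5p", "stu-MIR100", 5, 26, "5p")},
        selected_precursors={
            "sly-MIR201": sel1_prec, "sly-MIR202": sel2_prec,
            "sly-MIR203": sel3_prec, "sly-MIR204": sel4_prec,
        },
        selected_matures={
            "sly-miR201": MatureRecord("sly-miR201", "sly-MIR201", 5, 26, "5p"),
            "sly-miR202": MatureRecord("sly-miR202", "sly-MIR202", 5, 26, "5p"),
            "sly-miR203": MatureRecord("sly-miR203", "sly-MIR203", 5, 26, "5p"),
            "sly-miR204": MatureRecord("sly-miR204", "sly-MIR204", 5, 26, "5p"),
        },
        genome={"c1": contig1, "c2": contig2},
    )
    return bundle, {
        "spec_mature": spec_mature, "spec_prec": spec_prec,
        "sel1": sel1_mature, "sel2": sel2_mature, "sel3": sel3_mature,
        "sel4": sel4_mature, "novel": novel_mature,
    }


@pytest.fixture(scope="module")
def annotator(mini_bundle):
    bundle, _ = mini_bundle
    return Annotator(bundle)


class TestGroupAssignment:
    def test_specific_mature_is_1a(self, annotator, mini_bundle):
        _, seqs = mini_bundle
        rec = annotator.classify(seqs["spec_mature"])
        assert rec.group == "1a"
        assert rec.name == "stu-miR100-5p"

    def test_specific_isomir_is_1a_with_suffix(self, annotator, mini_bundle):
        _, seqs = mini_bundle
        prec = seqs["spec_prec"]
        rec = annotator.classify(prec[7:28])   # L-2 R+2 variant
        assert rec.group == "1a"
        assert rec.name == "stu-miR100-5p_L-2R+2"

    def test_opposite_arm_is_1a_p_candidate(self, annotator, mini_bundle):
        _, seqs = mini_bundle
        prec = seqs["spec_prec"]
        rec = annotator.classify(prec[40:61])  # inside the 3' arm
        assert rec.group == "1a"
        assert rec.name == "stu-MIR100-p3"

    def test_selected_with_genomic_precursor_is_1b(self, annotator, mini_bundle):
        _, seqs = mini_bundle
        rec = annotator.classify(seqs["sel1"])
        assert rec.group == "1b"
        assert rec.name == "sly-miR201"

    def test_selected_mature_in_genomic_hairpin_is_2a(self, annotator, mini_bundle):
        _, seqs = mini_bundle
        rec = annotator.classify(seqs["sel2"])
        assert rec.group == "2a"

    def test_selected_mature_flat_in_genome_is_2b(self, annotator, mini_bundle):
        _, seqs = mini_bundle
        rec = annotator.classify(seqs["sel3"])
        assert rec.group == "2b"

    def test_selected_mature_absent_from_genome_is_3b(self, annotator, mini_bundle):
        _, seqs = mini_bundle
        rec = annotator.classify(seqs["sel4"])
        assert rec.group == "3b"

    def test_unknown_tag_in_genomic_hairpin_is_4a(self, annotator, mini_bundle):
        _, seqs = mini_bundle
        rec = annotator.classify(seqs["novel"], total_count=37)
        assert rec.group == "4a"
        assert rec.name.startswith("PC-")
        assert rec.name.endswith("_37")

    def test_contaminant_fate_is_others(self, annotator):
        rec = annotator.classify("ACGTACGTACGTACGTACGTA", fate="rRNA")
        assert rec.group == "others"

    def test_unmatched_tag_is_nohit(self, annotator):
        rec = annotator.classify("TACGATCGGATCATGCCTAGA")
        assert rec.group == "nohit"

    def test_every_tag_gets_exactly_one_group(self, annotator, mini_bundle):
        _, seqs = mini_bundle
        rng = np.random.default_rng(3)
        for _ in range(50):
            tag = _random_seq(rng, int(rng.integers(18, 26)))
            rec = annotator.classify(tag)
            assert rec.group in ("1a", "1b", "2a", "2b", "3a", "3b", "4a", "others", "nohit")


class TestGenomeMapping:
    def test_both_strands_found(self, mini_bundle):
        # a stem-loop carries the mature on one strand and, via the opposite
        # arm, its complement -> the exact search must report both strands
        bundle, seqs = mini_bundle
        hits = map_to_genome(seqs["novel"], bundle.genome)
        assert len(hits) == 2
        assert {h.strand for h in hits} == {"+", "-"}

    def test_multimapping_capped(self):
        genome = {"c": ("ACGTTGCAGGTCCATGAACGTTAGC" * 1 + "TTTT") * 15}
        tag = "ACGTTGCAGGTCCATGAACG"
        hits = map_to_genome(tag, genome, max_loci=10)
        assert len(hits) == 11  # cap + 1 signals the over-cap case
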