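"""Junction-window coverage, indel calling, UMI collapse, and tallies."""

import pytest

from anchorseq.align import Edit
from anchorseq.quantify import (
    AMBIGUOUS,
    ClassifiedRead,
    QuantifyConfig,
    call_small_indel,
    collapse_umis,
    covers_junction,
    tally,
)
from anchorseq.reference import enumerate_outcomes


def M(pos, n):
    return Edit("MATCH", pos, n)


class TestCoversJunction:
    def test_full_match_span_covers(self, crafted_alignment):
        aln = crafted_alignment(330, 370, [M(330, 40)])
        assert covers_junction([aln], 350, 15)

    def test_read_ending_at_offset_plus_14_misses_half_open_bound(self, crafted_alignment):
        aln = crafted_alignment(300, 364, [M(300, 64)])
        assert not covers_junction([aln], 350, 15)
        assert covers_junction([crafted_alignment(300, 365, [M(300, 65)])], 350, 15)

    def test_deletion_crossing_junction_fails_strict_rule(self, crafted_alignment):
        edits = [M(300, 48), Edit("DEL", 348, 5), M(353, 47)]
        aln = crafted_alignment(300, 400, edits)
        assert not covers_junction([aln], 350, 15, require_contiguous=True)
        assert covers_junction([aln], 350, 15, require_contiguous=False)

    def test_insertion_at_junction_fails_strict_rule(self, crafted_alignment):
        edits = [M(300, 50), Edit("INS", 350, 4, "ACGT"), M(350, 50)]
        aln = crafted_alignment(300, 400, edits)
        assert not covers_junction([aln], 350, 15)

    def test_gap_outside_window_is_allowed(self, crafted_alignment):
        edits = [M(300, 20), Edit("DEL", 320, 3), M(323, 77)]
        aln = crafted_alignment(300, 400, edits)
        assert covers_junction([aln], 350, 15)

    def test_second_mate_may_provide_coverage(self, crafted_alignment):
        short = crafted_alignment(300, 340, [M(300, 40)])
        long = crafted_alignment(320, 380, [M(320, 60)])
        assert covers_junction([short, long], 350, 15)
        assert covers_junction([None, long], 350, 15)
        assert not covers_junction([short, None], 350, 15)


class TestCallSmallIndel:
    def test_pure_match_window_is_wildtype(self, crafted_alignment):
        aln = crafted_alignment(300, 400, [M(300, 100)])
        assert call_small_indel([aln], 350) is None

    def test_three_base_deletion_descriptor(self, crafted_alignment):
        edits = [M(300, 49), Edit("DEL", 349, 3), M(352, 48)]
        aln = crafted_alignment(300, 400, edits)
        desc = call_small_indel([aln], 350)
        assert desc.deleted_length == 3 and desc.inserted_bases == ""
        assert (desc.ref_start, desc.ref_end) == (349, 352)

    def test_insertion_at_cut(self, crafted_alignment):
        edits = [M(300, 50), Edit("INS", 350, 2, "TT"), M(350, 50)]
        desc = call_small_indel([crafted_alignment(300, 400, edits)], 350)
        assert desc.inserted_bases == "TT" and desc.deleted_length == 0

    def test_indel_outside_window_ignored(self, crafted_alignment):
        edits = [M(300, 10), Edit("DEL", 310, 4), M(314, 86)]
        assert call_small_indel([crafted_alignment(300, 400, edits)], 350, 15) is None

    def test_non_spanning_alignment_skipped(self, crafted_alignment):
        aln = crafted_alignment(300, 340, [M(300, 40)])
        assert call_small_indel([aln], 350) is None


class TestCollapseUmis:
    def test_duplicates_collapse_to_one_molecule(self):
        reads = [ClassifiedRead("s", "ACGTACGTAC", "DELETION") for _ in range(5)]
        mols = collapse_umis(reads)
        assert len(mols) == 1
        assert mols[0].supporting_reads == 5 and mols[0].category == "DELETION"

    def test_distinct_umis_stay_separate(self):
        reads = [
            ClassifiedRead("s", "ACGTACGTAC", "DELETION"),
            ClassifiedRead("s", "TTTTACGTAC", "DELETION"),
        ]
        assert len(collapse_umis(reads)) == 2

    def test_majority_vote_and_tie(self):
        reads = [ClassifiedRead("s", "A" * 10, "DELETION")] * 3 + [
            ClassifiedRead("s", "A" * 10, "WILDTYPE")
        ]
        (mol,) = collapse_umis(reads)
        assert mol.category == "DELETION"
        tie = [
            ClassifiedRead("s", "A" * 10, "DELETION"),
            ClassifiedRead("s", "A" * 10, "WILDTYPE"),
        ]
        assert collapse_umis(tie)[0].category == AMBIGUOUS

    def test_hamming1_directional_collapse(self):
        reads = [ClassifiedRead("s", "ACGTACGTAC", "DELETION")] * 9 + [
            ClassifiedRead("s", "ACGTACGTAT", "DELETION")
        ]
        cfg = QuantifyConfig(umi_collapse="HAMMING1")
        mols = collapse_umis(reads, cfg)
        assert len(mols) == 1 and mols[0].supporting_reads == 10
        # EXACT keeps them apart
        assert len(collapse_umis(reads)) == 2
        # equal counts do not absorb (directional threshold 2c-1)
        balanced = [ClassifiedRead("s", "ACGTACGTAC", "DELETION")] * 3 + [
            ClassifiedRead("s", "ACGTACGTAT", "DELETION")
        ] * 3
        assert len(collapse_umis(balanced, cfg)) == 2

    def test_min_reads_per_umi_filter(self):
        reads = [
            ClassifiedRead("s", "A" * 10, "DELETION"),
            ClassifiedRead("s", "C" * 10, "DELETION"),
            ClassifiedRead("s", "C" * 10, "DELETION"),
        ]
        cfg = QuantifyConfig(min_reads_per_umi=2)
        mols = collapse_umis(reads, cfg)
        assert len(mols) == 1 and mols[0].umi == "C" * 10

    def test_config_validation(self):
        with pytest.raises(ValueError):
            QuantifyConfig(junction_window=0)
        with pytest.raises(ValueError):
            QuantifyConfig(umi_collapse="FUZZY")


@pytest.fixture(scope="module")
def detectable():
    """Detectable classes at the dual-cut model's primer: includes the
    deletion, both inversion junctions and a homolog fusion."""
    from anchorseq.experiments import dual_cut_model
    from anchorseq.reference import detectable_classes

    model = dual_cut_model(seed=0)
    classes = enumerate_outcomes(model.cuts)
    return [jc for jc, _ in detectable_classes(classes, model.primers)]


@pytest.fixture(scope="module")
def detectable_cross(cross_loci):
    from anchorseq.reference import AnchorPrimer, detectable_classes

    classes = enumerate_outcomes(cross_loci)
    primers = [
        AnchorPrimer("pA", cross_loci[0].left_end, 50),
        AnchorPrimer("pB", cross_loci[1].left_end, 50),
    ]
    return [jc for jc, _ in detectable_classes(classes, primers)]


def mols(spec):
    from anchorseq.quantify import ClassifiedMolecule

    out = []
    i = 0
    for category, n in spec:
        for _ in range(n):
            out.append(ClassifiedMolecule("s", f"U{i:06d}", category, 1))
            i += 1
    return out


class TestTally:
    def test_simple_frequencies(self, detectable):
        table = tally(mols([("DELETION", 40), ("WILDTYPE", 60)]), detectable)
        assert table.denominator == 100
        assert table.frequency("DELETION") == pytest.approx(0.40)
        assert table.frequency("WILDTYPE") == pytest.approx(0.60)

    def test_single_category_is_unity(self, detectable):
        table = tally(mols([("SMALL_INDEL", 25)]), detectable)
        assert table.frequency("SMALL_INDEL") == 1.0

    def test_frequencies_sum_to_one(self, detectable):
        table = tally(
            mols([("DELETION", 10), ("WILDTYPE", 20), ("INVERSION", 3), ("UNASSIGNED", 4)]),
            detectable,
        )
        assert sum(r["frequency"] for r in table.rows) == pytest.approx(1.0)

    def test_empty_input_no_division(self, detectable):
        table = tally([], detectable)
        assert table.denominator == 0
        assert all(r["frequency"] == 0.0 for r in table.rows)

    def test_conservation_of_molecules(self, detectable):
        spec = [("DELETION", 7), ("WILDTYPE", 11), ("UNASSIGNED", 3), ("AMBIGUOUS", 2)]
        table = tally(mols(spec), detectable)
        assert (
            table.denominator + table.qc["unassigned"] + table.qc["ambiguous"]
            == table.qc["total_molecules"]
            == 23
        )

    def test_fusion_frequency_sums_subtypes(self, detectable_cross):
        table = tally(
            mols([("FUSION_LR", 2), ("FUSION_LL", 3), ("WILDTYPE", 95)]), detectable_cross
        )
        assert table.fusion_frequency() == pytest.approx(0.05)

    def test_duplication_invariance(self, detectable):
        """Multiplying every molecule's PCR depth leaves frequencies unchanged."""
        base = []
        for i, (cat, n) in enumerate([("DELETION", 30), ("WILDTYPE", 50), ("SMALL_INDEL", 20)]):
            for j in range(n):
                base.append(("s", f"U{i}_{j:04d}", cat))
        for k in (1, 3, 7):
            reads = [
                ClassifiedRead(s, u, c) for s, u, c in base for _ in range(k)
            ]
            table = tally(collapse_umis(reads), detectable)
            assert table.frequency("DELETION") == pytest.approx(0.30)
            assert table.denominator == 100

    def test_tsv_output(self, tmp_path, detectable):
        table = tally(mols([("DELETION", 1), ("WILDTYPE", 1)]), detectable)
        path = tmp_path / "f.tsv"
        table.to_tsv(path)
        text = path.read_text()
        assert "0-based" in text.splitlines()[0]
        assert "0.500000" in text
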