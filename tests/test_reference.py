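"""Outcome enumeration, amplicon construction, and primer detectability."""

import pytest

from anchorseq.reference import (
    AnchorPrimer,
    ConfigurationError,
    CutSite,
    JunctionKind,
    Locus,
    Side,
    build_amplicons,
    detectable_classes,
    enumerate_outcomes,
    junction_sequence,
    load_model_config,
    reverse_complement,
    write_amplicon_fasta,
)
from oracles import brute_force_outcome_count, rc


class TestEnumerateOutcomes:
    def test_one_cut_gives_three_classes(self, toy_two_cuts):
        classes = enumerate_outcomes(toy_two_cuts[:1])
        kinds = sorted(c.kind.value for c in classes)
        assert kinds == ["HOMOLOG_LL", "HOMOLOG_RR", "NHEJ"]

    def test_two_cuts_distinct_loci_give_ten_classes(self, cross_loci):
        classes = enumerate_outcomes(cross_loci)
        assert len(classes) == 10
        kinds = [c.kind for c in classes]
        for k in (JunctionKind.FUSION_LR, JunctionKind.FUSION_RL, JunctionKind.FUSION_LL, JunctionKind.FUSION_RR):
            assert kinds.count(k) == 1
        assert kinds.count(JunctionKind.NHEJ) == 2
        assert kinds.count(JunctionKind.HOMOLOG_LL) == 2
        assert kinds.count(JunctionKind.HOMOLOG_RR) == 2

    def test_same_locus_two_cuts_include_deletion_and_both_inversion_junctions(self, toy_two_cuts):
        kinds = [c.kind for c in enumerate_outcomes(toy_two_cuts)]
        assert kinds.count(JunctionKind.DELETION) == 1
        assert kinds.count(JunctionKind.INVERSION_J1) == 1
        assert kinds.count(JunctionKind.INVERSION_J2) == 1
        assert len(kinds) == 10

    @pytest.mark.parametrize("n_cuts", [1, 2])
    def test_matches_brute_force_end_pairing(self, cross_loci, n_cuts):
        cuts = cross_loci[:n_cuts]
        classes = enumerate_outcomes(cuts)
        flank = 15
        end_seqs = {}
        for c in cuts:
            end_seqs[f"{c.locus.name}:L"] = c.locus.sequence[c.position - flank : c.position]
            end_seqs[f"{c.locus.name}:R"] = rc(c.locus.sequence[c.position : c.position + flank])
        expected = brute_force_outcome_count(end_seqs)
        assert len(classes) == len(expected)
        # every enumerated class realizes exactly one brute-force junction
        got = {
            min(s, rc(s))
            for s in (junction_sequence(jc, flank) for jc in classes)
        }
        assert got == expected

    def test_canonicalization_is_idempotent(self, cross_loci):
        from anchorseq.reference import _canonical_pair

        for jc in enumerate_outcomes(cross_loci):
            assert _canonical_pair(*jc.ends) == jc.ends

    def test_unsupported_configurations(self, cross_loci, toy_two_cuts):
        with pytest.raises(ConfigurationError):
            enumerate_outcomes([])
        with pytest.raises(ConfigurationError):
            enumerate_outcomes(list(cross_loci) + toy_two_cuts[:1])


class TestBuildAmplicons:
    def test_nhej_amplicon_equals_unedited_locus_slice(self, toy_locus, toy_two_cuts):
        classes = [c for c in enumerate_outcomes(toy_two_cuts) if c.kind is JunctionKind.NHEJ]
        cut = toy_two_cuts[0]
        amp = next(
            a
            for a in build_amplicons(classes, flank=10, include_wildtype=False)
            if a.junction_class.ends[0].cut == cut
        )
        assert amp.sequence == toy_locus.sequence[10:30]
        assert amp.junction_offsets == (10,)

    def test_inversion_j1_right_half_is_rc_of_intercut_segment(self, toy_locus, toy_two_cuts):
        j1 = next(c for c in enumerate_outcomes(toy_two_cuts) if c.kind is JunctionKind.INVERSION_J1)
        amp = build_amplicons([j1], flank=10, include_wildtype=False)[0]
        mid = toy_locus.sequence[20:40]
        assert amp.sequence[10:] == reverse_complement(mid)[:10]
        assert amp.sequence[:10] == toy_locus.sequence[10:20]

    def test_deletion_arithmetic_for_1176_bp_separation(self):
        from anchorseq.experiments import dual_cut_model

        model = dual_cut_model(seed=0)
        classes = enumerate_outcomes(model.cuts)
        deletion = next(c for c in classes if c.kind is JunctionKind.DELETION)
        flank = 350
        amps = build_amplicons([deletion], flank=flank, include_wildtype=True)
        del_amp = next(a for a in amps if not a.is_wildtype)
        assert len(del_amp) == 2 * flank
        # wild-type span covering both cuts with the same flanks vs the
        # deletion amplicon: difference equals the cut separation
        c1, c2 = sorted(c.position for c in model.cuts)
        wildtype_span = (c2 + flank) - (c1 - flank)
        assert wildtype_span - len(del_amp) == c2 - c1 == 1176

    def test_junction_offsets_strictly_inside(self, toy_two_cuts):
        for amp in build_amplicons(enumerate_outcomes(toy_two_cuts), flank=10):
            for off in amp.junction_offsets:
                assert 0 < off < len(amp)

    def test_flank_bounds_error(self, toy_two_cuts):
        with pytest.raises(ConfigurationError):
            build_amplicons(enumerate_outcomes(toy_two_cuts), flank=30)

    def test_every_half_matches_a_source_locus_substring(self, cross_loci):
        loci = {c.locus for c in cross_loci}
        for amp in build_amplicons(enumerate_outcomes(cross_loci), flank=25, include_wildtype=True):
            off = amp.junction_offsets[0]
            for half in (amp.sequence[:off], amp.sequence[off:]):
                assert any(
                    half in l.sequence or reverse_complement(half) in l.sequence
                    for l in loci
                )


class TestDetectableClasses:
    def test_two_left_primers_detect_seven_of_ten(self, cross_loci):
        classes = enumerate_outcomes(cross_loci)
        primers = [
            AnchorPrimer("pA", cross_loci[0].left_end, 50),
            AnchorPrimer("pB", cross_loci[1].left_end, 50),
        ]
        det = detectable_classes(classes, primers)
        assert len(det) == 7
        missed = [jc for jc in classes if jc not in [d[0] for d in det]]
        assert sorted(jc.kind.value for jc in missed) == [
            "FUSION_RR",
            "HOMOLOG_RR",
            "HOMOLOG_RR",
        ]

    def test_empty_primer_list(self, cross_loci):
        assert detectable_classes(enumerate_outcomes(cross_loci), []) == []

    def test_one_primer_per_end_detects_everything(self, cross_loci):
        classes = enumerate_outcomes(cross_loci)
        primers = [
            AnchorPrimer(f"p{i}", end, 50)
            for i, end in enumerate(
                e for c in cross_loci for e in (c.left_end, c.right_end)
            )
        ]
        assert len(detectable_classes(classes, primers)) == len(classes)

    def test_detecting_primers_annotated(self, cross_loci):
        classes = enumerate_outcomes(cross_loci)
        primer = AnchorPrimer("pA", cross_loci[0].left_end, 50)
        for jc, hits in detectable_classes(classes, [primer]):
            assert primer in hits and jc.involves(primer.end)


class TestDomainValidation:
    def test_locus_rejects_invalid_bases(self):
        with pytest.raises(ConfigurationError):
            Locus("bad", "ACGTN")

    def test_cut_position_bounds(self, toy_locus):
        with pytest.raises(ConfigurationError):
            CutSite(toy_locus, 0)
        with pytest.raises(ConfigurationError):
            CutSite(toy_locus, len(toy_locus))

    def test_centromere_labels(self):
        la = Locus("A", "ACGT" * 50, centromere_side="LEFT")
        lb = Locus("B", "GGCA" * 50, centromere_side="LEFT")
        classes = enumerate_outcomes([CutSite(la, 100), CutSite(lb, 100)])
        labels = {c.kind: c.label for c in classes if c.kind.value.startswith("FUSION")}
        assert labels[JunctionKind.FUSION_LR] == "balanced"
        assert labels[JunctionKind.FUSION_RL] == "balanced"
        assert labels[JunctionKind.FUSION_LL] == "dicentric"
        assert labels[JunctionKind.FUSION_RR] == "acentric"


class TestConfigIO:
    def test_yaml_roundtrip_and_export(self, tmp_path, toy_locus):
        cfg = {
            "loci": [{"name": "toy", "sequence": toy_locus.sequence}],
            "cuts": [
                {"locus": "toy", "position": 20, "guide": "a"},
                {"locus": "toy", "position": 40, "guide": "b"},
            ],
            "primers": [
                {"name": "p1", "locus": "toy", "guide": "b", "side": "RIGHT", "distance_to_cut": 5}
            ],
        }
        model = load_model_config(cfg)
        assert model.primer_by_name("p1").end.side is Side.RIGHT
        amps = build_amplicons(model.outcome_classes(), flank=10)
        fasta, tsv = tmp_path / "a.fasta", tmp_path / "a.tsv"
        write_amplicon_fasta(amps, fasta, tsv)
        from Bio import SeqIO

        records = list(SeqIO.parse(str(fasta), "fasta"))
        assert len(records) == len(amps)
        lines = tsv.read_text().splitlines()
        assert lines[0].startswith("#") and "0-based" in lines[0]
        assert len(lines) == len(amps) + 2
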