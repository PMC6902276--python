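import numpy as np
import pytest

from conftest import make_genome_for
from zebralift.annotation_core import (
    DEFAULT_SPLICE_MOTIFS,
    FeatureClass,
    OrfParams,
    OrfRule,
    SpliceMotifSet,
    TranscriptModel,
    build_feature_track,
    check_orf_state,
    extract_cds_sequence,
    reverse_complement,
)
from zebralift.errors import ContractError


def single_exon(seq_len, chrom="c1", strand="+", start=0):
    return TranscriptModel(
        "g", "t", chrom, strand, [(start, start + seq_len)], [(start, start + seq_len)]
    )


class TestExtractCds:
    def test_split_cds_concatenates_in_genomic_order(self):
        t = TranscriptModel("g", "t", "c1", "+", [(0, 3), (6, 9)], [(0, 3), (6, 9)])
        assert extract_cds_sequence(t, {"c1": "ATGCCCTAA"}) == "ATGTAA"

    def test_minus_strand_reverse_complements(self):
        t = TranscriptModel("g", "t", "c1", "-", [(0, 6)], [(0, 6)])
        assert extract_cds_sequence(t, {"c1": "TTACAT"}) == "ATGTAA"

    def test_out_of_bounds_cds_is_contract_error(self):
        t = TranscriptModel("g", "t", "c1", "+", [(5, 12)], [(5, 12)])
        with pytest.raises(ContractError):
            extract_cds_sequence(t, {"c1": "ACGTACGTAC"})


class TestOrfRules:
    """One positive and one negative toy case per integrity rule."""

    def test_minimal_intact_orf(self):
        state = check_orf_state(single_exon(6), {"c1": "ATGTAA"},
                                OrfParams(min_intron_length=10, min_cds_length=3))
        assert state.intact

    def test_premature_stop(self):
        state = check_orf_state(single_exon(9), {"c1": "ATGTAGTAA"},
                                OrfParams(min_cds_length=3))
        assert state.failed_rules == {OrfRule.PREMATURE_STOP}

    def test_frame_violation(self):
        state = check_orf_state(single_exon(5), {"c1": "ATGCA"},
                                OrfParams(min_cds_length=3))
        assert OrfRule.FRAME in state.failed_rules

    def test_missing_start_and_stop(self):
        state = check_orf_state(single_exon(6), {"c1": "CCCCCC"},
                                OrfParams(min_cds_length=3))
        assert {OrfRule.NO_START, OrfRule.NO_END_STOP} <= state.failed_rules

    def test_short_cds(self):
        state = check_orf_state(single_exon(6), {"c1": "ATGTAA"},
                                OrfParams(min_cds_length=9))
        assert OrfRule.MIN_CDS_LEN in state.failed_rules

    def test_bad_splice_motif(self):
        # two-exon gene with a CT..AC intron: not a default motif pair
        t = TranscriptModel("g", "t", "c1", "+", [(0, 3), (23, 29)],
                            [(0, 3), (23, 29)])
        genome = {"c1": "ATG" + "CT" + "G" * 16 + "AC" + "GCCTAA"}
        state = check_orf_state(t, genome, OrfParams(min_cds_length=3))
        assert state.failed_rules == {OrfRule.SPLICE_MOTIF}

    def test_short_intron(self):
        t = TranscriptModel("g", "t", "c1", "+", [(0, 3), (7, 13)], [(0, 3), (7, 13)])
        genome = {"c1": "ATG" + "GTAG" + "GCCTAA"}
        state = check_orf_state(t, genome, OrfParams(min_intron_length=5,
                                                     min_cds_length=3))
        assert OrfRule.MIN_INTRON in state.failed_rules

    def test_all_failures_reported_not_just_first(self):
        state = check_orf_state(single_exon(5), {"c1": "TAGCA"},
                                OrfParams(min_cds_length=9))
        assert {OrfRule.FRAME, OrfRule.NO_START, OrfRule.MIN_CDS_LEN} <= (
            state.failed_rules
        )


class TestIupacSemantics:
    def test_ambiguous_codons_do_not_fail_permissive_rules(self):
        # NNN last codon may resolve to a stop; ANG first may resolve to ATG
        state = check_orf_state(single_exon(9), {"c1": "ANGCCCNNN"},
                                OrfParams(min_cds_length=3))
        assert OrfRule.NO_END_STOP not in state.failed_rules
        assert OrfRule.NO_START not in state.failed_rules

    def test_nnn_is_not_a_premature_stop(self):
        state = check_orf_state(single_exon(9), {"c1": "ATGNNNTAA"},
                                OrfParams(min_cds_length=3))
        assert state.intact

    def test_nnn_has_an_intact_resolution(self):
        # the permissive semantics claim: some resolution of N is stop-free
        found = any(
            mid not in ("TAA", "TAG", "TGA")
            for mid in ("".join(c) for c in __import__("itertools").product("ACGT",
                                                                            repeat=3))
        )
        assert found
        state = check_orf_state(single_exon(9), {"c1": "ATGNNNTAA"},
                                OrfParams(min_cds_length=3))
        assert state.intact

    def test_every_resolution_stop_is_premature(self):
        # TRA with R in {A,G}: both TAA and TGA are stops
        state = check_orf_state(single_exon(9), {"c1": "ATGTRATAA"},
                                OrfParams(min_cds_length=3))
        assert OrfRule.PREMATURE_STOP in state.failed_rules

    def test_ambiguous_splice_motif_matches_by_intersection(self):
        t = TranscriptModel("g", "t", "c1", "+", [(0, 3), (23, 29)],
                            [(0, 3), (23, 29)])
        genome = {"c1": "ATG" + "GN" + "G" * 16 + "NG" + "GCCTAA"}
        state = check_orf_state(t, genome, OrfParams(min_cds_length=3))
        assert OrfRule.SPLICE_MOTIF not in state.failed_rules


class TestStrandInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_mirror_gene_has_identical_orf_state(self, seed):
        from zebralift.fixtures import FixtureSpec, generate_genome_with_annotation

        spec = FixtureSpec(seed=seed, chromosome_length=4000, n_genes=1,
                           exons_per_gene=(2, 3), minus_strand_fraction=0.0)
        genome, ann = generate_genome_with_annotation(spec)
        t = next(ann.transcripts())
        L = len(genome[t.chrom])
        mirrored = TranscriptModel(
            t.gene_id, t.transcript_id, t.chrom, "-",
            [(L - e, L - s) for s, e in t.exons],
            [(L - e, L - s) for s, e in t.cds],
        )
        mirror_genome = {t.chrom: reverse_complement(genome[t.chrom])}
        assert check_orf_state(t, genome) == check_orf_state(
            mirrored, mirror_genome
        )


class TestFeatureTrack:
    def test_single_exon_start_stop_precedence(self):
        t = single_exon(9, start=10)
        track = build_feature_track(t, 10, 19)
        assert list(track[:3]) == [FeatureClass.START_STOP_CODON] * 3
        assert list(track[3:6]) == [FeatureClass.CDS] * 3
        assert list(track[6:]) == [FeatureClass.START_STOP_CODON] * 3

    def test_splice_sites_flank_each_internal_intron(self, two_exon_transcript):
        track = build_feature_track(two_exon_transcript, 10, 105)
        off = 10
        for p in (19, 20, 97, 98):
            assert track[p - off] == FeatureClass.SPLICE_SITE
        assert track[50 - off] == FeatureClass.INTRON

    def test_window_margin_is_other(self, two_exon_transcript):
        track = build_feature_track(two_exon_transcript, 5, 110)
        assert list(track[:5]) == [FeatureClass.OTHER] * 5
        assert list(track[-5:]) == [FeatureClass.OTHER] * 5

    def test_label_counts_for_fully_coding_transcripts(self):
        from zebralift.fixtures import FixtureSpec, generate_genome_with_annotation

        spec = FixtureSpec(seed=5, chromosome_length=8000, n_genes=2,
                           exons_per_gene=(2, 4))
        _genome, ann = generate_genome_with_annotation(spec)
        for t in ann.transcripts():
            cs, ce = t.cds_span
            track = build_feature_track(t, cs, ce)
            n_introns = len(t.cds_internal_introns())
            assert int((track == FeatureClass.START_STOP_CODON).sum()) == 6
            assert int((track == FeatureClass.SPLICE_SITE).sum()) == 4 * n_introns

    def test_window_not_covering_cds_is_error(self, two_exon_transcript):
        with pytest.raises(ContractError):
            build_feature_track(two_exon_transcript, 12, 105)


class TestSpliceMotifSet:
    def test_duplicate_pair_rejected(self):
        with pytest.raises(ContractError):
            SpliceMotifSet((("GT", "AG"), ("GT", "AG")))

    def test_default_set_is_canonical(self):
        assert DEFAULT_SPLICE_MOTIFS.pairs == (("GT", "AG"), ("GC", "AG"),
                                               ("AT", "AC"))
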