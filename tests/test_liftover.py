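import numpy as np
import pytest

from zebralift.annotation_core import (
    GenomeAnnotation,
    OrfParams,
    build_feature_track,
    check_orf_state,
)
from zebralift.errors import ContractError
from zebralift.fixtures import (
    FixtureSpec,
    generate_genome_with_annotation,
    plant_ambiguous_indel_locus,
)
from zebralift.formats_io import RangePair
from zebralift.liftover import (
    LiftMethod,
    lift_annotation_assembly,
    lift_annotation_resequencing,
    realign_transcript,
    recall_variants,
    replace_region_variants,
)
from zebralift.pseudogenome import Variant, apply_variants
from zebralift.zdp import AlignmentResult, ScoringProfile, zsdp_align


def small_gene(seed=31, minus=0.0):
    spec = FixtureSpec(seed=seed, chromosome_length=5000, n_genes=1,
                       exons_per_gene=(2, 3), minus_strand_fraction=minus)
    return generate_genome_with_annotation(spec)


class TestRealignTranscript:
    def test_identity_query_returns_identical_model(self, zebraic_profile):
        genome, ann = small_gene()
        t = next(ann.transcripts())
        cs, ce = t.cds_span
        ws, we = max(0, cs - 100), ce + 100
        model, state, _ = realign_transcript(
            t, genome, genome[t.chrom][ws:we], ws, t.chrom,
            zebraic_profile, OrfParams(), query_genome=genome,
        )
        assert state.intact
        assert model.cds == t.cds

    def test_intron_insertion_shifts_downstream_exons(self, zebraic_profile):
        genome, ann = small_gene(seed=32)
        t = next(ann.transcripts())
        a, b = t.cds_internal_introns()[0]
        mid = (a + b) // 2
        anchor = genome[t.chrom][mid]
        pseudo, _ = apply_variants(
            genome[t.chrom], [Variant(t.chrom, mid, anchor, anchor + "TTT")]
        )
        cs, ce = t.cds_span
        ws, we = max(0, cs - 100), ce + 120
        model, state, _ = realign_transcript(
            t, genome, pseudo[ws:we], ws, t.chrom,
            zebraic_profile, OrfParams(), query_genome={t.chrom: pseudo},
        )
        assert state.intact
        for (s0, e0), (s1, e1) in zip(t.cds, model.cds):
            shift = 3 if s0 > mid else 0
            assert (s1, e1) == (s0 + shift, e0 + shift)

    def test_minus_strand_realignment_maps_back(self, zebraic_profile):
        genome, ann = small_gene(seed=33, minus=1.0)
        t = next(ann.transcripts())
        assert t.strand == "-"
        cs, ce = t.cds_span
        ws, we = max(0, cs - 80), ce + 80
        model, state, _ = realign_transcript(
            t, genome, genome[t.chrom][ws:we], ws, t.chrom,
            zebraic_profile, OrfParams(), query_genome=genome,
        )
        assert state.intact
        assert model.cds == t.cds


class TestAmbiguousLocusRescue:
    def _setup(self, seed, rng):
        spec = FixtureSpec(seed=seed, chromosome_length=5000, n_genes=1,
                           exons_per_gene=(2, 3), intron_length=(40, 200),
                           minus_strand_fraction=0.0)
        genome, ann = generate_genome_with_annotation(spec)
        t = next(ann.transcripts())
        genome, t, locus = plant_ambiguous_indel_locus(genome, t, rng)
        s, e = locus.bad_span
        bad = Variant(t.chrom, s - 1,
                      genome[t.chrom][s - 1] + genome[t.chrom][s:e],
                      genome[t.chrom][s - 1])
        return genome, GenomeAnnotation([t]), t, locus, bad

    def test_bad_representation_breaks_standard_lift_zebraic_rescues(self, rng):
        genome, ann, t, locus, bad = self._setup(41, rng)
        _lifted, report, _pseudo, _ = lift_annotation_resequencing(
            ann, genome, [bad]
        )
        entry = report.entries[t.transcript_id]
        assert entry.method == LiftMethod.ZDP_REALIGNED
        assert not entry.orf_before.intact
        assert entry.orf_after.intact

    def test_uniform_profile_keeps_motif_breaking_placement_optimal(self, rng):
        from zebralift.zdp import score_alignment

        genome, ann, t, locus, bad = self._setup(42, rng)
        pseudo, _ = apply_variants(genome[t.chrom], [bad])
        cs, ce = t.cds_span
        track = build_feature_track(t, cs, ce)
        uniform = ScoringProfile.uniform(2, -2, 4, 1)
        res = zsdp_align(genome[t.chrom][cs:ce], track, pseudo[cs : ce + 60],
                         uniform)
        # hand-build the motif-breaking placement and show it scores the same
        gs = locus.bad_span[0] - cs
        ge_ = locus.bad_span[1] - cs
        ra = genome[t.chrom][cs:ce]
        qa = ra[:gs] + "-" * (ge_ - gs) + ra[ge_:]
        forced = score_alignment(ra, qa, track, uniform)
        assert forced == res.score


class TestResequencingLift:
    def test_empty_vcf_is_identity(self):
        genome, ann = small_gene(seed=51)
        lifted, report, pseudo, _ = lift_annotation_resequencing(ann, genome, [])
        assert pseudo == genome
        assert lifted == ann
        assert all(e.method == LiftMethod.STANDARD for e in report.entries.values())
        assert all(e.orf_after.intact for e in report.entries.values())

    def test_synonymous_snp_stays_standard(self):
        genome, ann = small_gene(seed=52)
        t = next(ann.transcripts())
        # third position of an internal GCC codon on the coding strand
        coding = [p for s, e in t.cds for p in range(s, e)]
        if t.strand == "-":
            coding = coding[::-1]
        pos = coding[3 * 5 + 2]
        base = genome[t.chrom][pos]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
        _lifted, report, _pseudo, _ = lift_annotation_resequencing(
            ann, genome, [Variant(t.chrom, pos, base, alt)]
        )
        entry = report.entries[t.transcript_id]
        assert entry.method == LiftMethod.STANDARD
        # a third-position transition is usually synonymous; at minimum the
        # lift must never crash -- intactness is asserted for wobble sites
        # of non-stop-adjacent codons by construction of the fixture genes

    def test_population_of_planted_ambiguities_all_realigned(self, rng):
        planted = 0
        rescued = 0
        for seed in range(6):
            spec = FixtureSpec(seed=60 + seed, chromosome_length=5000, n_genes=1,
                               exons_per_gene=(2, 3), intron_length=(40, 200),
                           minus_strand_fraction=0.0)
            genome, ann = generate_genome_with_annotation(spec)
            t = next(ann.transcripts())
            genome, t, locus = plant_ambiguous_indel_locus(genome, t, rng)
            s, e = locus.bad_span
            bad = Variant(t.chrom, s - 1,
                          genome[t.chrom][s - 1] + genome[t.chrom][s:e],
                          genome[t.chrom][s - 1])
            _l, report, _p, _ = lift_annotation_resequencing(
                GenomeAnnotation([t]), genome, [bad]
            )
            planted += 1
            entry = report.entries[t.transcript_id]
            if entry.method == LiftMethod.ZDP_REALIGNED and entry.orf_after.intact:
                rescued += 1
        assert rescued == planted


class TestAssemblyLift:
    def test_identity_query_full_range_all_standard(self):
        genome, ann = small_gene(seed=71)
        chrom = next(iter(genome))
        rp = RangePair(chrom, 0, len(genome[chrom]), chrom, 0, len(genome[chrom]))
        lifted, report = lift_annotation_assembly(ann, genome, genome, [rp])
        assert all(e.method == LiftMethod.STANDARD for e in report.entries.values())
        assert {t.cds_span for t in lifted.transcripts()} == {
            t.cds_span for t in ann.transcripts()
        }

    def test_transcript_outside_ranges_is_unplaced(self):
        genome, ann = small_gene(seed=72)
        chrom = next(iter(genome))
        rp = RangePair(chrom, 0, 10, chrom, 0, 10)
        _lifted, report = lift_annotation_assembly(ann, genome, genome, [rp])
        assert all(e.method == LiftMethod.UNPLACED for e in report.entries.values())

    def test_planted_indels_keep_all_transcripts_placed_intact(self, rng):
        spec = FixtureSpec(seed=73, chromosome_length=15_000, n_genes=4,
                           n_insertions=4, n_deletions=4, indel_length=(2, 6))
        genome, ann = generate_genome_with_annotation(spec)
        from zebralift.fixtures import plant_variants

        mutated, _truth = plant_variants(genome, ann, spec)
        chrom = next(iter(genome))
        rp = RangePair(chrom, 0, len(genome[chrom]), chrom, 0,
                       len(mutated[chrom]))
        lifted, report = lift_annotation_assembly(ann, genome, mutated, [rp],
                                                  window_size=2000)
        methods = {e.method for e in report.entries.values()}
        assert LiftMethod.UNPLACED not in methods
        intact = sum(
            1 for e in report.entries.values()
            if e.orf_after is not None and e.orf_after.intact
        )
        assert intact >= len(ann) - 1  # an INDEL may genuinely break one ORF


class TestRecallVariants:
    def _aln(self, ra, qa):
        return AlignmentResult(ra, qa, 0, (0, len(ra.replace("-", ""))),
                               (0, len(qa.replace("-", ""))))

    def test_identity_alignment_yields_nothing(self):
        assert recall_variants(self._aln("ACGT", "ACGT"), "c", 0) == []

    def test_single_mismatch_is_one_snp(self):
        (v,) = recall_variants(self._aln("ACGTACGT", "ACGTACGA"), "c", 0)
        assert (v.pos, v.ref_allele, v.alt_allele, v.kind) == (7, "T", "A", "SNP")

    def test_adjacent_gap_columns_merge_into_one_indel(self):
        (v,) = recall_variants(self._aln("AC--GT", "ACTTGT"), "c", 0)
        assert (v.pos, v.ref_allele, v.alt_allele, v.kind) == (1, "C", "CTT", "INS")

    def test_origin_offsets_positions(self):
        (v,) = recall_variants(self._aln("AGGT", "A--T"), "c", 100,
                               chrom_seq="N" * 100 + "AGGT")
        assert (v.pos, v.ref_allele, v.alt_allele) == (100, "AGG", "A")


class TestReplaceRegionVariants:
    def test_replacing_with_same_records_is_identity(self):
        old = [Variant("c", 5, "A", "T"), Variant("c", 50, "G", "GAT")]
        assert replace_region_variants(old, "c", (0, 20), [old[0]]) == sorted(old)

    def test_removal_only(self):
        old = [Variant("c", 5, "A", "T"), Variant("c", 8, "G", "C"),
               Variant("c", 50, "G", "GAT")]
        out = replace_region_variants(old, "c", (0, 20), [])
        assert out == [old[2]]

    def test_new_variant_outside_region_is_contract_error(self):
        with pytest.raises(ContractError):
            replace_region_variants([], "c", (0, 10), [Variant("c", 30, "A", "T")])

    def test_representation_swap_preserves_sequence(self, rng):
        genome, ann = small_gene(seed=81)
        t = next(ann.transcripts())
        genome, t, locus = plant_ambiguous_indel_locus(genome, t, rng)
        chrom = t.chrom
        s, e = locus.bad_span
        bad = Variant(chrom, s - 1,
                      genome[chrom][s - 1] + genome[chrom][s:e],
                      genome[chrom][s - 1])
        s, e = locus.good_span
        good = Variant(chrom, s - 1,
                       genome[chrom][s - 1] + genome[chrom][s:e],
                       genome[chrom][s - 1])
        cs, ce = t.cds_span
        updated = replace_region_variants([bad], chrom, (cs, ce), [good])
        assert updated == [good]
        before, _ = apply_variants(genome[chrom], [bad])
        after, _ = apply_variants(genome[chrom], updated)
        assert before == after
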