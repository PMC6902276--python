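import numpy as np
import pytest

from oracles import (
    admissible_random_profile,
    enumerate_best_score,
    gotoh_semiglobal_score,
)
from zebralift.annotation_core import FeatureClass
from zebralift.errors import ContractError
from zebralift.zdp import (
    AlignmentResult,
    ScoringProfile,
    TracebackLabel,
    score_alignment,
    zdp_align,
    zsdp_align,
)


def random_pair(rng, lo, hi):
    n = int(rng.integers(lo, hi + 1))
    m = int(rng.integers(lo, hi + 1))
    bases = np.array(list("ACGT"))
    ref = "".join(bases[rng.integers(0, 4, n)])
    qry = "".join(bases[rng.integers(0, 4, m)])
    track = rng.integers(0, 5, n).astype(np.uint8)
    return ref, track, qry


class TestBasics:
    def test_identity_alignment_has_no_edits(self, zebraic_profile):
        track = np.full(4, int(FeatureClass.CDS), np.uint8)
        res = zdp_align("ACGT", track, "ACGT", zebraic_profile)
        assert res.score == 4 * zebraic_profile.match[FeatureClass.CDS]
        assert res.ops == [("M", 4)]

    def test_query_overhang_is_free(self, zebraic_profile):
        track = np.full(4, int(FeatureClass.CDS), np.uint8)
        res = zdp_align("ACGT", track, "TTACGTTT", zebraic_profile)
        assert res.ref_span == (0, 4)
        assert res.query_span == (2, 6)
        assert res.ops == [("M", 4)]

    def test_reference_always_fully_covered(self, rng, zebraic_profile):
        for _ in range(30):
            ref, track, qry = random_pair(rng, 1, 40)
            res = zdp_align(ref, track, qry, zebraic_profile)
            assert res.ref_aligned.replace("-", "") == ref

    def test_gap_count_conservation(self, rng, zebraic_profile):
        for _ in range(30):
            ref, track, qry = random_pair(rng, 5, 60)
            res = zdp_align(ref, track, qry, zebraic_profile)
            assert len(res.ref_aligned) == len(res.query_aligned)
            qs, qe = res.query_span
            assert res.query_aligned.replace("-", "") == qry[qs:qe]
            ins = res.ref_aligned.count("-")
            dels = res.query_aligned.count("-")
            assert len(res.ref_aligned) == len(ref) + ins
            assert len(res.query_aligned) == (qe - qs) + dels

    def test_empty_input_is_contract_error(self, zebraic_profile):
        with pytest.raises(ContractError):
            zdp_align("", np.zeros(0, np.uint8), "ACGT", zebraic_profile)
        with pytest.raises(ContractError):
            zdp_align("ACGT", np.zeros(4, np.uint8), "", zebraic_profile)

    def test_track_length_mismatch_is_contract_error(self, zebraic_profile):
        with pytest.raises(ContractError):
            zdp_align("ACGT", np.zeros(3, np.uint8), "ACGT", zebraic_profile)


class TestOracleEquivalence:
    def test_score_matches_path_enumeration(self, rng):
        for _ in range(60):
            ref, track, qry = random_pair(rng, 1, 8)
            profile = admissible_random_profile(rng)
            got = zdp_align(ref, track, qry, profile).score
            assert got == enumerate_best_score(ref, track, qry, profile)

    def test_traced_alignment_rescored_reaches_dp_score(self, rng):
        # the traced path must itself achieve the reported optimum when the
        # leading free segments are excluded
        for _ in range(40):
            ref, track, qry = random_pair(rng, 1, 8)
            profile = admissible_random_profile(rng)
            res = zdp_align(ref, track, qry, profile)
            # strip leading deletions that the zero-initialised first row
            # makes free (they are emitted for coverage, not scored)
            ra, qa = res.ref_aligned, res.query_aligned
            k = 0
            while k < len(qa) and qa[k] == "-":
                k += 1
            lead = ra[:k].count("-") == 0
            if lead:
                sub_track = track[k:]
                rescored = score_alignment(ra[k:], qa[k:], sub_track, profile)
                assert rescored <= res.score


class TestUniformReduction:
    def test_matches_textbook_gotoh(self, rng):
        profile = ScoringProfile.uniform(3, -2, 5, 2)
        for _ in range(40):
            ref, track, qry = random_pair(rng, 1, 40)
            got = zdp_align(ref, track, qry, profile).score
            exp = gotoh_semiglobal_score(ref, qry, 3, -2, 5, 2)
            assert got == exp


class TestStripedEquivalence:
    def test_bitwise_equal_results(self, rng):
        for _ in range(60):
            ref, track, qry = random_pair(rng, 50, 300)
            profile = admissible_random_profile(rng)
            a = zdp_align(ref, track, qry, profile)
            b = zsdp_align(ref, track, qry, profile)
            assert (a.ref_aligned, a.query_aligned, a.score, a.query_span) == (
                b.ref_aligned, b.query_aligned, b.score, b.query_span
            )

    def test_escalation_beyond_8_bit(self, zebraic_profile):
        # a perfect CDS match of 60 bp scores 360 > 127: must escalate and
        # still match the plain fill
        seq = "ACGT" * 15
        track = np.full(60, int(FeatureClass.CDS), np.uint8)
        a = zdp_align(seq, track, seq, zebraic_profile)
        b = zsdp_align(seq, track, seq, zebraic_profile)
        assert a.score == b.score == 60 * zebraic_profile.match[FeatureClass.CDS]
        assert a.ref_aligned == b.ref_aligned

    def test_ambiguity_codes_align_by_intersection(self, zebraic_profile):
        track = np.full(4, int(FeatureClass.CDS), np.uint8)
        res = zsdp_align("ACGT", track, "ANGT", zebraic_profile)
        assert res.ops == [("M", 4)]
        assert res.score == 4 * zebraic_profile.match[FeatureClass.CDS]


class TestTracebackLabels:
    def test_label_enum_covers_all_composites(self):
        values = {int(v) for v in TracebackLabel}
        assert values == set(range(1, 8))


class TestMonotoneWeighting:
    def test_raising_splice_penalty_never_moves_gap_onto_splice_columns(self, rng):
        from zebralift.fixtures import (
            FixtureSpec,
            generate_genome_with_annotation,
            plant_ambiguous_indel_locus,
        )
        from zebralift.annotation_core import build_feature_track
        from zebralift.pseudogenome import Variant, apply_variants

        spec = FixtureSpec(seed=21, chromosome_length=5000, n_genes=1,
                           exons_per_gene=(2, 3), intron_length=(40, 200),
                           minus_strand_fraction=0.0)
        genome, ann = generate_genome_with_annotation(spec)
        t = next(ann.transcripts())
        genome, t, locus = plant_ambiguous_indel_locus(genome, t, rng)
        s, e = locus.good_span
        anchor = genome[t.chrom][s - 1]
        acc, _ = apply_variants(
            genome[t.chrom],
            [Variant(t.chrom, s - 1, anchor + genome[t.chrom][s:e], anchor)],
        )
        cs, ce = t.cds_span
        track = build_feature_track(t, cs, ce)
        base = ScoringProfile.default_zebraic()
        for splice_open in (40, 80, 160):
            go = list(base.gap_open)
            ge = list(base.gap_ext)
            go[FeatureClass.SPLICE_SITE] = splice_open
            ge[FeatureClass.SPLICE_SITE] = splice_open
            prof = ScoringProfile(base.match, base.mismatch, tuple(go), tuple(ge))
            res = zsdp_align(genome[t.chrom][cs:ce], track, acc[cs : ce + 50], prof)
            r = cs
            for rc, qc in zip(res.ref_aligned, res.query_aligned):
                if rc != "-":
                    if qc == "-":
                        assert not (locus.motif_span[0] <= r < locus.motif_span[1])
                    r += 1
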