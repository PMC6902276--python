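"""End-to-end annotation lift-over pipelines.

Resequencing mode builds the accession's pseudo-genome from a VCF, lifts all
transcripts arithmetically, ORF-checks each lifted model against the
pseudo-genome, and realigns only the broken ones with the feature-weighted
aligner (the ORF check is the trigger: an intact standard lift is kept
untouched). Assembly mode does the same against a de novo assembly, using
coarse range pairs from a whole-genome aligner to place each region before
base-pair-resolution alignment.

Realignment that rescues an ORF also implies the underlying variant records
were mis-placed; :func:`recall_variants` re-derives records from the new
alignment and :func:`replace_region_variants` swaps them into the variant
list without changing the implied pseudo-genome sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation_core import (
    GenomeAnnotation,
    OrfParams,
    OrfState,
    TranscriptModel,
    build_feature_track,
    check_orf_state,
    reverse_complement,
)
from .errors import ContractError, ValidationError
from .formats_io import RangePair
from .pseudogenome import ShiftIndex, Variant, apply_variants, lift_annotation
from .zdp import (
    AlignmentResult,
    ScoringProfile,
    sliding_window_align,
    zsdp_align,
)

__all__ = [
    "LiftMethod",
    "LiftReport",
    "lift_annotation_assembly",
    "lift_annotation_resequencing",
    "realign_transcript",
    "recall_variants",
    "replace_region_variants",
    "integrate_external_models",
]

log = logging.getLogger(__name__)


class LiftMethod:
    STANDARD = "STANDARD"
    ZDP_REALIGNED = "ZDP_REALIGNED"
    ORTHOLOGUE_HOOK = "ORTHOLOGUE_HOOK"
    UNPLACED = "UNPLACED"


@dataclass
class LiftReportEntry:
    transcript_id: str
    method: str
    orf_before: OrfState | None
    orf_after: OrfState | None


@dataclass
class LiftReport:
    entries: dict[str, LiftReportEntry] = field(default_factory=dict)

    def record(self, tid, method, orf_before, orf_after) -> None:
        if method == LiftMethod.ZDP_REALIGNED and (
            orf_before is None or orf_before.intact
        ):
            raise ContractError("realignment is only triggered by a broken ORF")
        self.entries[tid] = LiftReportEntry(tid, method, orf_before, orf_after)

    def by_method(self, method: str) -> list[str]:
        return [t for t, e in self.entries.items() if e.method == method]

    def to_tsv(self) -> str:
        lines = ["transcript_id\tmethod\torf_before\torf_after"]

        def fmt(state: OrfState | None) -> str:
            if state is None:
                return "."
            if state.intact:
                return "intact"
            return "lost:" + ",".join(sorted(state.failed_rules))

        for e in self.entries.values():
            lines.append(
                f"{e.transcript_id}\t{e.method}\t{fmt(e.orf_before)}\t"
                f"{fmt(e.orf_after)}"
            )
        return "\n".join(lines) + "\n"


def _map_boundary(qmap: np.ndarray, s: int, e: int) -> tuple[int, int] | None:
    """Map a half-open ref-window interval through a per-base query map.

    ``qmap[r]`` is the query offset aligned to ref offset ``r`` or -1 on a
    gap; boundaries landing on gaps snap toward the interval interior.
    Returns None if the whole interval is unaligned.
    """
    inside = qmap[s:e]
    hit = inside >= 0
    if not hit.any():
        return None
    first = int(np.argmax(hit))
    last = int(len(inside) - 1 - np.argmax(hit[::-1]))
    return int(inside[first]), int(inside[last]) + 1


def _rederive_model(
    transcript: TranscriptModel,
    window_start: int,
    qmap: np.ndarray,
    query_origin: int,
    query_chrom: str,
) -> TranscriptModel | None:
    """Project a transcript's CDS intervals through an alignment map."""
    new_cds = []
    for s, e in transcript.cds:
        mapped = _map_boundary(qmap, s - window_start, e - window_start)
        if mapped is not None:
            new_cds.append((query_origin + mapped[0], query_origin + mapped[1]))
    if not new_cds:
        return None
    merged = [new_cds[0]]
    for s, e in new_cds[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return TranscriptModel(
        gene_id=transcript.gene_id,
        transcript_id=transcript.transcript_id,
        chrom=query_chrom,
        strand=transcript.strand,
        exons=list(merged),
        cds=list(merged),
    )


def realign_transcript(
    transcript: TranscriptModel,
    ref_genome: Mapping[str, str],
    query_seq: str,
    query_origin: int,
    query_chrom: str,
    profile: ScoringProfile,
    orf_params: OrfParams,
    query_genome: Mapping[str, str] | None = None,
) -> tuple[TranscriptModel | None, OrfState | None, AlignmentResult]:
    """Realign one transcript's CDS region against a query window.

    The reference window runs from the start codon to the stop codon (the
    weighted region); the caller supplies a query window already extended
    around the expected locus. Minus-strand transcripts are aligned on the
    reverse-complemented strand and coordinates mapped back. Returns the
    re-derived model (CDS-only exon structure), its ORF state checked against
    ``query_genome`` (defaults to ``{query_chrom: padded query_seq}``), and
    the alignment. A model that cannot be placed returns ``(None, None,
    alignment)``.
    """
    cs, ce = transcript.cds_span
    ref_window = ref_genome[transcript.chrom][cs:ce]
    track = build_feature_track(transcript, cs, ce)
    if not query_seq:
        raise ContractError("empty query region")
    if transcript.strand == "-":
        aln = zsdp_align(
            reverse_complement(ref_window),
            track[::-1].copy(),
            reverse_complement(query_seq),
            profile,
        )
        qmap_rc = aln.ref_to_query_map()
        qmap = np.full(len(ref_window), -1, dtype=np.int64)
        alive = qmap_rc >= 0
        qmap[::-1][alive] = len(query_seq) - 1 - qmap_rc[alive]
    else:
        aln = zsdp_align(ref_window, track, query_seq, profile)
        qmap = aln.ref_to_query_map()
    model = _rederive_model(transcript, cs, qmap, query_origin, query_chrom)
    if model is None:
        return None, None, aln
    if query_genome is None:
        query_genome = {query_chrom: "N" * query_origin + query_seq}
    state = check_orf_state(model, query_genome, orf_params)
    return model, state, aln


def _realign_window(
    transcript: TranscriptModel, lifted: TranscriptModel, chrom_len: int
) -> tuple[int, int]:
    """Query window: the lifted locus extended by one gene length per side."""
    ls, le = lifted.cds_span
    gene_len = transcript.cds_span[1] - transcript.cds_span[0]
    return max(0, ls - gene_len), min(chrom_len, le + gene_len)


def lift_annotation_resequencing(
    annotation: GenomeAnnotation,
    ref_genome: Mapping[str, str],
    variants: Sequence[Variant],
    profile: ScoringProfile | None = None,
    orf_params: OrfParams = OrfParams(),
) -> tuple[GenomeAnnotation, LiftReport, dict[str, str], dict[str, ShiftIndex]]:
    """Lift an annotation onto the pseudo-genome implied by ``variants``.

    Returns (lifted annotation, report, pseudo-genome, shift indexes).
    Transcripts whose standard lift is ORF-intact are reported STANDARD;
    broken ones are realigned with the zebraic aligner and reported
    ZDP_REALIGNED when the realignment rescues or changes the model.
    """
    profile = profile or ScoringProfile.default_zebraic()
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    pseudo: dict[str, str] = {}
    indexes: dict[str, ShiftIndex] = {}
    for chrom, seq in ref_genome.items():
        pseudo[chrom], indexes[chrom] = apply_variants(
            seq, by_chrom.get(chrom, [])
        )
    lifted = lift_annotation(annotation, indexes)
    lifted_by_id = {t.transcript_id: t for t in lifted.transcripts()}
    report = LiftReport()
    final: list[TranscriptModel] = []
    for t in annotation.transcripts():
        lt = lifted_by_id.get(t.transcript_id)
        if lt is None or not lt.cds:
            report.record(t.transcript_id, LiftMethod.UNPLACED, None, None)
            continue
        state = check_orf_state(lt, pseudo, orf_params)
        if state.intact:
            final.append(lt)
            report.record(t.transcript_id, LiftMethod.STANDARD, state, state)
            continue
        ws, we = _realign_window(t, lt, len(pseudo[t.chrom]))
        model, new_state, _aln = realign_transcript(
            t,
            ref_genome,
            pseudo[t.chrom][ws:we],
            ws,
            t.chrom,
            profile,
            orf_params,
            query_genome=pseudo,
        )
        if model is not None and new_state is not None and new_state.intact:
            final.append(model)
            report.record(
                t.transcript_id, LiftMethod.ZDP_REALIGNED, state, new_state
            )
        else:
            final.append(lt)  # keep the conservative standard-lift model
            report.record(t.transcript_id, LiftMethod.STANDARD, state, state)
    return GenomeAnnotation(final), report, pseudo, indexes


def _check_range_pairs(range_pairs: Sequence[RangePair]) -> None:
    by_chrom: dict[str, list[RangePair]] = {}
    for rp in range_pairs:
        by_chrom.setdefault(rp.ref_chrom, []).append(rp)
    for chrom, rps in by_chrom.items():
        rps.sort(key=lambda r: r.ref_start)
        for a, b in zip(rps, rps[1:]):
            if b.ref_start < a.ref_end:
                raise ValidationError(
                    f"range pairs overlap on {chrom}: "
                    f"[{a.ref_start},{a.ref_end}) and [{b.ref_start},{b.ref_end})"
                )


def _combined_track(
    annotation: GenomeAnnotation, chrom: str, start: int, end: int
) -> np.ndarray:
    """Overlay the feature tracks of every transcript in a window."""
    track = np.zeros(end - start, dtype=np.uint8)
    for t in annotation.on(chrom):
        cs, ce = t.cds_span
        if ce <= start or cs >= end:
            continue
        if cs < start or ce > end:
            continue  # transcripts straddling the window edge are skipped
        sub = build_feature_track(t, cs, ce)
        np.maximum(track[cs - start : ce - start], sub, out=track[cs - start : ce - start])
    return track


def lift_annotation_assembly(
    annotation: GenomeAnnotation,
    ref_genome: Mapping[str, str],
    query_genome: Mapping[str, str],
    range_pairs: Sequence[RangePair],
    profile: ScoringProfile | None = None,
    orf_params: OrfParams = OrfParams(),
    window_size: int = 1000,
) -> tuple[GenomeAnnotation, LiftReport]:
    """Project an annotation onto a de novo assembly via coarse range pairs.

    Each range pair is aligned at base-pair resolution with the sliding
    window method; contained transcripts are lifted through the alignment,
    ORF-checked against the assembly, and realigned when broken. Transcripts
    covered by no range pair are reported UNPLACED.
    """
    profile = profile or ScoringProfile.default_zebraic()
    _check_range_pairs(range_pairs)
    for rp in range_pairs:
        rp.validate_against(ref_genome, query_genome)
    report = LiftReport()
    placed: set[str] = set()
    final: list[TranscriptModel] = []
    for rp in range_pairs:
        ref_slice = ref_genome[rp.ref_chrom][rp.ref_start : rp.ref_end]
        query_slice = query_genome[rp.query_chrom][rp.query_start : rp.query_end]
        if not rp.same_strand:
            query_slice = reverse_complement(query_slice)
        track = _combined_track(
            annotation, rp.ref_chrom, rp.ref_start, rp.ref_end
        )
        aln = sliding_window_align(
            ref_slice, track, query_slice, profile, window_size,
            free_query_ends=False,
        )
        qmap = aln.ref_to_query_map()
        if not rp.same_strand:
            alive = qmap >= 0
            flipped = np.full_like(qmap, -1)
            flipped[alive] = len(query_slice) - 1 - qmap[alive]
            qmap = flipped[:]
        for t in annotation.on(rp.ref_chrom):
            cs, ce = t.cds_span
            if cs < rp.ref_start or ce > rp.ref_end:
                continue
            placed.add(t.transcript_id)
            model = _rederive_model(
                t, rp.ref_start - 0, qmap if rp.same_strand else qmap,
                rp.query_start, rp.query_chrom,
            )
            if model is None:
                report.record(t.transcript_id, LiftMethod.UNPLACED, None, None)
                continue
            state = check_orf_state(model, query_genome, orf_params)
            if state.intact:
                final.append(model)
                report.record(t.transcript_id, LiftMethod.STANDARD, state, state)
                continue
            ws, we = _realign_window(t, model, len(query_genome[rp.query_chrom]))
            new_model, new_state, _ = realign_transcript(
                t,
                ref_genome,
                query_genome[rp.query_chrom][ws:we],
                ws,
                rp.query_chrom,
                profile,
                orf_params,
                query_genome=query_genome,
            )
            if new_model is not None and new_state is not None and new_state.intact:
                final.append(new_model)
                report.record(
                    t.transcript_id, LiftMethod.ZDP_REALIGNED, state, new_state
                )
            else:
                final.append(model)
                report.record(t.transcript_id, LiftMethod.STANDARD, state, state)
    for t in annotation.transcripts():
        if t.transcript_id not in placed:
            report.record(t.transcript_id, LiftMethod.UNPLACED, None, None)
    return GenomeAnnotation(final), report


def recall_variants(
    alignment: AlignmentResult,
    chrom: str,
    ref_origin: int,
    chrom_seq: str | None = None,
) -> list[Variant]:
    """Walk alignment columns and emit SNP/INS/DEL records (ref coordinates).

    Adjacent gap columns of one orientation merge into a single INDEL; INDEL
    records carry a VCF-style left anchor base (the base after the event when
    it occurs at position 0). ``chrom_seq`` supplies anchor bases that lie
    outside the aligned window.
    """
    variants: list[Variant] = []
    ref_pos = ref_origin
    last_ref_base: str | None = None
    if chrom_seq is not None and ref_origin > 0:
        last_ref_base = chrom_seq[ref_origin - 1]

    pending_op = ""
    pending_seq: list[str] = []
    pending_start = 0
    pending_anchor: str | None = None

    def flush() -> None:
        nonlocal pending_op, pending_seq
        if not pending_op:
            return
        seq = "".join(pending_seq)
        if pending_op == "D":
            if pending_anchor is not None:
                variants.append(
                    Variant(chrom, pending_start - 1, pending_anchor + seq,
                            pending_anchor)
                )
            else:  # deletion at the chromosome start: right-anchor
                nxt = _base_after(pending_start + len(seq))
                variants.append(Variant(chrom, pending_start, seq + nxt, nxt))
        else:
            if pending_anchor is not None:
                variants.append(
                    Variant(chrom, pending_start - 1, pending_anchor,
                            pending_anchor + seq)
                )
            else:
                nxt = _base_after(pending_start)
                variants.append(Variant(chrom, pending_start, nxt, seq + nxt))
        pending_op, pending_seq = "", []

    def _base_after(pos: int) -> str:
        if chrom_seq is not None:
            return chrom_seq[pos]
        # fall back to the alignment's own reference characters
        r = ref_origin
        for rc in alignment.ref_aligned:
            if rc != "-":
                if r == pos:
                    return rc
                r += 1
        raise ContractError("INDEL at window edge needs chrom_seq for its anchor")

    for rc, qc in zip(alignment.ref_aligned, alignment.query_aligned):
        if rc != "-" and qc != "-":
            flush()
            if rc.upper() != qc.upper():
                variants.append(Variant(chrom, ref_pos, rc.upper(), qc.upper()))
            last_ref_base = rc.upper()
            ref_pos += 1
        elif qc == "-":  # deletion run
            if pending_op != "D":
                flush()
                pending_op, pending_start = "D", ref_pos
                pending_anchor = last_ref_base
            pending_seq.append(rc.upper())
            last_ref_base = rc.upper()
            ref_pos += 1
        else:  # insertion run
            if pending_op != "I":
                flush()
                pending_op, pending_start = "I", ref_pos
                pending_anchor = last_ref_base
            pending_seq.append(qc.upper())
    flush()
    return variants


def replace_region_variants(
    vcf_variants: Sequence[Variant],
    chrom: str,
    region: tuple[int, int],
    new_variants: Sequence[Variant],
) -> list[Variant]:
    """Replace every record intersecting ``region`` with ``new_variants``.

    Representation surgery only: callers are expected to supply new records
    whose application yields the same pseudo-genome sequence (asserted by the
    pipeline tests, not here).
    """
    rs, re_ = region
    for v in new_variants:
        s, e = v.ref_span
        if v.chrom != chrom or s < rs - 1 or max(e, s + 1) > re_ + 1:
            raise ContractError(
                f"replacement variant {v.chrom}:{v.pos} outside region "
                f"{chrom}:[{rs},{re_})"
            )
    kept = []
    for v in vcf_variants:
        s, e = v.ref_span
        e = max(e, s + 1)
        if v.chrom == chrom and s < re_ and rs < e:
            continue
        kept.append(v)
    return sorted([*kept, *new_variants])


def integrate_external_models(
    annotation: GenomeAnnotation,
    report: LiftReport,
    candidates: Mapping[str, TranscriptModel],
    query_genome: Mapping[str, str],
    orf_params: OrfParams = OrfParams(),
) -> tuple[GenomeAnnotation, LiftReport]:
    """Hook for externally produced gene models (orthologue search etc.).

    Candidates are applied, in the caller's priority order, to transcripts
    whose lifted model is still ORF-broken or unplaced; an adopted candidate
    is reported ORTHOLOGUE_HOOK. No external tool is bundled or invoked.
    """
    models = {t.transcript_id: t for t in annotation.transcripts()}
    for tid, cand in candidates.items():
        entry = report.entries.get(tid)
        if entry is None:
            continue
        broken = entry.method == LiftMethod.UNPLACED or (
            entry.orf_after is not None and not entry.orf_after.intact
        )
        if not broken:
            continue
        state = check_orf_state(cand, query_genome, orf_params)
        if state.intact:
            models[tid] = cand
            report.entries[tid] = LiftReportEntry(
                tid, LiftMethod.ORTHOLOGUE_HOOK, entry.orf_before, state
            )
    return GenomeAnnotation(models.values()), report
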