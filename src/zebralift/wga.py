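"""Gene-anchored whole-genome alignment and base-pair-resolution variant calling.

The lifted annotation of a de novo assembly shares gene IDs with the
reference annotation. Aligning the two per-chromosome gene-ID sequences with
Needleman–Wunsch (identical IDs match) yields colinear anchor genes; their
start/stop-codon coordinates split both genomes into paired fragments that
tile each chromosome. Every fragment is aligned at base-pair resolution with
the sliding-window zebraic DP (intergenic scoring), variants are recalled
from the alignment, and — because every base of both genomes is covered by
exactly one fragment alignment — applying the calls to the reference
reconstructs the assembly byte-exactly. Structural events (relocations)
surface as paired DEL+INS records rather than rearrangement calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation_core import FeatureClass, GenomeAnnotation
from .errors import ContractError, ValidationError
from .liftover import recall_variants
from .pseudogenome import Variant, apply_variants
from .zdp import ScoringProfile, sliding_window_align

__all__ = [
    "AnchorPair",
    "FragmentPair",
    "call_variants",
    "match_gene_orders",
    "reconstruct_query",
    "split_fragments",
]


@dataclass(frozen=True)
class AnchorPair:
    """A gene matched by ID between the two annotations.

    ``ref_pos``/``query_pos`` are the outermost start/stop-codon coordinates
    (the CDS span); the cut point used for fragmentation is the span start.
    """

    gene_id: str
    ref_chrom: str
    ref_pos: tuple[int, int]
    query_chrom: str
    query_pos: tuple[int, int]


@dataclass(frozen=True)
class FragmentPair:
    """Paired inter-anchor intervals (either side may be empty)."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int


def _nw_ids(ref_ids: Sequence[str], query_ids: Sequence[str]):
    """Global alignment of two gene-ID sequences (+1 match, -1 mis/gap).

    Returns the matched (ref_index, query_index) pairs on the optimal path
    (ties broken toward the diagonal, then toward consuming the reference).
    """
    n, m = len(ref_ids), len(query_ids)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    H[:, 0] = -np.arange(n + 1)
    H[0, :] = -np.arange(m + 1)
    for i in range(1, n + 1):
        prev = H[i - 1]
        cur = H[i]
        rid = ref_ids[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (1 if rid == query_ids[j - 1] else -1)
            up = prev[j] - 1
            left = cur[j - 1] - 1
            cur[j] = max(diag, up, left)
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        diag = H[i - 1, j - 1] + (1 if ref_ids[i - 1] == query_ids[j - 1] else -1)
        if H[i, j] == diag:
            if ref_ids[i - 1] == query_ids[j - 1]:
                pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _chrom_pairing(
    ref_annotation: GenomeAnnotation, query_annotation: GenomeAnnotation
) -> list[tuple[str, str]]:
    """Pair chromosomes by shared gene content (majority vote)."""
    gene_chrom_q: dict[str, str] = {}
    for t in query_annotation.transcripts():
        gene_chrom_q.setdefault(t.gene_id, t.chrom)
    votes: dict[tuple[str, str], int] = {}
    for t in ref_annotation.transcripts():
        qc = gene_chrom_q.get(t.gene_id)
        if qc is not None:
            votes[(t.chrom, qc)] = votes.get((t.chrom, qc), 0) + 1
    pairing: dict[str, tuple[str, int]] = {}
    for (rc, qc), count in sorted(votes.items()):
        if rc not in pairing or count > pairing[rc][1]:
            pairing[rc] = (qc, count)
    return [(rc, qc) for rc, (qc, _n) in sorted(pairing.items())]


def match_gene_orders(
    ref_annotation: GenomeAnnotation, query_annotation: GenomeAnnotation
) -> list[AnchorPair]:
    """Match genes by ID with per-chromosome Needleman–Wunsch ordering.

    Matches that break coordinate monotonicity on the query side are
    discarded (longest colinear subset is kept), so the returned anchors are
    strictly increasing along both genomes within each chromosome pairing.
    """
    spans_r = _gene_spans(ref_annotation)
    spans_q = _gene_spans(query_annotation)
    anchors: list[AnchorPair] = []
    for rc, qc in _chrom_pairing(ref_annotation, query_annotation):
        ref_ids = ref_annotation.gene_order(rc)
        query_ids = query_annotation.gene_order(qc)
        matched = [
            (ref_ids[i], query_ids[j]) for i, j in _nw_ids(ref_ids, query_ids)
        ]
        # enforce colinearity of query coordinates (longest increasing subset)
        coords = [spans_q[(g, qc)][0] for g, _ in matched]
        keep = _lis_indexes(coords)
        for k in keep:
            gid = matched[k][0]
            anchors.append(
                AnchorPair(gid, rc, spans_r[(gid, rc)], qc, spans_q[(gid, qc)])
            )
    return anchors


def _gene_spans(annotation: GenomeAnnotation) -> dict[tuple[str, str], tuple[int, int]]:
    spans: dict[tuple[str, str], tuple[int, int]] = {}
    for t in annotation.transcripts():
        key = (t.gene_id, t.chrom)
        cs, ce = t.cds_span
        if key in spans:
            spans[key] = (min(spans[key][0], cs), max(spans[key][1], ce))
        else:
            spans[key] = (cs, ce)
    return spans


def _lis_indexes(values: Sequence[int]) -> list[int]:
    """Indexes of a longest strictly increasing subsequence."""
    if not values:
        return []
    best_len = [1] * len(values)
    parent = [-1] * len(values)
    for i, v in enumerate(values):
        for j in range(i):
            if values[j] < v and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                parent[i] = j
    end = max(range(len(values)), key=lambda k: best_len[k])
    out = []
    while end != -1:
        out.append(end)
        end = parent[end]
    return out[::-1]


def split_fragments(
    anchors: Sequence[AnchorPair],
    ref_chrom: str,
    ref_len: int,
    query_chrom: str,
    query_len: int,
) -> list[FragmentPair]:
    """Cut both chromosomes at anchor span starts into paired fragments.

    The anchor codon spans themselves belong to the following fragment, so
    fragments tile both chromosomes without overlap; zero-length sides encode
    pure insertions or deletions.
    """
    cuts_r = [0]
    cuts_q = [0]
    for a in anchors:
        if a.ref_chrom != ref_chrom or a.query_chrom != query_chrom:
            continue
        if a.ref_pos[0] < cuts_r[-1] or a.query_pos[0] < cuts_q[-1]:
            raise ContractError(f"anchors not colinear at gene {a.gene_id}")
        cuts_r.append(a.ref_pos[0])
        cuts_q.append(a.query_pos[0])
    cuts_r.append(ref_len)
    cuts_q.append(query_len)
    if cuts_r[-2] > ref_len or cuts_q[-2] > query_len:
        raise ContractError("anchor beyond chromosome end")
    return [
        FragmentPair(ref_chrom, rs, re_, query_chrom, qs, qe)
        for (rs, re_), (qs, qe) in zip(
            zip(cuts_r, cuts_r[1:]), zip(cuts_q, cuts_q[1:])
        )
    ]


def call_variants(
    ref_genome: Mapping[str, str],
    query_genome: Mapping[str, str],
    ref_annotation: GenomeAnnotation,
    query_annotation: GenomeAnnotation,
    profile: ScoringProfile | None = None,
    window_size: int = 1000,
) -> list[Variant]:
    """Anchored base-pair-resolution variant calling between two genomes.

    Per paired chromosome: anchor on shared genes, split into fragments,
    align every fragment with the sliding-window DP covering both sides
    completely, and recall variants. The returned records are sorted,
    non-overlapping, and reconstruct the query exactly (see
    :func:`reconstruct_query`).
    """
    profile = profile or ScoringProfile.default_zebraic()
    anchors = match_gene_orders(ref_annotation, query_annotation)
    variants: list[Variant] = []
    chrom_pairs = _chrom_pairing(ref_annotation, query_annotation)
    if not chrom_pairs:  # no shared genes: fall back to name pairing
        chrom_pairs = [
            (c, c) for c in ref_genome if c in query_genome
        ]
    for rc, qc in chrom_pairs:
        ref_seq = ref_genome[rc]
        query_seq = query_genome[qc]
        frags = split_fragments(anchors, rc, len(ref_seq), qc, len(query_seq))
        for fr in frags:
            variants.extend(_call_fragment(fr, ref_seq, query_seq, profile, window_size))
    # stable sort by rewritten span keeps fragment order for same-point events
    variants.sort(key=lambda v: (v.chrom, v.ref_span))
    variants = _merge_boundary_insertions(variants)
    _check_disjoint(variants)
    return variants


def _merge_boundary_insertions(variants: list[Variant]) -> list[Variant]:
    """Concatenate insertions that meet at one point (fragment seams)."""
    out: list[Variant] = []
    for v in variants:
        if out:
            p = out[-1]
            ps, pr, pa = p.core()
            vs, vr, va = v.core()
            if (
                p.chrom == v.chrom
                and not pr
                and not vr
                and ps == vs
            ):
                anchor = p.ref_allele[0]
                out[-1] = Variant(p.chrom, p.pos, p.ref_allele, anchor + pa + va)
                continue
        out.append(v)
    return out


def _call_fragment(
    fr: FragmentPair, ref_seq: str, query_seq: str, profile, window_size
) -> list[Variant]:
    rseq = ref_seq[fr.ref_start : fr.ref_end]
    qseq = query_seq[fr.query_start : fr.query_end]
    if not rseq and not qseq:
        return []
    if rseq == qseq:
        return []
    if not qseq:  # whole-fragment deletion
        anchor_pos = fr.ref_start - 1
        if anchor_pos >= 0:
            anc = ref_seq[anchor_pos]
            return [Variant(fr.ref_chrom, anchor_pos, anc + rseq, anc)]
        nxt = ref_seq[fr.ref_end]
        return [Variant(fr.ref_chrom, fr.ref_start, rseq + nxt, nxt)]
    if not rseq:  # whole-fragment insertion
        anchor_pos = fr.ref_start - 1
        if anchor_pos >= 0:
            anc = ref_seq[anchor_pos]
            return [Variant(fr.ref_chrom, anchor_pos, anc, anc + qseq)]
        nxt = ref_seq[fr.ref_start]
        return [Variant(fr.ref_chrom, fr.ref_start, nxt, qseq + nxt)]
    track = np.full(len(rseq), int(FeatureClass.OTHER), dtype=np.uint8)
    aln = sliding_window_align(
        rseq, track, qseq, profile, window_size, free_query_ends=False
    )
    return recall_variants(aln, fr.ref_chrom, fr.ref_start, chrom_seq=ref_seq)


def _check_disjoint(variants: Sequence[Variant]) -> None:
    prev_end: dict[str, int] = {}
    prev_v: dict[str, Variant] = {}
    for v in variants:
        s, e = v.ref_span
        e = max(e, s)
        if v.chrom in prev_end and s < prev_end[v.chrom]:
            raise ValidationError(
                f"overlapping calls at {v.chrom}:{v.pos} and "
                f"{prev_v[v.chrom].chrom}:{prev_v[v.chrom].pos}"
            )
        prev_end[v.chrom] = e
        prev_v[v.chrom] = v


def reconstruct_query(
    ref_genome: Mapping[str, str], variants: Sequence[Variant]
) -> dict[str, str]:
    """Apply variant calls to the reference, chromosome by chromosome."""
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    out = {}
    for chrom, seq in ref_genome.items():
        pseudo, _idx = apply_variants(seq, by_chrom.get(chrom, []))
        out[chrom] = pseudo
    return out
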