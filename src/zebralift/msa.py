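"""Per-feature multiple-sequence alignment for variant uniformization.

Different alignments of the same population can encode one haplotype as
different variant records (left- vs right-shifted INDELs and nearby SNPs).
To unify records, the reference is partitioned at genetic-feature boundaries
(CDS segment / intron / intergenic block), the corresponding pseudo-genome
interval of every accession is extracted through its shift index, each
element is multiply aligned, and every accession's records are re-derived
from its alignment row against the reference row. Identical element
haplotypes then receive byte-identical records, and applying an accession's
records still reproduces its pseudo-genome exactly.

The MSA core is reference-centred center-star: each accession is pairwise
aligned to the reference element (long elements through the sliding-window
aligner), and the pairwise alignments are merged on reference coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation_core import FeatureClass, GenomeAnnotation
from .errors import ContractError
from .liftover import _combined_track, recall_variants
from .pseudogenome import ShiftIndex, Variant, apply_variants
from .zdp import AlignmentResult, ScoringProfile, sliding_window_align

__all__ = [
    "FeatureElement",
    "FeaturePartition",
    "msa_element",
    "partition_by_feature",
    "uniformize_variants",
]


@dataclass(frozen=True)
class FeatureElement:
    """One partition element: a reference interval of a single feature class."""

    chrom: str
    start: int
    end: int
    feature_class: FeatureClass


@dataclass
class FeaturePartition:
    """Ordered elements tiling the reference, with per-accession intervals."""

    elements: list[FeatureElement]
    accession_intervals: dict[str, dict[FeatureElement, tuple[int, int]]] = field(
        default_factory=dict
    )
    absent: dict[str, set[FeatureElement]] = field(default_factory=dict)


def _element_boundaries(
    annotation: GenomeAnnotation, chrom: str, length: int
) -> list[tuple[int, int, FeatureClass]]:
    points = {0, length}
    cds_ivs: list[tuple[int, int]] = []
    gene_spans: list[tuple[int, int]] = []
    for t in annotation.on(chrom):
        cs, ce = t.cds_span
        gene_spans.append((cs, ce))
        points.update((cs, ce))
        for s, e in t.cds:
            points.update((s, e))
            cds_ivs.append((s, e))
    cuts = sorted(p for p in points if 0 <= p <= length)
    elements = []
    for s, e in zip(cuts, cuts[1:]):
        if s >= e:
            continue
        mid = (s + e) // 2
        if any(a <= mid < b for a, b in cds_ivs):
            cls = FeatureClass.CDS
        elif any(a <= mid < b for a, b in gene_spans):
            cls = FeatureClass.INTRON
        else:
            cls = FeatureClass.OTHER
        elements.append((s, e, cls))
    return elements


def partition_by_feature(
    ref_annotation: GenomeAnnotation,
    ref_lengths: Mapping[str, int],
    accession_shift_indexes: Mapping[str, Mapping[str, ShiftIndex]],
) -> FeaturePartition:
    """Split the reference at feature boundaries; derive accession intervals.

    Elements tile each chromosome; an accession missing a chromosome is
    flagged absent for those elements, and an element whose pseudo-genome
    interval collapsed to zero length (whole-element deletion) is flagged
    absent as well.
    """
    elements: list[FeatureElement] = []
    for chrom, length in ref_lengths.items():
        for s, e, cls in _element_boundaries(ref_annotation, chrom, length):
            elements.append(FeatureElement(chrom, s, e, cls))
    part = FeaturePartition(elements)
    for acc, by_chrom in accession_shift_indexes.items():
        ivs: dict[FeatureElement, tuple[int, int]] = {}
        absent: set[FeatureElement] = set()
        for el in elements:
            idx = by_chrom.get(el.chrom)
            if idx is None:
                absent.add(el)
                continue
            ps = idx.lift_point(el.start)
            pe = idx.lift_point(el.end)
            ivs[el] = (ps, pe)
            if ps >= pe:
                absent.add(el)
        part.accession_intervals[acc] = ivs
        part.absent[acc] = absent
    return part


def _pairwise(center: str, other: str, cls: FeatureClass, profile, window) -> tuple[str, str]:
    track = np.full(len(center), int(cls), dtype=np.uint8)
    aln = sliding_window_align(
        center, track, other, profile, window, free_query_ends=False
    )
    return aln.ref_aligned, aln.query_aligned


def msa_element(
    sequences: Mapping[str, str],
    element_class: FeatureClass,
    profile: ScoringProfile | None = None,
    window_size: int = 1000,
    center_key: str | None = None,
) -> dict[str, str]:
    """Center-star MSA of one element's sequences.

    The center row (``center_key``, default the first key) is aligned
    pairwise against every other row — directly for short elements, through
    the sliding-window aligner beyond ``window_size`` — and the pairwise
    alignments are merged on center coordinates. Returns equal-length rows.
    """
    profile = profile or ScoringProfile.default_zebraic()
    keys = list(sequences)
    if not keys:
        return {}
    if center_key is None:
        center_key = keys[0]
    center = sequences[center_key]
    others = [k for k in keys if k != center_key]
    if all(not sequences[k] for k in keys):
        return {k: "" for k in keys}
    if not center:
        raise ContractError("center sequence of an element must be non-empty")
    pair: dict[str, tuple[str, str]] = {}
    for k in others:
        if sequences[k]:
            pair[k] = _pairwise(center, sequences[k], element_class, profile, window_size)
        else:
            pair[k] = (center, "-" * len(center))
    # merge on center coordinates: take the max insertion length at each point
    ins = np.zeros(len(center) + 1, dtype=np.int64)
    for k in others:
        ca, _qa = pair[k]
        p = 0
        run = 0
        for c in ca:
            if c == "-":
                run += 1
            else:
                ins[p] = max(ins[p], run)
                run = 0
                p += 1
        ins[len(center)] = max(ins[len(center)], run)
    rows = {center_key: _pad_center(center, ins)}
    for k in others:
        rows[k] = _pad_row(*pair[k], ins)
    width = len(rows[center_key])
    assert all(len(r) == width for r in rows.values())
    return rows


def _pad_center(center: str, ins: np.ndarray) -> str:
    out = []
    for p, base in enumerate(center):
        out.append("-" * int(ins[p]))
        out.append(base)
    out.append("-" * int(ins[len(center)]))
    return "".join(out)


def _pad_row(center_aligned: str, row_aligned: str, ins: np.ndarray) -> str:
    """Re-pad one pairwise row onto the merged center coordinates."""
    out = []
    p = 0
    pending: list[str] = []
    for ca, ra in zip(center_aligned, row_aligned):
        if ca == "-":
            pending.append(ra)
        else:
            out.append("-" * (int(ins[p]) - len(pending)))
            out.extend(pending)
            pending = []
            out.append(ra)
            p += 1
    out.append("-" * (int(ins[p]) - len(pending)))
    out.extend(pending)
    return "".join(out)


def _alignment_cuts(
    ref_seq: str,
    pseudo_seq: str,
    boundaries: Sequence[int],
    track: np.ndarray,
    profile: ScoringProfile,
    window_size: int,
) -> dict[int, int]:
    """Map element boundaries onto a pseudo-genome via sequence alignment.

    The pseudo-genome is aligned to the reference (zebraic scoring, full
    coverage of both sides); a boundary ``b`` cuts the pseudo-genome right
    before the column that consumes reference base ``b``, so insertions
    immediately left of a boundary belong to the left element. Because the
    alignment depends only on the sequences, identical pseudo-genomes always
    receive identical cuts regardless of how their variants were written.
    """
    aln = sliding_window_align(
        ref_seq, track, pseudo_seq, profile, window_size, free_query_ends=False
    )
    wanted = sorted(set(boundaries))
    cuts: dict[int, int] = {}
    r = q = 0
    k = 0
    for rc, qc in zip(aln.ref_aligned, aln.query_aligned):
        if rc != "-":
            while k < len(wanted) and wanted[k] == r:
                cuts[wanted[k]] = q
                k += 1
            r += 1
        if qc != "-":
            q += 1
    for b in wanted[k:]:
        cuts[b] = len(pseudo_seq)
    cuts[0] = 0
    if wanted and wanted[-1] == len(ref_seq):
        cuts[len(ref_seq)] = len(pseudo_seq)
    return cuts


def uniformize_variants(
    ref_genome: Mapping[str, str],
    ref_annotation: GenomeAnnotation,
    per_accession_variants: Mapping[str, Sequence[Variant]],
    profile: ScoringProfile | None = None,
    window_size: int = 1000,
) -> dict[str, list[Variant]]:
    """Re-derive every accession's variant records from per-element MSAs.

    Element intervals are cut on a sequence-level alignment of each
    accession's pseudo-genome to the reference (not on the input variant
    arithmetic), so accessions carrying byte-identical haplotypes receive
    byte-identical records; applying an accession's new records reproduces
    its pseudo-genome exactly (representation changes only).
    """
    profile = profile or ScoringProfile.default_zebraic()
    pseudo: dict[str, dict[str, str]] = {}
    indexes: dict[str, dict[str, ShiftIndex]] = {}
    for acc, variants in per_accession_variants.items():
        by_chrom: dict[str, list[Variant]] = {}
        for v in variants:
            by_chrom.setdefault(v.chrom, []).append(v)
        pseudo[acc] = {}
        indexes[acc] = {}
        for chrom, seq in ref_genome.items():
            pseudo[acc][chrom], indexes[acc][chrom] = apply_variants(
                seq, by_chrom.get(chrom, [])
            )
    part = partition_by_feature(
        ref_annotation, {c: len(s) for c, s in ref_genome.items()}, indexes
    )
    bounds_by_chrom: dict[str, list[int]] = {}
    for el in part.elements:
        bounds_by_chrom.setdefault(el.chrom, []).extend((el.start, el.end))
    cuts: dict[tuple[str, str], dict[int, int]] = {}
    for chrom, bounds in bounds_by_chrom.items():
        track = _combined_track(
            ref_annotation, chrom, 0, len(ref_genome[chrom])
        )
        for acc in per_accession_variants:
            if pseudo[acc][chrom] == ref_genome[chrom]:
                cuts[(acc, chrom)] = {b: b for b in set(bounds)}
            else:
                cuts[(acc, chrom)] = _alignment_cuts(
                    ref_genome[chrom], pseudo[acc][chrom], bounds,
                    track, profile, window_size,
                )
    out: dict[str, list[Variant]] = {acc: [] for acc in per_accession_variants}
    for el in part.elements:
        ref_el = ref_genome[el.chrom][el.start : el.end]
        seqs: dict[str, str] = {"__ref__": ref_el}
        for acc in per_accession_variants:
            c = cuts[(acc, el.chrom)]
            seqs[acc] = pseudo[acc][el.chrom][c[el.start] : c[el.end]]
        if all(seqs[a] == ref_el for a in per_accession_variants):
            continue
        rows = msa_element(
            seqs, el.feature_class, profile, window_size, center_key="__ref__"
        )
        for acc in per_accession_variants:
            ra, qa = _strip_mutual_gaps(rows["__ref__"], rows[acc])
            aln = AlignmentResult(ra, qa, 0, (0, el.end - el.start), (0, len(seqs[acc])))
            out[acc].extend(
                recall_variants(
                    aln, el.chrom, el.start, chrom_seq=ref_genome[el.chrom]
                )
            )
    for acc in out:
        out[acc].sort(key=lambda v: (v.chrom, v.ref_span))
        out[acc] = _merge_same_point(out[acc])
    return out


def _strip_mutual_gaps(row_a: str, row_b: str) -> tuple[str, str]:
    pairs = [(a, b) for a, b in zip(row_a, row_b) if not (a == "-" and b == "-")]
    return "".join(p[0] for p in pairs), "".join(p[1] for p in pairs)


def _merge_same_point(variants: list[Variant]) -> list[Variant]:
    out: list[Variant] = []
    for v in variants:
        if out:
            p = out[-1]
            ps, pr, pa = p.core()
            vs, vr, va = v.core()
            if p.chrom == v.chrom and not pr and not vr and ps == vs:
                out[-1] = Variant(
                    p.chrom, p.pos, p.ref_allele, p.ref_allele[0] + pa + va
                )
                continue
        out.append(v)
    return out
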