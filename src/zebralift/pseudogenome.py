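"""Pseudo-genome construction and coordinate lift-over.

A pseudo-genome is the per-accession sequence obtained by substituting ALT
alleles into the reference. Lift-over between reference and pseudo-genome
coordinates is pure arithmetic: each position is shifted by the cumulative
length difference of the variants strictly upstream of it. The
:class:`ShiftIndex` records this as a list of positionally-matched blocks, so
both directions are O(log v) lookups.

Variants follow the VCF left-anchored convention externally (POS is the first
affected base and INDEL alleles share a leading anchor base); the anchor and
any common prefix/suffix are stripped internally before application.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation_core import GenomeAnnotation, TranscriptModel
from .errors import ContractError, ValidationError

__all__ = [
    "Variant",
    "ShiftIndex",
    "Deleted",
    "apply_variants",
    "lift_position",
    "lift_annotation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class Variant:
    """One normalized variant record (VCF-style, 0-based ``pos``)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ContractError("REF and ALT alleles must be non-empty")
        if self.pos < 0:
            raise ContractError(f"negative position {self.pos}")

    @property
    def kind(self) -> str:
        r, a = len(self.ref_allele), len(self.alt_allele)
        if r == a:
            return "SNP" if r == 1 else "MNP"
        return "INS" if a > r else "DEL"

    def core(self) -> tuple[int, str, str]:
        """Strip the common prefix and suffix: (pos, ref_core, alt_core).

        For an insertion ``ref_core`` is empty and ``pos`` is the point the
        new bases precede; for a deletion ``alt_core`` is empty and
        ``[pos, pos+len(ref_core))`` is the deleted span.
        """
        ref, alt, pos = self.ref_allele, self.alt_allele, self.pos
        while ref and alt and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        while ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        return pos, ref, alt

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference span actually rewritten (anchor stripped), half-open."""
        pos, ref, _ = self.core()
        return pos, pos + len(ref)


@dataclass(frozen=True)
class Deleted:
    """Lift result for a position with no image: the span it collapsed to.

    ``left == right`` is the zero-width insertion point in the target
    coordinate system where the deleted sequence used to sit.
    """

    left: int
    right: int


@dataclass
class ShiftIndex:
    """Monotone block map between reference and pseudo-genome coordinates.

    ``blocks`` are ``(ref_start, ref_end, pseudo_start)`` triples of
    positionally-matched sequence; positions outside every block were
    deleted (forward) or inserted (backward).
    """

    ref_length: int
    pseudo_length: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._ref_starts = [b[0] for b in self.blocks]
        self._pseudo_starts = [b[2] for b in self.blocks]

    @classmethod
    def identity(cls, length: int) -> "ShiftIndex":
        return cls(length, length, [(0, length, 0)])

    @property
    def breakpoints(self) -> list[tuple[int, int]]:
        """(reference_position, cumulative_offset_after) pairs."""
        return [(rs, ps - rs) for rs, _re, ps in self.blocks]

    def _locate(self, pos: int, starts, blocks_key) -> tuple[int, int, int] | None:
        k = bisect.bisect_right(starts, pos) - 1
        if k < 0:
            return None
        return self.blocks[k]

    def forward(self, pos: int) -> int | Deleted:
        """Reference position -> pseudo-genome position (or Deleted)."""
        if not 0 <= pos < self.ref_length:
            raise ContractError(f"position {pos} outside [0,{self.ref_length})")
        blk = self._locate(pos, self._ref_starts, 0)
        if blk is not None:
            rs, re, ps = blk
            if pos < re:
                return ps + (pos - rs)
        # deleted: collapse to the start of the next surviving block
        k = bisect.bisect_right(self._ref_starts, pos)
        point = self.blocks[k][2] if k < len(self.blocks) else self.pseudo_length
        return Deleted(point, point)

    def backward(self, pos: int) -> int | Deleted:
        """Pseudo-genome position -> reference position (or Deleted)."""
        if not 0 <= pos < self.pseudo_length:
            raise ContractError(f"position {pos} outside [0,{self.pseudo_length})")
        k = bisect.bisect_right(self._pseudo_starts, pos) - 1
        if k >= 0:
            rs, re, ps = self.blocks[k]
            if pos < ps + (re - rs):
                return rs + (pos - ps)
        k = bisect.bisect_right(self._pseudo_starts, pos)
        point = self.blocks[k][0] if k < len(self.blocks) else self.ref_length
        return Deleted(point, point)

    def lift_point(self, boundary: int) -> int:
        """Map a half-open boundary coordinate (0..ref_length) forward.

        Deleted boundaries collapse to their insertion point, so a sorted set
        of reference boundaries always maps to a sorted set of pseudo-genome
        boundaries that tile the pseudo-genome.
        """
        if boundary == self.ref_length:
            return self.pseudo_length
        hit = self.forward(boundary)
        return hit.left if isinstance(hit, Deleted) else hit


def _sorted_cores(
    variants: Sequence[Variant], chrom_seq: str | None
) -> list[tuple[int, str, str, Variant]]:
    cores = []
    for v in variants:
        pos, ref, alt = v.core()
        if chrom_seq is not None:
            anchored = chrom_seq[v.pos : v.pos + len(v.ref_allele)].upper()
            if anchored != v.ref_allele.upper():
                raise ValidationError(
                    f"REF mismatch at {v.chrom}:{v.pos}: VCF says "
                    f"{v.ref_allele!r}, genome has {anchored!r}"
                )
        cores.append((pos, ref, alt, v))
    cores.sort(key=lambda c: (c[0], len(c[1])))
    for (p1, r1, _a1, v1), (p2, r2, _a2, v2) in zip(cores, cores[1:]):
        if p2 < p1 + len(r1) or (p1 == p2 and not r1 and not r2):
            raise ValidationError(
                f"overlapping variants: {v1.chrom}:{v1.pos} "
                f"{v1.ref_allele}>{v1.alt_allele} collides with "
                f"{v2.chrom}:{v2.pos} {v2.ref_allele}>{v2.alt_allele}"
            )
    return cores


def apply_variants(
    chrom_seq: str,
    variants: Sequence[Variant],
    validate_ref: bool = True,
) -> tuple[str, ShiftIndex]:
    """Substitute ALT alleles into ``chrom_seq`` and build the shift index.

    Variants must lie on one chromosome and be non-overlapping in their
    rewritten reference spans. Substituted spans of equal REF/ALT length stay
    positionally mapped; the length-changing remainder is recorded as
    deleted/inserted sequence.
    """
    cores = _sorted_cores(variants, chrom_seq if validate_ref else None)
    parts: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    ref_cursor = 0
    pseudo_cursor = 0
    for pos, ref, alt, _v in cores:
        if pos > len(chrom_seq) or pos + len(ref) > len(chrom_seq):
            raise ValidationError(f"variant at {pos} outside chromosome")
        # identity block up to the variant
        if pos > ref_cursor:
            parts.append(chrom_seq[ref_cursor:pos])
            blocks.append((ref_cursor, pos, pseudo_cursor))
            pseudo_cursor += pos - ref_cursor
        parts.append(alt)
        matched = min(len(ref), len(alt))
        if matched:  # positional part of a substitution
            blocks.append((pos, pos + matched, pseudo_cursor))
        pseudo_cursor += len(alt)
        ref_cursor = pos + len(ref)
    if ref_cursor < len(chrom_seq):
        parts.append(chrom_seq[ref_cursor:])
        blocks.append((ref_cursor, len(chrom_seq), pseudo_cursor))
        pseudo_cursor += len(chrom_seq) - ref_cursor
    pseudo = "".join(parts)
    assert len(pseudo) == pseudo_cursor
    return pseudo, ShiftIndex(len(chrom_seq), len(pseudo), blocks)


def lift_position(
    pos: int, shift_index: ShiftIndex, direction: str = "forward"
) -> int | Deleted:
    """Lift one position; ``direction`` is ``"forward"`` (ref->pseudo) or
    ``"backward"`` (pseudo->ref)."""
    if direction == "forward":
        return shift_index.forward(pos)
    if direction == "backward":
        return shift_index.backward(pos)
    raise ContractError(f"direction must be forward/backward, got {direction!r}")


def _lift_interval(iv: tuple[int, int], idx: ShiftIndex) -> tuple[int, int, bool]:
    """Lift a half-open interval, snapping deleted endpoints inward.

    Returns (start, end, snapped); start >= end means the interval vanished.
    """
    s, e = iv
    snapped = False
    hs = idx.forward(s)
    if isinstance(hs, Deleted):
        s2, snapped = hs.right, True
    else:
        s2 = hs
    he = idx.forward(e - 1)
    if isinstance(he, Deleted):
        e2, snapped = he.left, True
    else:
        e2 = he + 1
    return s2, e2, snapped


def lift_annotation(
    annotation: GenomeAnnotation,
    shift_indexes: Mapping[str, ShiftIndex],
) -> GenomeAnnotation:
    """Lift every transcript through the per-chromosome shift indexes.

    Boundaries landing inside deleted spans are snapped toward the feature
    interior and the transcript is flagged ``needs_orf_recheck``; fully
    deleted features are dropped (a transcript losing its whole CDS is
    dropped with a warning).
    """
    lifted: list[TranscriptModel] = []
    for t in annotation.transcripts():
        idx = shift_indexes.get(t.chrom)
        if idx is None:
            lifted.append(t.shifted(t.exons, t.cds, needs_orf_recheck=False))
            continue
        snapped_any = False
        new_exons, new_cds = [], []
        for src, dst in ((t.exons, new_exons), (t.cds, new_cds)):
            for iv in src:
                s2, e2, snapped = _lift_interval(iv, idx)
                snapped_any |= snapped
                if s2 < e2:
                    dst.append((s2, e2))
                else:
                    snapped_any = True
        if not new_cds:
            log.warning(
                "transcript %s fully deleted during lift-over; dropped",
                t.transcript_id,
            )
            continue
        lifted.append(
            t.shifted(new_exons or new_cds, new_cds, needs_orf_recheck=snapped_any)
        )
    return GenomeAnnotation(lifted)
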