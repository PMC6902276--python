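"""Gene models, feature-class tracks and the ORF-state checker.

A :class:`TranscriptModel` is the unit of lift-over: an exon/CDS structure on
one strand of one chromosome. The per-base :class:`FeatureClass` track drives
the feature-weighted alignment (different scores for CDS, splice sites,
start/stop codons and introns), and :func:`check_orf_state` applies seven
integrity rules to decide whether a (possibly lifted) transcript still encodes
an intact open reading frame.

All coordinates in this module are 0-based half-open genomic coordinates;
conversion to/from the 1-based formats happens in :mod:`zebralift.formats_io`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import ContractError

__all__ = [
    "FeatureClass",
    "FeatureClassTrack",
    "GenomeAnnotation",
    "OrfParams",
    "OrfRule",
    "OrfState",
    "SpliceMotifSet",
    "TranscriptModel",
    "DEFAULT_SPLICE_MOTIFS",
    "build_feature_track",
    "check_orf_state",
    "extract_cds_sequence",
    "reverse_complement",
    "iupac_intersects",
]

# IUPAC nucleotide codes as base sets. Comparisons between ambiguous codes use
# set intersection; see check_orf_state for the per-rule semantics.
IUPAC: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN-acgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBN-tgcaayrswmkvhdbn",
)

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_intersects(a: str, b: str) -> bool:
    """True if two same-length IUPAC strings can denote the same sequence.

    Position-wise base-set intersection: ``"TRA"`` intersects ``"TAA"``,
    ``"NNN"`` intersects anything of length 3.
    """
    if len(a) != len(b):
        return False
    try:
        return all(IUPAC[x] & IUPAC[y] for x, y in zip(a, b))
    except KeyError as exc:  # non-nucleotide letter
        raise ContractError(f"not an IUPAC nucleotide code: {exc}") from exc


def _resolutions(codon: str) -> Iterator[str]:
    sets = [sorted(IUPAC[c]) for c in codon]
    for combo in itertools.product(*sets):
        yield "".join(combo)


def codon_must_be_stop(codon: str) -> bool:
    """Every IUPAC resolution of ``codon`` is a stop codon."""
    return all(r in STOP_CODONS for r in _resolutions(codon))


def codon_may_be(codon: str, targets: Sequence[str]) -> bool:
    return any(iupac_intersects(codon, t) for t in targets)


class FeatureClass(IntEnum):
    """Reference feature classes, ordered by labelling precedence.

    When a base is claimed by multiple features the highest class wins:
    START_STOP_CODON > SPLICE_SITE > CDS > INTRON > OTHER.
    """

    OTHER = 0
    INTRON = 1
    CDS = 2
    SPLICE_SITE = 3
    START_STOP_CODON = 4


@dataclass(frozen=True)
class SpliceMotifSet:
    """Donor/acceptor dinucleotide motif pairs (transcription orientation)."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ContractError("splice motif set must be non-empty")
        seen = set()
        for donor, acceptor in self.pairs:
            for motif in (donor, acceptor):
                if len(motif) != 2 or any(c not in IUPAC for c in motif):
                    raise ContractError(
                        f"splice motif must be a 2-letter IUPAC string: {motif!r}"
                    )
            if (donor, acceptor) in seen:
                raise ContractError(f"duplicate splice motif pair {donor}-{acceptor}")
            seen.add((donor, acceptor))

    def matches(self, donor: str, acceptor: str) -> bool:
        """Intersection semantics: ambiguity codes may satisfy a motif."""
        return any(
            iupac_intersects(donor, d) and iupac_intersects(acceptor, a)
            for d, a in self.pairs
        )


#: Canonical eukaryotic splice motifs, used when no motif file is supplied.
DEFAULT_SPLICE_MOTIFS = SpliceMotifSet((("GT", "AG"), ("GC", "AG"), ("AT", "AC")))


@dataclass(frozen=True)
class OrfParams:
    min_intron_length: int = 5
    min_cds_length: int = 9
    splice_motifs: SpliceMotifSet = DEFAULT_SPLICE_MOTIFS

    def __post_init__(self) -> None:
        if self.min_intron_length <= 0 or self.min_cds_length <= 0:
            raise ContractError("ORF length thresholds must be positive")


class OrfRule:
    """Names for the seven ORF integrity rules."""

    SPLICE_MOTIF = "SPLICE_MOTIF"
    MIN_INTRON = "MIN_INTRON"
    MIN_CDS_LEN = "MIN_CDS_LEN"
    FRAME = "FRAME"
    PREMATURE_STOP = "PREMATURE_STOP"
    NO_END_STOP = "NO_END_STOP"
    NO_START = "NO_START"

    ALL = (
        SPLICE_MOTIF,
        MIN_INTRON,
        MIN_CDS_LEN,
        FRAME,
        PREMATURE_STOP,
        NO_END_STOP,
        NO_START,
    )


@dataclass(frozen=True)
class OrfState:
    failed_rules: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.failed_rules - set(OrfRule.ALL)
        if unknown:
            raise ContractError(f"unknown ORF rules: {sorted(unknown)}")

    @property
    def intact(self) -> bool:
        return not self.failed_rules


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` and ``cds`` are sorted, non-overlapping 0-based half-open
    intervals in genomic orientation; ``strand`` is ``'+'`` or ``'-'``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    needs_orf_recheck: bool = False
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ContractError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(iv) for iv in self.exons)
        self.cds = sorted(tuple(iv) for iv in self.cds)
        for name, ivs in (("exon", self.exons), ("cds", self.cds)):
            prev_end = None
            for s, e in ivs:
                if s >= e:
                    raise ContractError(f"{name} interval empty: {(s, e)}")
                if prev_end is not None and s < prev_end:
                    raise ContractError(f"{name} intervals overlap at {s}")
                prev_end = e
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ContractError(
                    f"CDS interval {(s, e)} not contained in any exon "
                    f"of {self.transcript_id}"
                )

    @property
    def cds_span(self) -> tuple[int, int]:
        if not self.cds:
            raise ContractError(f"{self.transcript_id} has no CDS")
        return self.cds[0][0], self.cds[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        ivs = self.exons or self.cds
        return ivs[0][0], ivs[-1][1]

    def cds_internal_introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive CDS intervals (the coding introns)."""
        return [
            (self.cds[k][1], self.cds[k + 1][0]) for k in range(len(self.cds) - 1)
        ]

    def shifted(self, exons, cds, **kw) -> "TranscriptModel":
        return replace(self, exons=list(exons), cds=list(cds), **kw)


class GenomeAnnotation:
    """Transcripts grouped by chromosome, ordered by start coordinate."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()):
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda t: (t.span[0], t.span[1], t.transcript_id))

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def on(self, chrom: str) -> list[TranscriptModel]:
        return self._by_chrom.get(chrom, [])

    def transcripts(self) -> Iterator[TranscriptModel]:
        for chrom in self.chromosomes:
            yield from self._by_chrom[chrom]

    def gene_order(self, chrom: str) -> list[str]:
        """Gene IDs in coordinate order (first transcript per gene)."""
        seen, order = set(), []
        for t in self.on(chrom):
            if t.gene_id not in seen:
                seen.add(t.gene_id)
                order.append(t.gene_id)
        return order

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self._by_chrom == other._by_chrom


FeatureClassTrack = np.ndarray  # uint8 array of FeatureClass values


def _coding_positions(transcript: TranscriptModel) -> list[int]:
    """Genomic positions of coding bases, in transcription order."""
    pos = [p for s, e in transcript.cds for p in range(s, e)]
    return pos[::-1] if transcript.strand == "-" else pos


def build_feature_track(
    transcript: TranscriptModel, window_start: int, window_end: int
) -> FeatureClassTrack:
    """Label every base of ``[window_start, window_end)`` with a FeatureClass.

    CDS bases are CDS, the first/last three coding bases (start and stop
    codons) are START_STOP_CODON, the two intronic bases flanking every
    CDS-internal intron boundary are SPLICE_SITE, remaining intra-span bases
    are INTRON, everything outside the transcript span is OTHER. Labels are
    genomic-orientation; precedence resolves multiple claims.
    """
    cs, ce = transcript.cds_span
    if window_start > cs or window_end < ce:
        raise ContractError(
            f"window [{window_start},{window_end}) does not cover "
            f"CDS span [{cs},{ce}) of {transcript.transcript_id}"
        )
    n = window_end - window_start
    track = np.zeros(n, dtype=np.uint8)

    def paint(s: int, e: int, cls: FeatureClass) -> None:
        s = max(s, window_start) - window_start
        e = min(e, window_end) - window_start
        if s < e:
            np.maximum(track[s:e], np.uint8(cls), out=track[s:e])

    paint(cs, ce, FeatureClass.INTRON)  # intra-span background
    for s, e in transcript.cds:
        paint(s, e, FeatureClass.CDS)
    for a, b in transcript.cds_internal_introns():
        paint(a, min(a + 2, b), FeatureClass.SPLICE_SITE)
        paint(max(b - 2, a), b, FeatureClass.SPLICE_SITE)
    coding = _coding_positions(transcript)
    for p in coding[:3] + coding[-3:]:
        paint(p, p + 1, FeatureClass.START_STOP_CODON)
    return track


def extract_cds_sequence(
    transcript: TranscriptModel, genome: Mapping[str, str]
) -> str:
    """Concatenated CDS in transcription order (reverse-complemented on '-')."""
    if not transcript.cds:
        raise ContractError(f"{transcript.transcript_id} has no CDS")
    try:
        chrom_seq = genome[transcript.chrom]
    except KeyError:
        raise ContractError(f"chromosome {transcript.chrom!r} absent from genome")
    for s, e in transcript.cds:
        if s < 0 or e > len(chrom_seq):
            raise ContractError(
                f"CDS interval {(s, e)} outside chromosome "
                f"{transcript.chrom} (length {len(chrom_seq)})"
            )
    seq = "".join(chrom_seq[s:e] for s, e in transcript.cds)
    return reverse_complement(seq) if transcript.strand == "-" else seq


def check_orf_state(
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    params: OrfParams = OrfParams(),
) -> OrfState:
    """Apply the seven ORF integrity rules; report every failure.

    1. every CDS-internal intron's terminal dinucleotides match a splice
       motif pair (donor/acceptor, transcription orientation);
    2. every CDS-internal intron is longer than ``min_intron_length``;
    3. the CDS is longer than ``min_cds_length``;
    4. the CDS length is divisible by 3;
    5. no premature stop codon (a codon counts as a stop only if *every*
       IUPAC resolution is a stop, so ``NNN`` never fails this rule);
    6. the last codon can be a stop (intersection semantics);
    7. the first codon can be ATG (intersection semantics).

    Rules 6/7 and the motif rule use permissive intersection semantics so
    ambiguity codes do not produce false loss-of-function calls; rule 5 uses
    must-be-a-stop semantics for the same reason.
    """
    cds_seq = extract_cds_sequence(transcript, genome).upper()
    chrom_seq = genome[transcript.chrom]
    failed: set[str] = set()

    introns = transcript.cds_internal_introns()
    if transcript.strand == "-":
        introns = introns[::-1]
    for s, e in introns:
        intron_seq = chrom_seq[s:e].upper()
        if transcript.strand == "-":
            intron_seq = reverse_complement(intron_seq)
        if e - s <= params.min_intron_length:
            failed.add(OrfRule.MIN_INTRON)
        if len(intron_seq) < 4 or not params.splice_motifs.matches(
            intron_seq[:2], intron_seq[-2:]
        ):
            failed.add(OrfRule.SPLICE_MOTIF)

    if len(cds_seq) <= params.min_cds_length:
        failed.add(OrfRule.MIN_CDS_LEN)
    if len(cds_seq) % 3 != 0:
        failed.add(OrfRule.FRAME)

    codons = [cds_seq[k : k + 3] for k in range(0, len(cds_seq) - 2, 3)]
    if codons:
        if any(codon_must_be_stop(c) for c in codons[:-1]):
            failed.add(OrfRule.PREMATURE_STOP)
        if not codon_may_be(codons[-1], STOP_CODONS):
            failed.add(OrfRule.NO_END_STOP)
        if not codon_may_be(codons[0], [START_CODON]):
            failed.add(OrfRule.NO_START)
    else:
        failed.update({OrfRule.NO_END_STOP, OrfRule.NO_START})
    return OrfState(frozenset(failed))
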