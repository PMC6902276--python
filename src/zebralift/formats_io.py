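"""Readers and writers for the external formats the tool touches.

FASTA goes through Bio.SeqIO, GFF3 reading through gffutils, VCF reading
through pysam; the GFF3/VCF writers emit the minimal record subset this
package round-trips (8-column VCF without genotypes, gene/mRNA/exon/CDS GFF3
lines). External formats are 1-based inclusive; everything returned by this
module is converted to the package-internal 0-based half-open convention at
the boundary, and converted back on write.

Two small interchange formats are this package's own: the splice-motif file
(two whitespace-separated dinucleotides per line) and the coarse-alignment
range-pair file (7 columns: ref_chrom ref_start ref_end query_chrom
query_start query_end strand).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO

from .annotation_core import GenomeAnnotation, SpliceMotifSet, TranscriptModel
from .errors import ContractError, FormatError, ValidationError
from .pseudogenome import ShiftIndex, Variant

__all__ = [
    "RangePair",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_vcf",
    "write_vcf",
    "read_splice_motifs",
    "read_range_pairs",
    "write_range_pairs",
    "write_shift_index",
]


@dataclass(frozen=True)
class RangePair:
    """A coarse whole-genome-alignment range match (0-based half-open)."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    same_strand: bool = True

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end or self.query_start >= self.query_end:
            raise ContractError(f"empty range in {self}")
        if min(self.ref_start, self.query_start) < 0:
            raise ContractError(f"negative coordinate in {self}")

    def validate_against(
        self, ref_genome: Mapping[str, str], query_genome: Mapping[str, str]
    ) -> None:
        for chrom, end, genome, side in (
            (self.ref_chrom, self.ref_end, ref_genome, "reference"),
            (self.query_chrom, self.query_end, query_genome, "query"),
        ):
            if chrom not in genome:
                raise ValidationError(f"{side} chromosome {chrom!r} unknown")
            if end > len(genome[chrom]):
                raise ValidationError(
                    f"range end {end} beyond {side} {chrom} "
                    f"(length {len(genome[chrom])})"
                )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {id: uppercased sequence}."""
    records = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise FormatError(f"duplicate FASTA id {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    except (ValueError, UnicodeDecodeError) as exc:
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def _gff_db(path) -> gffutils.FeatureDB:
    try:
        return gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise FormatError(f"malformed GFF3 {path}: {exc}") from exc


def read_gff3(path) -> GenomeAnnotation:
    """Parse gene/mRNA/exon/CDS features into TranscriptModels.

    Features are linked by ID/Parent; an exon or CDS whose Parent mRNA is
    missing, or an mRNA whose Parent gene is missing, is a format error
    naming the offending ID.
    """
    if os.path.getsize(path) == 0:
        raise FormatError(f"empty GFF3 file {path}")
    db = _gff_db(path)
    mrnas: dict[str, gffutils.Feature] = {}
    gene_ids: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype == "gene":
            gene_ids.add(feat.id)
        elif feat.featuretype in ("mRNA", "transcript"):
            mrnas[feat.id] = feat
    transcripts = []
    for tid, mrna in mrnas.items():
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else tid
        if parents and parents[0] not in gene_ids:
            raise FormatError(f"mRNA {tid!r} references unknown gene {parents[0]!r}")
        exons, cds = [], []
        for child in db.children(tid, level=1):
            iv = (child.start - 1, child.end)  # to 0-based half-open
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
        if not exons:
            exons = list(cds)
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tid,
                chrom=mrna.seqid,
                strand=mrna.strand if mrna.strand in "+-" else "+",
                exons=exons,
                cds=cds,
            )
        )
    # orphan exon/CDS: children of a Parent that is neither mRNA nor gene
    known = set(mrnas) | gene_ids
    for feat in db.all_features():
        if feat.featuretype in ("exon", "CDS"):
            for parent in feat.attributes.get("Parent", ["<missing>"]):
                if parent not in known:
                    raise FormatError(
                        f"{feat.featuretype} at {feat.seqid}:{feat.start} "
                        f"references unknown Parent {parent!r}"
                    )
    if not transcripts:
        raise FormatError(f"no transcripts in GFF3 {path}")
    return GenomeAnnotation(transcripts)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Emit gene/mRNA/exon/CDS lines (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annotation.chromosomes:
            by_gene: dict[str, list[TranscriptModel]] = {}
            for t in annotation.on(chrom):
                by_gene.setdefault(t.gene_id, []).append(t)
            for gene_id, ts in by_gene.items():
                gs = min(t.span[0] for t in ts) + 1
                ge = max(t.span[1] for t in ts)
                strand = ts[0].strand
                fh.write(
                    f"{chrom}\t.\tgene\t{gs}\t{ge}\t.\t{strand}\t.\t"
                    f"ID={gene_id}\n"
                )
                for t in ts:
                    ts1, te1 = t.span[0] + 1, t.span[1]
                    attrs = f"ID={t.transcript_id};Parent={gene_id}"
                    for k, v in t.attributes.items():
                        attrs += f";{k}={v}"
                    fh.write(
                        f"{chrom}\t.\tmRNA\t{ts1}\t{te1}\t.\t{t.strand}\t.\t"
                        f"{attrs}\n"
                    )
                    for s, e in t.exons:
                        fh.write(
                            f"{chrom}\t.\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                            f"Parent={t.transcript_id}\n"
                        )
                    phase = 0
                    cds = t.cds if t.strand == "+" else t.cds[::-1]
                    for s, e in cds:
                        fh.write(
                            f"{chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t"
                            f"{phase}\tParent={t.transcript_id}\n"
                        )
                        phase = (3 - ((e - s) - phase) % 3) % 3


def read_vcf(path, genome: Mapping[str, str] | None = None) -> list[Variant]:
    """Read VCF records as Variants; multi-allelic records are split.

    When ``genome`` is given, REF alleles are validated against it.
    """
    if os.path.getsize(path) == 0:
        raise FormatError(f"empty VCF file {path}")
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"malformed VCF {path}: {exc}") from exc
    variants: list[Variant] = []
    with vf:
        for rec in vf:
            if rec.ref is None or not rec.alts:
                continue
            for alt in rec.alts:
                if any(c not in "ACGTNacgtn" for c in alt):
                    continue  # symbolic/breakend alleles are out of scope
                variants.append(
                    Variant(rec.chrom, rec.pos - 1, rec.ref.upper(), alt.upper())
                )
    if genome is not None:
        for v in variants:
            if v.chrom not in genome:
                raise ValidationError(f"VCF chromosome {v.chrom!r} not in genome")
            have = genome[v.chrom][v.pos : v.pos + len(v.ref_allele)].upper()
            if have != v.ref_allele:
                raise ValidationError(
                    f"REF mismatch at {v.chrom}:{v.pos + 1}: VCF says "
                    f"{v.ref_allele!r}, genome has {have!r}"
                )
    return sorted(variants)


def write_vcf(
    variants: Sequence[Variant],
    path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write minimal 8-column VCF 4.2 records (no genotype columns)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants):
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t.\n"
            )


def read_splice_motifs(path) -> SpliceMotifSet:
    """Parse the splice-motif file: one donor/acceptor pair per line."""
    pairs = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path} line {ln}: expected 'DONOR ACCEPTOR', got {raw!r}"
                )
            pairs.append((fields[0].upper(), fields[1].upper()))
    if not pairs:
        raise FormatError(f"no splice motifs in {path}")
    try:
        return SpliceMotifSet(tuple(pairs))
    except ContractError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_range_pairs(path) -> list[RangePair]:
    """Parse the 7-column range-pair file (1-based inclusive on disk)."""
    pairs = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7 or fields[6] not in "+-":
                raise FormatError(
                    f"{path} line {ln}: expected 7 columns ending in +/-"
                )
            try:
                rs, re_, qs, qe = (
                    int(fields[1]),
                    int(fields[2]),
                    int(fields[4]),
                    int(fields[5]),
                )
            except ValueError as exc:
                raise FormatError(f"{path} line {ln}: non-integer bound") from exc
            pairs.append(
                RangePair(
                    fields[0], rs - 1, re_, fields[3], qs - 1, qe, fields[6] == "+"
                )
            )
    if not pairs:
        raise FormatError(f"no range pairs in {path}")
    return pairs


def write_range_pairs(pairs: Iterable[RangePair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.ref_chrom}\t{p.ref_start + 1}\t{p.ref_end}\t"
                f"{p.query_chrom}\t{p.query_start + 1}\t{p.query_end}\t"
                f"{'+' if p.same_strand else '-'}\n"
            )


def write_shift_index(
    indexes: Mapping[str, ShiftIndex], path
) -> None:
    """Tab-delimited sidecar: chrom, reference breakpoint, cumulative offset."""
    with open(path, "w") as fh:
        fh.write("#chrom\tref_breakpoint\tcumulative_offset\n")
        for chrom, idx in indexes.items():
            for ref_pos, offset in idx.breakpoints:
                fh.write(f"{chrom}\t{ref_pos}\t{offset}\n")
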