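"""Seeded synthetic genomes, annotations and variant sets.

Everything the test-bench needs is generated here: random genomes carrying
ORF-intact multi-exon gene models, planted SNP/INDEL sets with ground truth,
relocated segments, and the adversarial "ambiguous INDEL" loci in which a
deletion has several equal-cost placements under uniform scoring — only the
intron-interior one keeps the splice-site columns aligned. All operations
are deterministic under a single explicitly threaded
:class:`numpy.random.Generator`.

The generated models emulate compact plant-like genes (multi-exon CDS with
GT..AG introns of 20–200 bp, exons of 30–120 codons, ~0.5 GC background).
They carry no UTRs, repeats, paralogy or realistic population structure —
passing tests demonstrate algorithmic correctness on clean gene structures,
not performance on real assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_core import (
    GenomeAnnotation,
    OrfParams,
    TranscriptModel,
    check_orf_state,
    reverse_complement,
)
from .errors import ContractError
from .pseudogenome import Variant, apply_variants

__all__ = [
    "AmbiguousLocus",
    "FixtureSpec",
    "generate_genome_with_annotation",
    "plant_ambiguous_indel_locus",
    "plant_relocation",
    "plant_variants",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic genome."""

    seed: int
    n_chromosomes: int = 1
    chromosome_length: int = 10_000
    n_genes: int = 5
    exons_per_gene: tuple[int, int] = (1, 4)
    intron_length: tuple[int, int] = (20, 200)
    codons_per_exon: tuple[int, int] = (30, 120)
    n_snps: int = 0
    n_insertions: int = 0
    n_deletions: int = 0
    indel_length: tuple[int, int] = (1, 10)
    n_ambiguous_loci: int = 0
    minus_strand_fraction: float = 0.5

    def __post_init__(self) -> None:
        counts = (
            self.n_chromosomes,
            self.chromosome_length,
            self.n_genes,
            self.n_snps,
            self.n_insertions,
            self.n_deletions,
            self.n_ambiguous_loci,
        )
        if any(c < 0 for c in counts):
            raise ContractError("fixture counts must be non-negative")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_gene(
    rng: np.random.Generator, spec: FixtureSpec
) -> tuple[str, list[tuple[int, int]]]:
    """One gene sequence plus CDS intervals relative to the gene start."""
    n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
    exon_codons = [
        int(rng.integers(spec.codons_per_exon[0], spec.codons_per_exon[1] + 1))
        for _ in range(n_exons)
    ]
    codons = ["ATG"]
    for _ in range(sum(exon_codons) - 2):
        codons.append(_CODONS[int(rng.integers(0, len(_CODONS)))])
    codons.append(("TAA", "TAG", "TGA")[int(rng.integers(0, 3))])
    cds_seq = "".join(codons)
    # split coding bases across exons at codon-scale boundaries
    exon_lens = [3 * c for c in exon_codons]
    parts = []
    off = 0
    for el in exon_lens:
        parts.append(cds_seq[off : off + el])
        off += el
    pieces = [parts[0]]
    cds: list[tuple[int, int]] = [(0, exon_lens[0])]
    cursor = exon_lens[0]
    for part in parts[1:]:
        ilen = int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1))
        intron = "GT" + _random_seq(rng, ilen - 4) + "AG"
        pieces.append(intron)
        cursor += ilen
        cds.append((cursor, cursor + len(part)))
        pieces.append(part)
        cursor += len(part)
    return "".join(pieces), cds


def generate_genome_with_annotation(
    spec: FixtureSpec,
    orf_params: OrfParams = OrfParams(),
) -> tuple[dict[str, str], GenomeAnnotation]:
    """Deterministically generate a genome whose genes are all ORF-intact."""
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    genes_per_chrom = [
        spec.n_genes // spec.n_chromosomes
        + (1 if k < spec.n_genes % spec.n_chromosomes else 0)
        for k in range(spec.n_chromosomes)
    ]
    gene_no = 0
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = list(_random_seq(rng, spec.chromosome_length))
        n_here = genes_per_chrom[ci]
        genes = []
        for _ in range(n_here):
            genes.append(_random_gene(rng, spec))
        total = sum(len(g[0]) for g in genes)
        margin = spec.chromosome_length - total
        if margin < (n_here + 1) * 10:
            raise ContractError(
                f"chromosome of {spec.chromosome_length} bp cannot hold "
                f"{n_here} genes totalling {total} bp"
            )
        gap_unit = margin // (n_here + 1)
        cursor = gap_unit
        for gseq, gcds in genes:
            gene_no += 1
            strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
            if strand == "-":
                placed_seq = reverse_complement(gseq)
                glen = len(gseq)
                placed_cds = sorted(
                    (cursor + glen - e, cursor + glen - s) for s, e in gcds
                )
            else:
                placed_seq = gseq
                placed_cds = [(cursor + s, cursor + e) for s, e in gcds]
            seq[cursor : cursor + len(gseq)] = placed_seq
            transcripts.append(
                TranscriptModel(
                    gene_id=f"g{gene_no:04d}",
                    transcript_id=f"g{gene_no:04d}.1",
                    chrom=chrom,
                    strand=strand,
                    exons=list(placed_cds),
                    cds=list(placed_cds),
                )
            )
            cursor += len(gseq) + gap_unit
        genome[chrom] = "".join(seq)
    annotation = GenomeAnnotation(transcripts)
    for t in annotation.transcripts():
        state = check_orf_state(t, genome, orf_params)
        assert state.intact, (t.transcript_id, state.failed_rules)
    return genome, annotation


def plant_variants(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[Variant]]:
    """Plant the requested SNP/INS/DEL counts; return mutated genome + truth.

    Events are spaced so no two rewritten spans (or their anchor bases)
    touch; the mutated genome is produced by applying the truth set, so the
    truth is consistent by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    chroms = sorted(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    total = spec.n_snps + spec.n_insertions + spec.n_deletions
    if total == 0:
        return dict(genome), []
    max_dl = spec.indel_length[1]
    slot = max_dl + 4
    truth: list[Variant] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place(span_len: int, tries: int = 200) -> tuple[str, int]:
        for _ in range(tries):
            c = chroms[int(rng.integers(0, len(chroms)))]
            if lengths[c] < span_len + 4:
                continue
            p = int(rng.integers(2, lengths[c] - span_len - 2))
            if all(
                p + span_len + slot <= s or e + slot <= p for s, e in occupied[c]
            ):
                occupied[c].append((p, p + span_len))
                return c, p
        raise ContractError("variant density too high to avoid overlaps")

    for _ in range(spec.n_snps):
        c, p = place(1)
        ref = genome[c][p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        truth.append(Variant(c, p, ref, alt))
    for _ in range(spec.n_insertions):
        ln = int(rng.integers(spec.indel_length[0], max_dl + 1))
        c, p = place(1)
        anchor = genome[c][p]
        truth.append(Variant(c, p, anchor, anchor + _random_seq(rng, ln)))
    for _ in range(spec.n_deletions):
        ln = int(rng.integers(spec.indel_length[0], max_dl + 1))
        c, p = place(ln + 1)
        anchor = genome[c][p]
        truth.append(Variant(c, p, anchor + genome[c][p + 1 : p + 1 + ln], anchor))
    truth.sort()
    mutated = {}
    by_chrom: dict[str, list[Variant]] = {c: [] for c in chroms}
    for v in truth:
        by_chrom[v.chrom].append(v)
    for c in chroms:
        mutated[c], _ = apply_variants(genome[c], by_chrom[c])
    return mutated, truth


def plant_relocation(
    genome: dict[str, str],
    chrom: str,
    src: tuple[int, int],
    dest: int,
    ) -> dict[str, str]:
    """Move ``[src_start, src_end)`` of ``chrom`` to point ``dest``.

    ``dest`` is a position in the post-excision coordinate system and must
    not fall inside the excised span. Used to test structural-variation
    decomposition into DEL+INS records.
    """
    s, e = src
    seq = genome[chrom]
    if not (0 <= s < e <= len(seq)):
        raise ContractError(f"bad relocation span {src}")
    segment = seq[s:e]
    remaining = seq[:s] + seq[e:]
    if not 0 <= dest <= len(remaining):
        raise ContractError("relocation destination out of range")
    out = dict(genome)
    out[chrom] = remaining[:dest] + segment + remaining[dest:]
    return out


@dataclass(frozen=True)
class AmbiguousLocus:
    """Descriptor of one engineered ambiguous-deletion locus."""

    chrom: str
    transcript_id: str
    exon_start: int          # genomic start of the downstream exon
    repeat_length: int       # period of the engineered tandem repeat
    good_span: tuple[int, int]   # intronic placement (splice motif preserved)
    bad_span: tuple[int, int]    # placement crossing the acceptor motif
    motif_span: tuple[int, int]  # the acceptor AG positions


def plant_ambiguous_indel_locus(
    genome: dict[str, str],
    transcript: TranscriptModel,
    rng: np.random.Generator,
    deletion_length: int = 14,
) -> tuple[dict[str, str], TranscriptModel, AmbiguousLocus]:
    """Engineer a tandem repeat straddling an intron/exon boundary.

    A unit of period ``deletion_length // 2`` ending in the AG acceptor is
    written three times into the intron tail (the genuine acceptor is the
    last unit's AG) and twice into the exon head. Deleting two units
    (``deletion_length`` bases) at any unit phase inside the tract yields
    the same accession sequence, so uniform scoring cannot distinguish the
    placements: the intron-interior one (``good_span``) leaves the acceptor
    columns matched and the reading frame intact, while ``bad_span``
    (straddling the boundary) destroys the acceptor and shifts the frame.
    Returns (edited reference genome, transcript, descriptor); apply the
    deletion at ``good_span`` (or any equivalent span) to obtain the
    accession sequence.

    The transcript must be plus-strand with a CDS-internal intron of length
    >= 1.5 * deletion_length + 6; ``deletion_length`` must be even, not
    divisible by 3, and >= 8 so the bad placement breaks the frame and the
    unit can host the acceptor motif.
    """
    if transcript.strand != "+":
        raise ContractError("ambiguous-locus engineering expects a + transcript")
    dl = deletion_length
    if dl % 2 or dl % 3 == 0 or dl < 8:
        raise ContractError(
            "deletion length must be even, not divisible by 3, and >= 8"
        )
    u = dl // 2
    introns = transcript.cds_internal_introns()
    usable = [iv for iv in introns if iv[1] - iv[0] >= 3 * u + 6]
    rng.shuffle(usable)
    if not usable:
        raise ContractError("no intron long enough for the engineered repeat")
    chrom_seq = genome[transcript.chrom]
    for _a, b in usable:
        exon_end = next(e for s, e in transcript.cds if s == b)
        if exon_end - b < 2 * u + 3:
            continue
        for _ in range(200):
            unit = _random_seq(rng, u - 2) + "AG"
            tract = unit * 5  # 3 intronic + 2 exonic copies
            edited = chrom_seq[: b - 3 * u] + tract + chrom_seq[b + 2 * u :]
            cand_genome = dict(genome)
            cand_genome[transcript.chrom] = edited
            if check_orf_state(transcript, cand_genome).intact:
                return cand_genome, transcript, AmbiguousLocus(
                    chrom=transcript.chrom,
                    transcript_id=transcript.transcript_id,
                    exon_start=b,
                    repeat_length=dl,
                    good_span=(b - 3 * u, b - u),
                    bad_span=(b - u, b + u),
                    motif_span=(b - 2, b),
                )
    raise ContractError("no usable intron/exon junction for the repeat")
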