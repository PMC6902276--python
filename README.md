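# zebralift

Feature-weighted ("zebraic") pairwise alignment for genome-annotation
lift-over, ORF-aware gene-model realignment, anchored base-pair-resolution
variant calling for de novo assemblies, and population variant
uniformization.

## The problem

When a reference annotation is projected onto another accession of the same
species — a pseudo-genome built from resequencing variants, or a de novo
assembly — INDELs near exon boundaries often have several equal-cost
placements under ordinary alignment scoring ("inconsistent alignment"). A
placement that crosses a splice site or shifts the reading frame turns a
perfectly functional gene into an apparent loss-of-function allele, which
contaminates downstream genetic-load, burden-test and expression analyses.
This is especially severe in plant populations, where INDEL density is high.

## The method

zebralift aligns the reference gene region (start codon to stop codon)
semi-globally against the query, but scores every reference column by its
genetic feature class. With `W_c`, `Gopen_c`, `Gext_c` per class
`c ∈ {start/stop codon, splice site, CDS, intron, other}`, the recurrences
are the affine-gap (Gotoh) system

    E[i,j] = max(E[i,j-1] − Gext_c(j),  H[i,j-1] − Gopen_c(j))
    F[i,j] = max(F[i-1,j] − Gext_c(j),  H[i-1,j] − Gopen_c(j))
    H[i,j] = max(H[i-1,j-1] + W_c(j)(q_i, d_j),  E[i,j],  F[i,j])

with the first row and column initialised to zero, traceback from the
maximum cell of the last reference column (the reference is covered end to
end; the query overhangs freely), and a traceback matrix whose cells hold
composite labels (e.g. `SNPORINSERTION`) wherever the maximum is tied.
Because splice-site and start/stop-codon columns carry near-unbreakable gap
penalties while intron columns are cheap, an ambiguously placeable INDEL is
steered into the intron and the lifted model stays ORF-intact.

A striped equivalent (`zsdp_align`) evaluates columns in array batches with
per-class query profiles, a lazy-F scan, and 8/16/32-bit score storage that
escalates on saturation; it is bitwise-identical to the plain fill. Long
sequences are aligned with a sliding window: each window's maximum last-row/
last-column cell anchors the next window, giving linear cost.

Around the aligner:

* **ORF-state checker** — seven integrity rules (splice motifs, minimum
  intron/CDS lengths, frame, premature stop, terminal stop, initial ATG)
  with IUPAC-ambiguity-aware semantics.
* **Pseudo-genome lift-over** — builds per-accession sequences from VCF and
  lifts coordinates/annotations by cumulative upstream shift counting.
* **Anchored variant calling** — matches gene IDs between two annotations
  with Needleman–Wunsch, uses start/stop-codon coordinates of colinear genes
  as anchors, aligns the inter-anchor fragments, and emits a variant set
  that reconstructs the assembly byte-exactly.
* **Per-feature MSA** — partitions the reference at feature boundaries and
  re-derives every accession's variant records from a common center-star
  alignment, so identical haplotypes share identical records.

## Worked example

A two-exon gene is engineered with a tandem repeat straddling an
intron/exon acceptor site, and the accession carries a 14-bp deletion whose
VCF record was (validly but unluckily) written across the acceptor:

```python
import numpy as np
from zebralift.fixtures import (FixtureSpec, generate_genome_with_annotation,
                                plant_ambiguous_indel_locus)
from zebralift.liftover import lift_annotation_resequencing
from zebralift.pseudogenome import Variant

spec = FixtureSpec(seed=42, chromosome_length=5000, n_genes=1,
                   exons_per_gene=(2, 3), intron_length=(40, 200),
                   minus_strand_fraction=0.0)
genome, annotation = generate_genome_with_annotation(spec)
transcript = next(annotation.transcripts())
genome, transcript, locus = plant_ambiguous_indel_locus(
    genome, transcript, np.random.default_rng(0))

s, e = locus.bad_span            # the motif-crossing representation
chrom = transcript.chrom
bad = Variant(chrom, s - 1, genome[chrom][s - 1] + genome[chrom][s:e],
              genome[chrom][s - 1])
lifted, report, pseudo, _ = lift_annotation_resequencing(
    annotation, genome, [bad])
entry = report.entries[transcript.transcript_id]
```

which prints, for the record above:

```
engineered locus: (2467, 2481) (intronic) vs (2481, 2495) (crosses the acceptor at (2486, 2488) )
standard lift ORF : lost (FRAME,NO_END_STOP,PREMATURE_STOP)
method            : ZDP_REALIGNED
after realignment : intact
```

The arithmetic lift inherits the record's placement and reports the gene as
loss-of-function; the feature-weighted realignment moves the deletion into
the intron and restores an intact ORF. `recall_variants` /
`replace_region_variants` then rewrite the VCF record to the intronic
representation without changing the accession's sequence.

## Command line

`zebralift` exposes the pipelines as subcommands: `pseudogeno` (pseudo-genome
from VCF), `liftgff` (resequencing-mode lift), `revariant` (realign broken
transcripts and rewrite their records), `annwga` (assembly-mode lift via
coarse range pairs), `varcall` (anchored variant calling), `msa` (variant
uniformization) and `orfcheck`. Run `zebralift COMMAND --help` for flags
(`--window`, `--score-profile`, `--splice-motifs`, `--min-intron`,
`--min-cds`, ...).

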