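# Methods

## Model

zebralift treats annotation lift-over as a constrained alignment problem:
the reference gene region (start codon through stop codon) must be aligned
end to end, the query locus may overhang freely, and the cost of disrupting
a reference base depends on what that base *is*. Each reference position
carries one of five feature classes — start/stop codon, splice site (the two
intronic bases at each CDS-internal intron boundary), CDS, intron, other —
assigned with precedence start/stop > splice > CDS > intron > other when
features overlap. Match/mismatch scores and affine gap penalties are chosen
per class, so the optimal alignment preferentially conserves coding sequence
and splice motifs and absorbs ambiguity into introns.

The recurrences are the standard affine-gap (Gotoh) system with per-column
parameters; `E` is the ref-consuming (deletion) channel penalised with the
consumed column's class, `F` the query-consuming (insertion) channel
penalised with the class of the most recently consumed reference column
(which for a vertical gap run is the column it sits at). Boundary rules:
`H` is zero along the first row *and* first column; the traceback starts at
the maximum-`H` cell of the last reference column (tie: smallest query
index) and runs to row 0 or column 0; any reference columns remaining when
the query is exhausted are emitted as deletions so the reference is always
fully covered. The reported score is the `H` optimum; the edge deletions
emitted for coverage are not part of it.

One design point deserves emphasis. A literal label-conditioned gap rule
("extend iff the neighbouring traceback label permits a continuation") is
*not* equivalent to the affine optimum whenever continuing a currently
non-optimal gap would beat re-opening (`H − E < Gopen − Gext`). This
package deliberately uses the exact `max(extend, open)` form: it coincides
with the label rule whenever the label is unambiguous, it is the form that
reduces to a textbook semi-global aligner under uniform scoring, and it is
what the brute-force path-enumeration oracle in the test suite verifies
cell-exactly.

### Traceback labels

The traceback matrix stores, per cell, the bit-set of channels achieving
the maximum: `MATCH` (diagonal), `DELETION` (ref-consuming), `INSERTION`
(query-consuming), plus the four composite tie labels
(`SNPORDELETION`, ..., `SNPORINSERTIONORDELETION`). During the walk a
composite cell inherits the move of the most recently seen certain cell
when that move is among its options, otherwise precedence MATCH > DELETION
> INSERTION applies. This is deterministic and seed-free; the traced path
is one of the tied optima. Label names follow variant semantics: an
insertion is extra query sequence (gap in the reference row).

### Striped evaluation

`zsdp_align` produces bitwise-identical output by construction: the same
integer recurrences are evaluated column-by-column over vectorised row
batches. Per (feature class, reference residue) a query profile vector of
`W` values is precomputed once; the intra-column dependency of `F` is
folded into a prefix-max scan (the lazy-F step: `F_i =
max(F_{i-1} − g, Htmp_{i-1} − Gopen)` with `g = min(Gext, Gopen)`, which is
exact because `H = max(Htmp, F)`). Score frontiers are stored at the
narrowest of 8/16/32/64-bit widths; before any stored value could leave the
representable range, the fill restarts one width up, so narrow arithmetic
can never silently wrap. Hardware SIMD intrinsics are not used; batched
array arithmetic realises the same contract.

### Sliding window

For long sequences the DP plane is tiled with `window × window` blocks.
Each block is filled with the striped DP (zero-initialised, as for a fresh
semi-global problem); the maximum cell of its last row or last column
(preferring the last column on ties) anchors the next block's origin, and
the per-block tracebacks are stitched. With `window ≥ max(m, n)` there is a
single block and the result equals the plain DP exactly; smaller windows
give linear total cost but, like banded alignment, can mis-place events
larger than the window (a relocated segment then decomposes into scattered
calls — reconstruction remains exact, see below). Multi-block alignments
report the stitched alignment's re-derived score rather than a sum of
incomparable per-block optima. In full-coverage mode (used for variant
calling) query overhangs at block seams and sequence ends are emitted as
explicit insertions, so every base of both sequences appears in the
alignment.

## ORF-state rules

A transcript is ORF-intact iff all of: (1) every CDS-internal intron's
terminal dinucleotides (transcription orientation) match a donor/acceptor
pair in the motif set (default GT–AG, GC–AG, AT–AC); (2) every CDS-internal
intron is longer than `min_intron_length` (default 5 bp); (3) the CDS is
longer than `min_cds_length` (default 9 bp); (4) CDS length ≡ 0 (mod 3);
(5) no premature stop; (6) the last codon is a stop; (7) the first codon is
ATG. The length defaults admit the smallest biologically sensible models
and are overridable everywhere. All failures are reported, not only the
first. UTR introns are not checked (they cannot affect the ORF), and UTR
exon bases are labelled `other` in the feature track, since the weighted
alignment region runs from start codon to stop codon.

IUPAC ambiguity codes are handled by base-set intersection, asymmetrically
by design: rules 1, 6 and 7 accept a codon/motif if *some* resolution
matches (an `N` never causes a false loss-of-function call), while rule 5
counts a codon as a premature stop only if *every* resolution is a stop
(`TRA` is a stop, `NNN` is not). Residue comparison inside the aligner uses
the same intersection rule via 4-bit base masks.

## Coordinate lift-over

Pseudo-genomes substitute ALT alleles into the reference; lift-over adds
the cumulative length difference of strictly upstream variants. The
`ShiftIndex` stores positionally matched sequence blocks, making both
directions O(log v) and exactly inverse on surviving positions. A position
inside a deleted span reports the zero-width pseudo-genome interval the
span collapsed to (`Deleted(left == right)`); feature boundaries landing in
deleted spans snap toward the feature interior, so lifted features never
grow across deleted sequence. Overlapping input variants are a hard error.
INDEL records use the VCF left-anchored convention externally; the common
prefix/suffix is stripped internally before application.

## Lift-over pipelines

Resequencing mode lifts all transcripts arithmetically, ORF-checks each
against the pseudo-genome, and realigns only broken ones (the check is the
trigger); a realignment that yields an intact model replaces the standard
lift, otherwise the conservative standard-lift model is kept and reported
lost. The realignment window is the lifted locus extended by one gene
length per side; minus-strand transcripts are aligned on the
reverse-complemented strand and mapped back. Realigned models are re-derived
inside the CDS span only, so they carry no UTR exons. Assembly mode does
the same through coarse range pairs (e.g. from a whole-genome aligner),
aligning each range at base-pair resolution with the sliding window and a
feature track overlaid from all contained transcripts. A hook accepts
externally produced candidate models (orthologue search, ab initio) for
transcripts that remain broken; no external tool is invoked.

`recall_variants` walks alignment columns, merging adjacent same-orientation
gap columns into single INDELs with VCF anchors; `replace_region_variants`
swaps records for a region while — by construction of the recalled set —
leaving the implied pseudo-genome sequence unchanged.

## Anchored variant calling

Per-chromosome gene-ID sequences of the two annotations are aligned with
Needleman–Wunsch (+1 identical IDs, −1 mismatch and gap; these values are
this package's choice). Chromosomes are paired by majority shared gene
content. Matched genes that break query-coordinate monotonicity are dropped
(longest increasing subsequence), so anchors are colinear; relocations
therefore surface as DEL+INS decompositions rather than rearrangement
calls. Anchors cut both genomes at the CDS-span start (the anchor codons
themselves are aligned within the following fragment, so no real variant is
skipped); fragments tile both genomes, are aligned in full-coverage mode
with intergenic-class scoring, and their recalled records — with insertions
meeting at fragment seams concatenated — reconstruct the query genome
byte-exactly. That reconstruction identity is the module's central,
representation-independent contract and holds for any valid alignment of
each fragment.

## Variant uniformization

The reference is partitioned at feature boundaries into CDS / intron /
intergenic elements. For uniformization, each accession's element intervals
are cut on a sequence-level alignment of its pseudo-genome to the reference
(zebraic scoring, full coverage), *not* on the input variants' shift
arithmetic: shift-derived cuts inherit the input representation, so two
encodings of one haplotype would partition differently and could never
converge. Alignment-derived cuts depend only on the sequences, so identical
haplotypes receive identical intervals, identical per-element alignments,
and byte-identical records, while applying any accession's records still
regenerates its pseudo-genome exactly. Elements are multiply aligned by
reference-centred center-star: each accession is pairwise aligned to the
reference element (long elements through the sliding-window aligner, which
realises windowed alignment plus stitching) and merged on reference
coordinates with maximal insertion slots. Center-star with the reference as
center is this package's choice of MSA objective; it keeps reference
coordinates primary and is deterministic.

## Default scoring profile

| class | match | mismatch | gap open | gap ext |
|---|---|---|---|---|
| CDS | +6 | −6 | 26 | 2 |
| splice site, start/stop codon | +30 | −30 | 110 | 110 |
| intron, other | +2 | −2 | 4 | 1 |

The ordering (splice/codon ≫ CDS ≫ intron) is the method's substance; the
magnitudes are package defaults chosen so that a splice-site gap can never
out-compete any plausible intronic alternative within a gene-sized window,
and are fully overridable via the `<class>.<field>=<int>` config. Profiles
violating `gap_open ≥ gap_ext` or the class ordering trigger a warning, not
an error.

## Synthetic data

The fixture generator emulates compact plant-like genomes: uniform-random
background (GC ≈ 0.5), 1–4 exons per gene of 30–120 codons, GT..AG introns
of 20–200 bp, both strands, no UTRs; every generated transcript is asserted
ORF-intact at generation time. Variant planting spaces events so spans and
anchors cannot interact, and returns a truth set whose application *is* the
mutated genome. The ambiguous-INDEL locus writes a tandem repeat (unit
length 7 ending in AG, three copies in the intron tail, two in the exon
head) so a 14-bp deletion has three equal-result placements: uniform
scoring cannot distinguish them, and only the intron-interior one leaves
the acceptor columns aligned. (A 14-bp unit-pair deletion is used rather
than an arbitrary odd length because placement equivalence across the
acceptor requires the deletion to be a whole number of repeat units;
14 ≢ 0 mod 3 still shifts the frame under mis-placement.) What passing
tests show is algorithmic correctness on clean gene structures — not
robustness to assembly errors, repeats, paralogy or real splice-site
diversity.

## Problem sizes

The shipped test-bench and `scripts/acceptance.py` run, per invocation:
200 short pairs against the path-enumeration oracle; 500 pairs (50–300 bp)
of plain-vs-striped equivalence; 100 pairs against the textbook aligner;
100 sliding-window exactness pairs plus a 10-kb / 10-SNP recovery; 100
(tests) or 50 (script) ambiguous loci; 50 genome pairs of 10–100 kb (tests)
or 10 of 20–60 kb (script) for reconstruction exactness; 1,000 random
variant sets for lift inversion; and 20 (tests) or 10 (script) population
fixtures for uniformization. These sizes exercise every code path at
population scale while keeping a full run in minutes on one CPU.

## Known limitations

* The sliding window is a heuristic: events larger than the window may be
  decomposed suboptimally (reconstruction stays exact; representation
  quality degrades). Use a window larger than the largest expected event.
* Gene models are single-ORF and use the standard genetic code; no
  selenocysteine or polycistronic handling.
* Assembly-mode lift skips transcripts straddling a range-pair edge
  (reported UNPLACED) rather than merging across ranges.
* The variant caller's non-colinear gene matches are dropped, so inverted
  or translocated blocks are represented as DEL+INS, never classified.
* VCF output is minimal 8-column; genotypes and phasing are out of scope.
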