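import numpy as np
import pytest

from zebralift.annotation_core import GenomeAnnotation, TranscriptModel
from zebralift.zdp import ScoringProfile


@pytest.fixture(scope="session")
def zebraic_profile() -> ScoringProfile:
    return ScoringProfile.default_zebraic()


@pytest.fixture(scope="session")
def uniform_profile() -> ScoringProfile:
    return ScoringProfile.uniform(match=2, mismatch=-2, gap_open=4, gap_ext=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def two_exon_transcript() -> TranscriptModel:
    """A plus-strand two-exon gene: CDS [10,19) + [99,105), intron [19,99)."""
    return TranscriptModel(
        gene_id="g1",
        transcript_id="g1.1",
        chrom="c1",
        strand="+",
        exons=[(10, 19), (99, 105)],
        cds=[(10, 19), (99, 105)],
    )


def make_genome_for(transcript: TranscriptModel, length: int = 200) -> dict:
    """Background genome that renders ``transcript`` ORF-intact."""
    rng = np.random.default_rng(1)
    seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)]))
    coding = [p for s, e in transcript.cds for p in range(s, e)]
    body = "ATG" + "GCC" * ((len(coding) - 6) // 3) + "TAA"
    assert len(body) == len(coding)
    if transcript.strand == "-":
        from zebralift.annotation_core import reverse_complement

        body = reverse_complement(body)
    for p, b in zip(coding, body):
        seq[p] = b
    for a, b in transcript.cds_internal_introns():
        if transcript.strand == "+":
            seq[a], seq[a + 1], seq[b - 2], seq[b - 1] = "G", "T", "A", "G"
        else:
            seq[a], seq[a + 1], seq[b - 2], seq[b - 1] = "C", "T", "A", "C"
    return {transcript.chrom: "".join(seq)}
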