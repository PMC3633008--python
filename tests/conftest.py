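import pytest
from hypothesis import settings

from trex.models import GeneModel, GenomicInterval, TranscriptModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_transcript(
    chrom="chr1",
    strand="+",
    exons=((100, 200), (300, 400), (500, 650)),
    tx_id="tx1",
    gene_id="geneA",
    cds_span=None,
):
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return TranscriptModel(transcript_id=tx_id, gene_id=gene_id, exons=ivs, cds_span=cds_span)


def make_gene(gene_id="geneA", chrom="chr1", strand="+", exons=((100, 200), (300, 400), (500, 650)), cds_span=None):
    tx = make_transcript(chrom, strand, exons, f"{gene_id}.t1", gene_id, cds_span)
    span = GenomicInterval(chrom, tx.start, tx.end, strand)
    return GeneModel(gene_id=gene_id, symbol=gene_id.upper(), span=span, transcripts=(tx,))


@pytest.fixture
def three_exon_gene():
    return make_gene()


@pytest.fixture
def flat_genome():
    """A constant background genome so splice motifs are controllable."""
    from trex.io_formats import ReferenceGenome

    seq = list("A" * 2000)

    def plant(pos, motif):
        seq[pos : pos + len(motif)] = list(motif)

    # canonical motifs for the introns of the standard three-exon gene
    plant(200, "GT")
    plant(298, "AG")
    plant(400, "GT")
    plant(498, "AG")
    return ReferenceGenome.from_dict({"chr1": "".join(seq)})
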