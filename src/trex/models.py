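"""Core domain types shared by every stage of the pipeline.

All coordinates are 0-based, half-open, on the forward genomic strand.
Conversion from the 1-based inclusive conventions of GFF and SAM happens
only in :mod:`trex.io_formats`; nothing else in the package ever sees a
1-based coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-", "?")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``+``, ``-`` or ``?`` (unknown / not applicable).
    """

    chrom: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def key(self) -> tuple:
        """Strand-free identity used for intron bookkeeping."""
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an exon chain plus an optional CDS.

    ``exons`` are sorted, non-overlapping intervals on a single chromosome
    and strand; the gaps between consecutive exons are the annotated
    introns.  ``cds_span`` is given in *transcript* coordinates (0-based,
    half-open over the spliced sequence, 5' to 3').
    """

    transcript_id: str
    gene_id: str
    exons: tuple
    cds_span: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"transcript {self.transcript_id} spans chromosomes")
        if len(strands) > 1 or "?" in strands:
            raise ValueError(f"transcript {self.transcript_id} has mixed strands")
        prev = None
        for e in self.exons:
            if prev is not None and e.start <= prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons not sorted or "
                    f"separated by at least one base"
                )
            prev = e
        if self.cds_span is not None:
            s, e = self.cds_span
            if not (0 <= s < e <= self.spliced_length):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS outside spliced length"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> list:
        """Annotated introns, i.e. the gaps of the exon chain."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    # --- coordinate projection -------------------------------------------
    # Transcript coordinate 0 is the 5' end of the mature transcript, which
    # for a '-' strand transcript is the *last* genomic exon end.

    def genomic_blocks_for(self, t_start: int, t_end: int) -> list:
        """Genomic intervals covered by transcript slice ``[t_start, t_end)``."""
        if not (0 <= t_start < t_end <= self.spliced_length):
            raise ValueError("transcript slice out of range")
        exons = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        blocks = []
        offset = 0
        for exon in exons:
            lo = max(t_start, offset)
            hi = min(t_end, offset + exon.length)
            if lo < hi:
                if self.strand == "+":
                    g0 = exon.start + (lo - offset)
                    g1 = exon.start + (hi - offset)
                else:
                    g1 = exon.end - (lo - offset)
                    g0 = exon.end - (hi - offset)
                blocks.append(GenomicInterval(self.chrom, g0, g1, self.strand))
            offset += exon.length
        blocks.sort()
        return blocks

    def transcript_intervals_for(self, block: GenomicInterval) -> list:
        """Project a genomic interval onto transcript coordinates.

        Returns the (possibly empty) list of transcript-coordinate
        half-open intervals covered by ``block``; parts of ``block``
        falling in introns or outside the transcript are dropped.
        """
        exons = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        out = []
        offset = 0
        for exon in exons:
            ov = exon.overlap_length(block)
            if ov:
                lo_g = max(exon.start, block.start)
                hi_g = min(exon.end, block.end)
                if self.strand == "+":
                    out.append((offset + (lo_g - exon.start), offset + (hi_g - exon.start)))
                else:
                    out.append((offset + (exon.end - hi_g), offset + (exon.end - lo_g)))
            offset += exon.length
        return sorted(out)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: a strand-bearing span plus its transcripts."""

    gene_id: str
    symbol: str
    span: GenomicInterval
    transcripts: tuple = ()

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for tx in self.transcripts:
            if tx.chrom != self.span.chrom:
                raise ValueError(f"gene {self.gene_id}: transcript off-chromosome")
            if tx.start < self.span.start or tx.end > self.span.end:
                raise ValueError(
                    f"gene {self.gene_id}: span does not cover transcript "
                    f"{tx.transcript_id}"
                )

    @property
    def strand(self) -> str:
        return self.span.strand

    def annotated_introns(self) -> set:
        """Strand-free keys of every intron of every transcript."""
        keys = set()
        for tx in self.transcripts:
            for intron in tx.introns():
                keys.add(intron.key())
        return keys


@dataclass
class AlignedRead:
    """One genomic alignment ("hit") of one read.

    ``blocks`` are the aligned reference segments; gaps between
    consecutive blocks are candidate introns.  ``matches`` counts
    identically aligned bases, ``aligned_bases`` the read bases aligned to
    the reference.  ``n_hits`` is the number of genomic hits reported for
    the read as a whole, so every hit of a multi-mapping read carries the
    same value.  ``read_strand`` is the strand of the reference the read
    sequence aligned to; it equals the transcript strand only when
    ``oriented`` is true (i.e. preprocessing established strandness).
    """

    read_id: str
    blocks: list
    read_length: int
    matches: int
    aligned_bases: int
    n_hits: int = 1
    oriented: bool = False
    read_strand: str = "?"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id}: no aligned blocks")
        chroms = {b.chrom for b in self.blocks}
        if len(chroms) > 1:
            raise ValueError(f"read {self.read_id}: blocks span chromosomes")
        prev = None
        for b in self.blocks:
            if prev is not None and b.start < prev.end:
                raise ValueError(f"read {self.read_id}: blocks overlap or unsorted")
            prev = b
        if self.aligned_bases > self.read_length:
            raise ValueError(f"read {self.read_id}: aligned_bases > read_length")
        if self.matches > self.aligned_bases:
            raise ValueError(f"read {self.read_id}: matches > aligned_bases")
        if self.n_hits < 1:
            raise ValueError(f"read {self.read_id}: n_hits < 1")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.blocks[0].start, self.blocks[-1].end, self.read_strand
        )

    def introns(self) -> list:
        """Gaps between aligned blocks (candidate introns)."""
        out = []
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return out

    @property
    def spliced(self) -> bool:
        return any(b.start > a.end for a, b in zip(self.blocks, self.blocks[1:]))


CONFIDENCE_ORDER = {"T": 3, "G": 2, "P": 1}


@dataclass(frozen=True)
class Assignment:
    """Final read-to-gene assignment record.

    ``confidence`` is one of T (transcript-compatible), G (genic) or P
    (proximal); ``ambiguity_class`` is a frozenset drawn from {"I", "II"};
    ``status`` is ``unique`` (never ambiguous), ``resolved`` (ambiguity
    solved by the cascade), ``shared`` (unresolved, assigned to all
    competing genes) or ``discarded``.
    """

    read_id: str
    gene_id: str
    confidence: str
    ambiguity_class: frozenset = frozenset()
    status: str = "unique"

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_ORDER:
            raise ValueError(f"invalid confidence {self.confidence!r}")
        if self.status not in ("unique", "resolved", "shared", "discarded"):
            raise ValueError(f"invalid status {self.status!r}")
        if not self.ambiguity_class <= {"I", "II"}:
            raise ValueError("ambiguity_class must be a subset of {'I','II'}")


@dataclass
class IntronObservation:
    """One distinct observed intron with per-dataset read support.

    ``donor``/``acceptor`` are strand-adjusted terminal dinucleotides (the
    donor is at the 5' end of the intron *on the transcript strand*);
    ``canonical`` means GT..AG after strand adjustment.
    """

    locus: GenomicInterval
    donor: str
    acceptor: str
    inferred_strand: str
    annotated: bool
    canonical: bool
    support: dict = field(default_factory=dict)
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.locus.length < 4:
            raise ValueError("intron shorter than 4 bases")

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass(frozen=True)
class GeneMetrics:
    """Per-gene, per-dataset expression indices.

    coverage: number of reads assigned to the gene; depth: maximum number
    of assigned reads covering any single genic position; focusing_index:
    depth / coverage, near 1 when reads stack at one spot (repeat-like),
    near 0 when spread evenly.
    """

    gene_id: str
    dataset_id: str
    coverage: int
    depth: int

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise ValueError("metrics are only defined for covered genes")
        if not (1 <= self.depth <= self.coverage):
            raise ValueError("depth must lie in [1, coverage]")

    @property
    def focusing_index(self) -> float:
        return self.depth / self.coverage


@dataclass(frozen=True)
class DEResult:
    """Differential representation of one feature between two datasets."""

    feature_id: str
    count_ref: int
    count_other: int
    total_ref: int
    total_other: int
    fold_change: float
    p_value: float
    q_value: float

    @property
    def direction(self) -> str:
        return "up" if self.fold_change >= 1.0 else "down"
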