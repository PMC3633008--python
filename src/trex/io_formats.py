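"""Readers and writers for FASTA, FASTQ, SAM, GFF/GTF and report tables.

This is the only module that touches file-format coordinate conventions:
GFF and SAM are 1-based inclusive on disk and converted to the package's
internal 0-based half-open convention on the way in, and back on the way
out.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import gffutils
import pysam
from intervaltree import IntervalTree

from .models import AlignedRead, GeneModel, GenomicInterval, TranscriptModel

log = logging.getLogger(__name__)


class CigarError(ValueError):
    """Raised on a malformed CIGAR string."""


class AnnotationError(ValueError):
    """Raised on structurally invalid gene annotation."""


# ---------------------------------------------------------------------------
# CIGAR handling
# ---------------------------------------------------------------------------

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")

# reference-consuming ops that stay inside the current block
_BLOCK_OPS = set("MDX=")


def cigar_to_blocks(pos: int, cigar: str) -> Tuple[List[GenomicInterval], List[GenomicInterval]]:
    """Convert a SAM CIGAR into aligned blocks and intron gaps.

    ``pos`` is the 1-based leftmost mapping position as stored in SAM.
    M/=/X/D consume reference within the current block; N closes the block
    and records an intron; S/H/I consume no reference.  Returned
    coordinates are 0-based half-open on an unnamed chromosome placeholder
    ``"."`` — callers re-home them onto the record's reference.

    Raises :class:`CigarError` on any token outside M/I/D/N/S/H/=/X.
    """
    if not cigar or cigar == "*":
        raise CigarError("empty CIGAR")
    consumed = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        consumed += len(m.group(0))
    if consumed != len(cigar):
        raise CigarError(f"malformed CIGAR {cigar!r}")

    ref = pos - 1
    block_start = ref
    blocks: List[GenomicInterval] = []
    introns: List[GenomicInterval] = []
    for m in _CIGAR_TOKEN.finditer(cigar):
        length, op = int(m.group(1)), m.group(2)
        if op == "P":
            raise CigarError(f"unsupported CIGAR operator 'P' in {cigar!r}")
        if op in _BLOCK_OPS:
            ref += length
        elif op == "N":
            if ref > block_start:
                blocks.append(GenomicInterval(".", block_start, ref))
            introns.append(GenomicInterval(".", ref, ref + length))
            ref += length
            block_start = ref
        # S, H, I: no reference consumption
    if ref > block_start:
        blocks.append(GenomicInterval(".", block_start, ref))
    if not blocks:
        raise CigarError(f"CIGAR {cigar!r} consumes no reference")
    return blocks, introns


def _rehome(intervals: List[GenomicInterval], chrom: str, strand: str = "?") -> List[GenomicInterval]:
    return [GenomicInterval(chrom, iv.start, iv.end, strand) for iv in intervals]


# ---------------------------------------------------------------------------
# Genome access
# ---------------------------------------------------------------------------


class ReferenceGenome:
    """Uniform 0-based half-open sequence access over FASTA or dict sources."""

    def __init__(self, source):
        self._source = source

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        import pyfaidx

        return cls(pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True))

    @classmethod
    def from_dict(cls, seqs: Dict[str, str]) -> "ReferenceGenome":
        return cls({k: v.upper() for k, v in seqs.items()})

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._source:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._source[chrom][start:end]
        return str(seq).upper()

    def length(self, chrom: str) -> int:
        return len(self._source[chrom])

    def chroms(self) -> List[str]:
        return list(self._source.keys())


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def write_fasta(seqs: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str) -> Iterator[Tuple[str, str, List[int]]]:
    """Yield (read_id, bases, phred_qualities) from a Sanger-encoded FASTQ."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"])


def write_fastq(records: Iterable[Tuple[str, str, List[int]]], path: str) -> int:
    n = 0
    with open(path, "w") as fh:
        for read_id, bases, quals in records:
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read_id}\n{bases}\n+\n{qline}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Annotation (GFF3 / GTF)
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


class GeneIndex:
    """Gene models indexed per chromosome for interval queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: Dict[str, GeneModel] = {}
        self._trees: Dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            tree = self._trees.setdefault(gene.span.chrom, IntervalTree())
            tree.addi(gene.span.start, gene.span.end, gene.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def query(self, chrom: str, start: int, end: int) -> List[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end), key=lambda iv: (iv.begin, iv.data))
        return [self.genes[iv.data] for iv in hits]

    def annotated_introns(self) -> Dict[tuple, set]:
        """Map strand-free intron key -> set of owning gene ids."""
        table: Dict[tuple, set] = {}
        for gene in self:
            for key in gene.annotated_introns():
                table.setdefault(key, set()).add(gene.gene_id)
        return table


def load_annotation(path: str) -> GeneIndex:
    """Load gene/transcript/exon/CDS structure from GFF3 or GTF.

    1-based inclusive file coordinates become 0-based half-open.  CDS
    features, when present, are projected into transcript coordinates and
    stored as ``cds_span``.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        log.warning("annotation %s contains no features", path)
        return GeneIndex([])
    gene_features = list(db.features_of_type("gene"))
    if not gene_features:
        log.warning("annotation %s contains no gene features", path)
        return GeneIndex([])

    genes: List[GeneModel] = []
    seen_tx_parents = set()
    for gf in gene_features:
        transcripts = []
        for tf in db.children(gf, level=1):
            if tf.featuretype not in _TRANSCRIPT_TYPES:
                continue
            seen_tx_parents.add(tf.id)
            exons = []
            cds_parts = []
            for child in db.children(tf, level=1):
                iv = GenomicInterval(child.seqid, child.start - 1, child.end, child.strand)
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds_parts.append(iv)
            if not exons:
                raise AnnotationError(f"transcript {tf.id} has no exons")
            strands = {e.strand for e in exons}
            if len(strands) > 1:
                raise AnnotationError(f"transcript {tf.id} has mixed-strand exons")
            if strands == {"?"} or "?" in strands:
                raise AnnotationError(f"transcript {tf.id} has unstranded exons")
            exons.sort(key=lambda e: e.start)
            try:
                tx = TranscriptModel(
                    transcript_id=tf.id,
                    gene_id=gf.id,
                    exons=tuple(exons),
                    cds_span=_cds_to_transcript_coords(exons, cds_parts, tf.id),
                )
            except ValueError as exc:
                raise AnnotationError(str(exc)) from exc
            transcripts.append(tx)
        if not transcripts:
            raise AnnotationError(f"gene {gf.id} has no transcripts")
        start = min(tx.start for tx in transcripts)
        end = max(tx.end for tx in transcripts)
        span = GenomicInterval(
            gf.seqid, min(start, gf.start - 1), max(end, gf.end), gf.strand
        )
        symbol = gf.attributes.get("Name", [gf.id])[0]
        genes.append(
            GeneModel(gene_id=gf.id, symbol=symbol, span=span, transcripts=tuple(transcripts))
        )

    # orphan checks: exons/transcripts whose parents are not in the tree
    for tf in db.features_of_type(tuple(_TRANSCRIPT_TYPES)):
        parents = [p for p in db.parents(tf, level=1) if p.featuretype == "gene"]
        if not parents:
            raise AnnotationError(f"transcript {tf.id} has no parent gene")
    for ef in db.features_of_type("exon"):
        parents = [p for p in db.parents(ef, level=1) if p.featuretype in _TRANSCRIPT_TYPES]
        if not parents:
            raise AnnotationError(f"exon at {ef.seqid}:{ef.start}-{ef.end} has no parent transcript")

    return GeneIndex(genes)


def _cds_to_transcript_coords(exons, cds_parts, tx_id) -> Optional[tuple]:
    if not cds_parts:
        return None
    tmp = TranscriptModel(transcript_id=tx_id, gene_id="_", exons=tuple(exons))
    positions = []
    for part in cds_parts:
        ivs = tmp.transcript_intervals_for(part)
        if sum(b - a for a, b in ivs) != part.length:
            raise AnnotationError(f"transcript {tx_id}: CDS not contained in exons")
        positions.extend(ivs)
    start = min(a for a, _ in positions)
    end = max(b for _, b in positions)
    return (start, end)


def write_annotation(index: GeneIndex, path: str) -> None:
    """Write gene models back out as GFF3 (inverse of :func:`load_annotation`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in index:
            g = gene.span
            fh.write(
                f"{g.chrom}\ttrex\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={gene.gene_id};Name={gene.symbol}\n"
            )
            for tx in gene.transcripts:
                fh.write(
                    f"{g.chrom}\ttrex\tmRNA\t{tx.start + 1}\t{tx.end}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={gene.gene_id}\n"
                )
                for i, exon in enumerate(tx.exons, 1):
                    fh.write(
                        f"{g.chrom}\ttrex\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{tx.strand}\t.\tID={tx.transcript_id}.e{i};Parent={tx.transcript_id}\n"
                    )
                if tx.cds_span is not None:
                    for j, block in enumerate(tx.genomic_blocks_for(*tx.cds_span), 1):
                        fh.write(
                            f"{g.chrom}\ttrex\tCDS\t{block.start + 1}\t{block.end}\t.\t"
                            f"{tx.strand}\t0\tID={tx.transcript_id}.c{j};Parent={tx.transcript_id}\n"
                        )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _matches_from_record(rec: "pysam.AlignedSegment", aligned_bases: int) -> int:
    """Identically aligned bases, from NM when present, else MD, else all.

    NM counts mismatches plus inserted and deleted bases, so mismatches =
    NM - I - D and matches = aligned_bases - mismatches.
    """
    ins = sum(l for op, l in rec.cigartuples if op == 1)  # I
    dels = sum(l for op, l in rec.cigartuples if op == 2)  # D
    if rec.has_tag("NM"):
        mismatches = int(rec.get_tag("NM")) - ins - dels
        return aligned_bases - max(0, mismatches)
    if rec.has_tag("MD"):
        md = str(rec.get_tag("MD"))
        matched = sum(int(x) for x in re.findall(r"(\d+)", md))
        return min(matched, aligned_bases)
    return aligned_bases


def read_sam(path: str) -> Dict[str, List[AlignedRead]]:
    """Load a SAM file into hits grouped per read.

    ``n_hits`` comes from the NH tag when present; otherwise it is the
    number of alignment records sharing the read id.  Unmapped records are
    skipped.
    """
    by_read: Dict[str, List[AlignedRead]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            cigar = rec.cigarstring
            blocks, _ = cigar_to_blocks(rec.reference_start + 1, cigar)
            strand = "-" if rec.is_reverse else "+"
            blocks = _rehome(blocks, rec.reference_name, strand)
            aligned = sum(l for op, l in rec.cigartuples if op in (0, 7, 8))  # M,=,X
            read_len = rec.infer_read_length() or aligned
            hit = AlignedRead(
                read_id=rec.query_name,
                blocks=blocks,
                read_length=read_len,
                matches=_matches_from_record(rec, aligned),
                aligned_bases=aligned,
                n_hits=int(rec.get_tag("NH")) if rec.has_tag("NH") else 1,
                read_strand=strand,
            )
            by_read.setdefault(rec.query_name, []).append(hit)
    for read_id, hits in by_read.items():
        n = max(len(hits), max(h.n_hits for h in hits))
        for h in hits:
            h.n_hits = n
    return by_read


def sam_header(chrom_lengths: Dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
        }
    )


# ---------------------------------------------------------------------------
# Tab-delimited report tables
# ---------------------------------------------------------------------------


def write_table(rows: Iterable[dict], columns: List[str], path: str, comments: Optional[List[str]] = None) -> None:
    """UTF-8, tab-delimited, one header line, '#'-prefixed comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def read_table(path: str):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
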