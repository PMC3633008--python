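"""Intron-centric splice-site catalog.

Splicing is represented as a catalog of observed introns rather than
exon-level event types: every distinct (chrom, start, end) gap seen in a
spliced alignment becomes one observation, annotated or novel, with its
donor/acceptor motif, an inferred strand and per-dataset read support.
Observations are never assembled into transcript models.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence

from .assign import AssignResult, infer_strand_from_splices
from .io_formats import GeneIndex, ReferenceGenome, write_table
from .models import AlignedRead, GenomicInterval, IntronObservation, reverse_complement

log = logging.getLogger(__name__)


def _motifs(locus: GenomicInterval, strand: str, genome: ReferenceGenome) -> tuple:
    """Strand-adjusted (donor, acceptor) dinucleotides of an intron."""
    left = genome.fetch(locus.chrom, locus.start, locus.start + 2)
    right = genome.fetch(locus.chrom, locus.end - 2, locus.end)
    if strand == "-":
        return reverse_complement(right), reverse_complement(left)
    return left, right


def collect_introns(
    datasets: Dict[str, tuple],
    genome: ReferenceGenome,
    genes: GeneIndex,
    annotated_introns: Optional[Dict[tuple, set]] = None,
) -> List[IntronObservation]:
    """Build the intron catalog over one or more datasets.

    ``datasets`` maps dataset_id to ``(hits_by_read, AssignResult)`` for
    that dataset.  Reads discarded as unresolvable ambiguous do not
    contribute support; extragenic (O) reads do, with no owning gene.
    Identity of an intron is its exact coordinates; support from several
    datasets accumulates on a single observation.
    """
    if annotated_introns is None:
        annotated_introns = genes.annotated_introns()

    support: Dict[tuple, Dict[str, int]] = {}
    owner_votes: Dict[tuple, Dict[str, int]] = {}
    for dataset_id, (hits_by_read, result) in datasets.items():
        assigned_gene: Dict[str, Optional[str]] = {}
        for a in result.assignments:
            # a shared read votes for each of its genes; first wins below
            assigned_gene.setdefault(a.read_id, a.gene_id)
        for read_id in result.extragenic:
            assigned_gene[read_id] = None
        for read_id, hits in hits_by_read.items():
            if read_id not in assigned_gene:
                continue  # discarded-ambiguous or filtered upstream
            seen_keys = set()
            for hit in hits:
                for intron in hit.introns():
                    if intron.length < 4:
                        log.warning("read %s: intron %s too short, skipped", read_id, intron)
                        continue
                    if intron.end > genome.length(intron.chrom):
                        raise ValueError(
                            f"read {read_id}: intron end {intron.end} beyond "
                            f"chromosome {intron.chrom}"
                        )
                    seen_keys.add(intron.key())
            for key in seen_keys:
                support.setdefault(key, {}).setdefault(dataset_id, 0)
                support[key][dataset_id] += 1
                gene_id = assigned_gene[read_id]
                if gene_id is not None:
                    owner_votes.setdefault(key, {}).setdefault(gene_id, 0)
                    owner_votes[key][gene_id] += 1

    observations: List[IntronObservation] = []
    for key in sorted(support):
        chrom, start, end = key
        locus = GenomicInterval(chrom, start, end)
        votes = owner_votes.get(key, {})
        gene_id = max(sorted(votes), key=lambda g: votes[g]) if votes else None
        strand = infer_strand_from_splices([locus], genome)
        if strand == "?" and gene_id is not None:
            strand = genes.genes[gene_id].strand
        donor, acceptor = _motifs(locus, strand, genome)
        observations.append(
            IntronObservation(
                locus=GenomicInterval(chrom, start, end, strand),
                donor=donor,
                acceptor=acceptor,
                inferred_strand=strand,
                annotated=key in annotated_introns,
                canonical=(donor == "GT" and acceptor == "AG"),
                support=dict(support[key]),
                gene_id=gene_id,
            )
        )
    return observations


def filter_introns(
    observations: Sequence[IntronObservation],
    min_support: int = 1,
    canonical_only: bool = False,
) -> List[IntronObservation]:
    """Keep observations with total support >= min_support (and, when
    requested, canonical GT..AG motifs), sorted by descending support then
    locus."""
    kept = [
        o
        for o in observations
        if o.total_support >= min_support and (o.canonical or not canonical_only)
    ]
    kept.sort(key=lambda o: (-o.total_support, o.locus))
    return kept


def write_intron_table(
    observations: Sequence[IntronObservation], dataset_ids: Sequence[str], path: str
) -> None:
    columns = [
        "chrom",
        "start",
        "end",
        "strand",
        "donor",
        "acceptor",
        "canonical",
        "annotated",
        "gene_id",
    ] + [f"support_{d}" for d in dataset_ids]
    rows = []
    for o in observations:
        row = {
            "chrom": o.locus.chrom,
            "start": o.locus.start,
            "end": o.locus.end,
            "strand": o.inferred_strand,
            "donor": o.donor,
            "acceptor": o.acceptor,
            "canonical": int(o.canonical),
            "annotated": int(o.annotated),
            "gene_id": o.gene_id if o.gene_id is not None else ".",
        }
        for d in dataset_ids:
            row[f"support_{d}"] = o.support.get(d, 0)
        rows.append(row)
    write_table(rows, columns, path)


def write_junction_bed(observations: Sequence[IntronObservation], path: str) -> None:
    """BED12-style junction export (2-base anchors flanking each intron)."""
    with open(path, "w") as fh:
        for i, o in enumerate(observations):
            chrom_start = o.locus.start - 2
            chrom_end = o.locus.end + 2
            name = f"JUNC{i + 1:06d}"
            strand = o.inferred_strand if o.inferred_strand in "+-" else "."
            block_starts = f"0,{o.locus.end - chrom_start}"
            fh.write(
                f"{o.locus.chrom}\t{chrom_start}\t{chrom_end}\t{name}\t"
                f"{o.total_support}\t{strand}\t{chrom_start}\t{chrom_end}\t0,0,255\t"
                f"2\t2,2\t{block_starts}\n"
            )
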