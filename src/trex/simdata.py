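"""Deterministic synthetic data: genome, annotation, reads and truth tables.

The generator plants every hard case the annotation engine has to face:
multi-exon genes with canonical GT..AG introns, antisense gene pairs that
overlap (class I ambiguity), paralogous gene copies that make reads
multi-map (class II ambiguity), un-annotated GT..AG introns with a fixed
number of supporting junction reads, barcoded/adapter-flanked reads for
the preprocessing stage, and per-gene abundance folds between datasets
for differential expression.  All randomness flows from a single integer
seed through one ``numpy`` generator; rerunning with the same
configuration is byte-identical.

Antisense pairs are deliberately single-exon: a read inside the shared
window is then transcript-compatible with *both* genes, so nothing but
orientation (or policy) can separate them — the cleanest possible class I
instance.  Substitution errors only, so truth CIGARs remain exact.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam

from .io_formats import GeneIndex, ReferenceGenome, sam_header, write_fasta, write_fastq, write_annotation, write_table
from .models import GeneModel, GenomicInterval, TranscriptModel, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    chrom_length: int = 400_000
    n_genes: int = 20
    exons_per_gene: Tuple[int, int] = (2, 5)
    exon_length: Tuple[int, int] = (150, 400)
    intron_length: Tuple[int, int] = (60, 300)
    intergenic_gap: Tuple[int, int] = (600, 1500)
    # class I: overlapping antisense single-exon gene pairs
    n_antisense_pairs: int = 0
    antisense_gene_length: int = 900
    antisense_overlap: int = 400
    antisense_reads_per_gene: int = 20
    # class II: paralogous gene copies
    n_paralog_pairs: int = 0
    paralog_identity: float = 1.0
    # novel splice sites
    n_novel_introns: int = 0
    novel_intron_length: Tuple[int, int] = (80, 200)
    novel_support: int = 3
    novel_anchor: int = 20
    # reads
    reads_per_dataset: Dict[str, int] = field(default_factory=lambda: {"A": 2000})
    read_length: int = 100
    error_rate: float = 0.0
    base_quality: int = 38
    n_lowquality_reads: int = 0
    adapter5: str = ""
    adapter3: str = ""
    antisense_emission_fraction: float = 0.0
    barcodes: Dict[str, str] = field(default_factory=dict)
    oriented: bool = False
    # differential expression between the first and second dataset
    n_de_genes: int = 0
    de_fold: float = 4.0

    def __post_init__(self) -> None:
        if not (0.8 <= self.paralog_identity <= 1.0):
            raise ValueError("paralog identity must lie in [0.8, 1.0]")
        if self.de_fold <= 0:
            raise ValueError("planted folds must be positive")
        if min(self.n_genes, self.n_antisense_pairs, self.n_paralog_pairs,
               self.n_novel_introns, self.novel_support) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_novel_introns > self.n_genes:
            raise ValueError("at most one novel intron is planted per gene")


@dataclass
class Reference:
    genome: Dict[str, str]
    genes: GeneIndex
    novel_introns: Dict[str, GenomicInterval]  # host transcript_id -> locus
    antisense_pairs: List[Tuple[str, str]]
    paralog_pairs: List[Tuple[str, str, int]]  # (source, copy, genomic offset)

    def genome_source(self) -> ReferenceGenome:
        return ReferenceGenome.from_dict(self.genome)


@dataclass
class SimReads:
    fastq: Dict[str, List[tuple]]  # dataset -> [(read_id, bases, quals)]
    sam_records: List[dict]
    truth_reads: List[dict]
    truth_counts: Dict[str, Dict[str, int]]  # dataset -> gene -> reads generated
    truth_junctions: List[dict]
    truth_de: List[dict]


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------


def _plant_intron_motif(genome: np.ndarray, locus: GenomicInterval, strand: str) -> None:
    if strand == "+":
        genome[locus.start : locus.start + 2] = list("GT")
        genome[locus.end - 2 : locus.end] = list("AG")
    else:
        genome[locus.start : locus.start + 2] = list("CT")
        genome[locus.end - 2 : locus.end] = list("AC")


def _build_gene(
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    exon_lengths: List[int],
    intron_lengths: List[int],
    with_cds: bool = True,
) -> GeneModel:
    exons = []
    cursor = start
    for i, elen in enumerate(exon_lengths):
        exons.append(GenomicInterval(chrom, cursor, cursor + elen, strand))
        cursor += elen
        if i < len(intron_lengths):
            cursor += intron_lengths[i]
    spliced = sum(exon_lengths)
    cds = None
    if with_cds and spliced >= 120:
        cds = (spliced // 4, spliced - spliced // 4)
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1", gene_id=gene_id, exons=tuple(exons), cds_span=cds
    )
    span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    return GeneModel(gene_id=gene_id, symbol=gene_id.upper(), span=span, transcripts=(tx,))


def simulate_reference(cfg: SimConfig) -> Reference:
    """Random genome with planted gene structures, deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    genome = rng.choice(_BASES, size=cfg.chrom_length)

    genes: List[GeneModel] = []
    cursor = int(rng.integers(*cfg.intergenic_gap))
    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"g{serial:04d}"

    def advance(span_end: int) -> None:
        nonlocal cursor
        cursor = span_end + int(rng.integers(*cfg.intergenic_gap))
        if cursor >= cfg.chrom_length - 5000:
            raise ValueError("genes requested exceed placeable capacity of the genome")

    # ordinary multi-exon genes
    normal_ids: List[str] = []
    for _ in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lengths = [int(rng.integers(*cfg.exon_length)) for _ in range(n_ex)]
        intron_lengths = [int(rng.integers(*cfg.intron_length)) for _ in range(n_ex - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _build_gene(next_id(), chrom, cursor, strand, exon_lengths, intron_lengths)
        genes.append(gene)
        normal_ids.append(gene.gene_id)
        advance(gene.span.end)

    # antisense pairs: two single-exon genes sharing a window
    antisense_pairs: List[Tuple[str, str]] = []
    for _ in range(cfg.n_antisense_pairs):
        a = _build_gene(next_id(), chrom, cursor, "+", [cfg.antisense_gene_length], [])
        b_start = a.span.end - cfg.antisense_overlap
        b = _build_gene(next_id(), chrom, b_start, "-", [cfg.antisense_gene_length], [])
        genes.extend([a, b])
        antisense_pairs.append((a.gene_id, b.gene_id))
        advance(b.span.end)

    # paralog pairs: a fresh source gene plus a genomic copy
    paralog_pairs: List[Tuple[str, str, int]] = []
    paralog_sources: List[GeneModel] = []
    for _ in range(cfg.n_paralog_pairs):
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lengths = [int(rng.integers(*cfg.exon_length)) for _ in range(n_ex)]
        intron_lengths = [int(rng.integers(*cfg.intron_length)) for _ in range(n_ex - 1)]
        src = _build_gene(next_id(), chrom, cursor, "+", exon_lengths, intron_lengths)
        advance(src.span.end)
        offset = cursor - src.span.start
        copy = _build_gene(next_id(), chrom, cursor, "+", exon_lengths, intron_lengths)
        genes.extend([src, copy])
        paralog_pairs.append((src.gene_id, copy.gene_id, offset))
        paralog_sources.append(src)
        advance(copy.span.end)

    # plant annotated intron motifs
    for gene in genes:
        for tx in gene.transcripts:
            for intron in tx.introns():
                _plant_intron_motif(genome, intron, gene.strand)

    # novel introns: one per host gene, inside the widest exon
    novel: Dict[str, GenomicInterval] = {}
    host_ids = list(normal_ids[: cfg.n_novel_introns])
    gene_by_id = {g.gene_id: g for g in genes}
    for host_id in host_ids:
        tx = gene_by_id[host_id].transcripts[0]
        margin = cfg.novel_anchor + 10
        candidates = [e for e in tx.exons if e.length >= cfg.novel_intron_length[0] + 2 * margin]
        if not candidates:
            raise ValueError(f"gene {host_id}: no exon wide enough for a novel intron")
        exon = max(candidates, key=lambda e: e.length)
        max_len = min(cfg.novel_intron_length[1], exon.length - 2 * margin)
        length = int(rng.integers(cfg.novel_intron_length[0], max_len + 1))
        start = exon.start + margin + int(rng.integers(0, exon.length - 2 * margin - length + 1))
        locus = GenomicInterval(exon.chrom, start, start + length, tx.strand)
        _plant_intron_motif(genome, locus, tx.strand)
        novel[tx.transcript_id] = locus

    # paralog copies: duplicate the (motif-planted) source sequence
    for (src_id, copy_id, offset), src in zip(paralog_pairs, paralog_sources):
        s, e = src.span.start, src.span.end
        segment = genome[s:e].copy()
        if cfg.paralog_identity < 1.0:
            protected = set()
            for intron in src.transcripts[0].introns():
                for p in (intron.start, intron.start + 1, intron.end - 2, intron.end - 1):
                    protected.add(p - s)
            mutate = rng.random(e - s) < (1.0 - cfg.paralog_identity)
            for i in np.flatnonzero(mutate):
                if int(i) in protected:
                    continue
                choices = [b for b in "ACGT" if b != segment[i]]
                segment[i] = choices[int(rng.integers(0, 3))]
        genome[s + offset : e + offset] = segment

    return Reference(
        genome={chrom: "".join(genome)},
        genes=GeneIndex(genes),
        novel_introns=novel,
        antisense_pairs=antisense_pairs,
        paralog_pairs=paralog_pairs,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def transcript_sequence(tx: TranscriptModel, genome: ReferenceGenome) -> str:
    parts = [genome.fetch(e.chrom, e.start, e.end) for e in tx.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if tx.strand == "-" else seq


def _blocks_to_cigar(blocks: List[GenomicInterval]) -> str:
    parts = []
    for i, b in enumerate(blocks):
        if i:
            parts.append(f"{b.start - blocks[i - 1].end}N")
        parts.append(f"{b.length}M")
    return "".join(parts)


def _variant_exons(tx: TranscriptModel, novel: GenomicInterval) -> Tuple[TranscriptModel, int]:
    """Exon chain with ``novel`` excised, plus the junction position in
    variant-transcript coordinates."""
    exons = []
    for e in tx.exons:
        if e.start < novel.start < novel.end < e.end:
            exons.append(GenomicInterval(e.chrom, e.start, novel.start, e.strand))
            exons.append(GenomicInterval(e.chrom, novel.end, e.end, e.strand))
        else:
            exons.append(e)
    variant = TranscriptModel(
        transcript_id=tx.transcript_id + ".v", gene_id=tx.gene_id, exons=tuple(exons)
    )
    if variant.strand == "+":
        junction = sum(e.length for e in exons if e.end <= novel.start)
    else:
        junction = sum(e.length for e in exons if e.start >= novel.end)
    return variant, junction


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> Tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr), len(hits)


def simulate_reads(ref: Reference, cfg: SimConfig) -> SimReads:
    """Sample reads from mature transcripts, with truth alignments.

    Expression reads come from the ordinary (and paralogous) genes with
    per-gene weights (the first ``n_de_genes`` ordinary genes are
    up-weighted ``de_fold``-fold in the first dataset); antisense-pair
    genes receive dedicated reads from the shared window; each novel
    intron receives ``novel_support`` junction-spanning reads in the
    first dataset.  Reads from identity-1.0 paralog pairs carry two
    alignment records (NH=2) — one per homologous locus.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genome = ref.genome_source()
    datasets = list(cfg.reads_per_dataset)
    gene_by_id = {g.gene_id: g for g in ref.genes}
    antisense_ids = {g for pair in ref.antisense_pairs for g in pair}
    paralog_partner = {}
    paralog_offset = {}
    for src, copy, offset in ref.paralog_pairs:
        if cfg.paralog_identity == 1.0:
            paralog_partner[src], paralog_partner[copy] = copy, src
            paralog_offset[src], paralog_offset[copy] = offset, -offset

    expr_genes = [g.gene_id for g in ref.genes if g.gene_id not in antisense_ids]
    tx_seqs = {
        g.gene_id: transcript_sequence(gene_by_id[g.gene_id].transcripts[0], genome)
        for g in ref.genes
    }

    de_genes = expr_genes[: cfg.n_de_genes]
    fastq: Dict[str, List[tuple]] = {d: [] for d in datasets}
    sam_records: List[dict] = []
    truth_reads: List[dict] = []
    truth_counts: Dict[str, Dict[str, int]] = {d: {} for d in datasets}
    serial = 0

    def emit(
        dataset: str,
        category: str,
        tx: TranscriptModel,
        t_start: int,
        expected_tag: str,
        novel_key: str = "",
        variant_of: Optional[TranscriptModel] = None,
    ) -> None:
        nonlocal serial
        serial += 1
        read_id = f"{dataset}_{category}_{serial:06d}"
        mature = tx_seqs.get(tx.gene_id) if variant_of is None else transcript_sequence(tx, genome)
        insert = mature[t_start : t_start + cfg.read_length]
        insert, n_err = _apply_errors(insert, rng, cfg.error_rate)
        blocks = tx.genomic_blocks_for(t_start, t_start + cfg.read_length)
        sam_records.append(
            {
                "read_id": read_id,
                "chrom": tx.chrom,
                "pos": blocks[0].start,
                "cigar": _blocks_to_cigar(blocks),
                "is_reverse": tx.strand == "-",
                "seq": insert if tx.strand == "+" else reverse_complement(insert),
                "nm": n_err,
                "gene_id": tx.gene_id,
            }
        )
        gene = gene_by_id.get(tx.gene_id) or gene_by_id[variant_of.gene_id]
        partner = paralog_partner.get(gene.gene_id)
        n_hits = 1
        if partner is not None:
            n_hits = 2
            off = paralog_offset[gene.gene_id]
            shifted = [
                GenomicInterval(b.chrom, b.start + off, b.end + off, b.strand) for b in blocks
            ]
            sam_records.append(
                {
                    "read_id": read_id,
                    "chrom": tx.chrom,
                    "pos": shifted[0].start,
                    "cigar": _blocks_to_cigar(shifted),
                    "is_reverse": tx.strand == "-",
                    "seq": insert if tx.strand == "+" else reverse_complement(insert),
                    "nm": n_err,
                    "gene_id": partner,
                    "secondary": True,
                }
            )
        sam_records[-1 - (n_hits - 1)]["n_hits"] = n_hits
        if partner is not None:
            sam_records[-1]["n_hits"] = n_hits

        payload = cfg.adapter5 + insert + cfg.adapter3
        if cfg.antisense_emission_fraction > 0 and rng.random() < cfg.antisense_emission_fraction:
            payload = reverse_complement(payload)
        payload = cfg.barcodes.get(dataset, "") + payload
        fastq[dataset].append((read_id, payload, [cfg.base_quality] * len(payload)))
        truth_reads.append(
            {
                "read_id": read_id,
                "dataset": dataset,
                "gene_id": gene.gene_id,
                "transcript_id": tx.transcript_id,
                "expected_tag": expected_tag,
                "strand": tx.strand,
                "category": category,
                "novel_intron": novel_key,
            }
        )
        truth_counts[dataset][gene.gene_id] = truth_counts[dataset].get(gene.gene_id, 0) + 1

    # expression reads
    for d_index, dataset in enumerate(datasets):
        n = cfg.reads_per_dataset[dataset]
        if expr_genes and n > 0:
            weights = np.array(
                [
                    cfg.de_fold if (g in de_genes and d_index == 0) else 1.0
                    for g in expr_genes
                ]
            )
            probs = weights / weights.sum()
            choices = rng.choice(len(expr_genes), size=n, p=probs)
            for gi in choices:
                gene = gene_by_id[expr_genes[int(gi)]]
                tx = gene.transcripts[0]
                span = tx.spliced_length - cfg.read_length
                if span < 0:
                    raise ValueError(
                        f"read length {cfg.read_length} exceeds transcript "
                        f"{tx.transcript_id} ({tx.spliced_length} nt)"
                    )
                t_start = int(rng.integers(0, span + 1))
                emit(dataset, "expr", tx, t_start, "T")

    # antisense window reads
    for dataset in datasets:
        for a_id, b_id in ref.antisense_pairs:
            a, b = gene_by_id[a_id], gene_by_id[b_id]
            lo, hi = b.span.start, a.span.end  # the shared window
            for gene in (a, b):
                tx = gene.transcripts[0]
                for _ in range(cfg.antisense_reads_per_gene):
                    g_start = int(rng.integers(lo, hi - cfg.read_length + 1))
                    if tx.strand == "+":
                        t_start = g_start - tx.start
                    else:
                        t_start = tx.end - (g_start + cfg.read_length)
                    emit(dataset, "anti", tx, t_start, "T")

    # novel intron junction reads (first dataset)
    if ref.novel_introns and datasets:
        dataset = datasets[0]
        for tx_id, locus in sorted(ref.novel_introns.items()):
            host_gene = tx_id.rsplit(".", 1)[0]
            tx = gene_by_id[host_gene].transcripts[0]
            variant, junction = _variant_exons(tx, locus)
            for _ in range(cfg.novel_support):
                lo = max(0, junction - (cfg.read_length - cfg.novel_anchor))
                hi = min(variant.spliced_length - cfg.read_length, junction - cfg.novel_anchor)
                t_start = int(rng.integers(lo, hi + 1))
                emit(
                    dataset,
                    "novel",
                    variant,
                    t_start,
                    "G",
                    novel_key=f"{locus.chrom}:{locus.start}-{locus.end}",
                    variant_of=tx,
                )

    # low-quality reads: rejected at the trimming step, never aligned
    for dataset in datasets:
        for _ in range(cfg.n_lowquality_reads):
            serial += 1
            read_id = f"{dataset}_lowq_{serial:06d}"
            bases = cfg.barcodes.get(dataset, "") + "".join(
                rng.choice(_BASES, size=cfg.read_length)
            )
            fastq[dataset].append((read_id, bases, [2] * len(bases)))
            truth_reads.append(
                {
                    "read_id": read_id,
                    "dataset": dataset,
                    "gene_id": "",
                    "transcript_id": "",
                    "expected_tag": "rejected",
                    "strand": "?",
                    "category": "lowq",
                    "novel_intron": "",
                }
            )

    truth_junctions = [
        {
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
            "strand": locus.strand,
            "transcript_id": tx_id,
            "gene_id": tx_id.rsplit(".", 1)[0],
            "support": cfg.novel_support,
        }
        for tx_id, locus in sorted(ref.novel_introns.items())
    ]
    truth_de = [{"gene_id": g, "fold": cfg.de_fold} for g in de_genes]
    return SimReads(fastq, sam_records, truth_reads, truth_counts, truth_junctions, truth_de)


# ---------------------------------------------------------------------------
# Count-level DE simulation
# ---------------------------------------------------------------------------


def simulate_de_counts(
    rng: np.random.Generator,
    n_planted: int = 10,
    planted_ref: float = 100.0,
    planted_other: float = 25.0,
    n_null: int = 200,
    null_expected: float = 20.0,
    total: int = 100_000,
) -> Tuple[Dict[str, int], Dict[str, int], List[str], List[str]]:
    """Multinomial per-gene counts for a two-dataset DE experiment.

    Planted genes have expected counts ``planted_ref`` vs
    ``planted_other`` (a fold in reads-per-million of their ratio given
    equal totals); null genes have ``null_expected`` in both.  The
    remaining probability mass goes to an unreported background bucket so
    each dataset's mapped total is exactly ``total``.
    """
    planted = [f"de{i:03d}" for i in range(n_planted)]
    nulls = [f"null{i:03d}" for i in range(n_null)]

    def draw(expected_planted: float) -> Dict[str, int]:
        probs = [expected_planted / total] * n_planted + [null_expected / total] * n_null
        background = 1.0 - sum(probs)
        if background < 0:
            raise ValueError("expected counts exceed the dataset total")
        counts = rng.multinomial(total, probs + [background])
        return dict(zip(planted + nulls, counts[:-1].tolist()))

    return draw(planted_ref), draw(planted_other), planted, nulls


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_outputs(ref: Reference, reads: SimReads, outdir: str) -> Dict[str, str]:
    """Write genome.fa, genes.gff, per-dataset FASTQ, truth.sam and truth tables."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    paths["genome"] = os.path.join(outdir, "genome.fa")
    write_fasta(ref.genome, paths["genome"])
    paths["annotation"] = os.path.join(outdir, "genes.gff")
    write_annotation(ref.genes, paths["annotation"])
    for dataset, records in reads.fastq.items():
        p = os.path.join(outdir, f"reads_{dataset}.fastq")
        write_fastq(records, p)
        paths[f"fastq_{dataset}"] = p

    paths["sam"] = os.path.join(outdir, "truth.sam")
    header = sam_header({c: len(s) for c, s in ref.genome.items()})
    with pysam.AlignmentFile(paths["sam"], "w", header=header) as out:
        for rec in reads.sam_records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec["read_id"]
            a.reference_name = rec["chrom"]
            a.reference_start = rec["pos"]
            a.cigarstring = rec["cigar"]
            a.query_sequence = rec["seq"]
            a.mapping_quality = 60
            a.flag = (16 if rec["is_reverse"] else 0) | (256 if rec.get("secondary") else 0)
            a.set_tag("NM", rec["nm"])
            a.set_tag("NH", rec.get("n_hits", 1))
            out.write(a)

    paths["truth_reads"] = os.path.join(outdir, "truth_reads.tsv")
    cols = ["read_id", "dataset", "gene_id", "transcript_id", "expected_tag", "strand", "category", "novel_intron"]
    write_table(reads.truth_reads, cols, paths["truth_reads"])

    paths["truth_counts"] = os.path.join(outdir, "truth_counts.tsv")
    count_rows = [
        {"dataset": d, "gene_id": g, "reads": n}
        for d in sorted(reads.truth_counts)
        for g, n in sorted(reads.truth_counts[d].items())
    ]
    write_table(count_rows, ["dataset", "gene_id", "reads"], paths["truth_counts"])

    paths["truth_junctions"] = os.path.join(outdir, "truth_junctions.tsv")
    write_table(
        reads.truth_junctions,
        ["chrom", "start", "end", "strand", "transcript_id", "gene_id", "support"],
        paths["truth_junctions"],
    )
    paths["truth_de"] = os.path.join(outdir, "truth_de.tsv")
    write_table(reads.truth_de, ["gene_id", "fold"], paths["truth_de"])
    return paths


def split_hits_by_dataset(
    truth_reads: List[dict], hits_by_read: Dict[str, list]
) -> Dict[str, Dict[str, list]]:
    """Partition SAM hits per dataset using the truth read table."""
    out: Dict[str, Dict[str, list]] = {}
    for row in truth_reads:
        rid = row["read_id"]
        if rid in hits_by_read:
            out.setdefault(row["dataset"], {})[rid] = hits_by_read[rid]
    return out


def simulate(cfg: SimConfig, outdir: Optional[str] = None):
    """Convenience: reference + reads (+ files when ``outdir`` given)."""
    ref = simulate_reference(cfg)
    reads = simulate_reads(ref, cfg)
    if outdir is not None:
        write_outputs(ref, reads, outdir)
    return ref, reads
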