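"""End-to-end pipeline: preprocess -> filter -> assign -> splice -> express.

A single configuration mapping drives the whole run; every stage writes
its outputs before the next starts, and a machine-readable run report
(TSV + JSON) mirrors the per-stage read accounting.  The report asserts
read conservation: every input read ends in exactly one terminal bucket.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from . import __version__
from .assign import AssignParams, AssignResult, assign_dataset
from .express import de_scan, gene_metrics, locate_on_transcript
from .io_formats import (
    GeneIndex,
    ReferenceGenome,
    load_annotation,
    read_fastq,
    read_sam,
    write_fastq,
    write_table,
)
from .map_filter import FilterParams, filter_hits
from .preprocess import AdapterSpec, BarcodeSpec, RawRead, demultiplex, strip_and_orient, trim_low_quality
from .splice import collect_introns, filter_introns, write_intron_table

log = logging.getLogger(__name__)

DEFAULT_PARAMS: Dict[str, object] = {
    "qcut": 20,
    "min_len": 30,
    "adapter5": "",
    "adapter3": "",
    "adapter_mismatches": 1,
    "barcode_mismatches": 0,
    "min_overlap": 70.0,
    "min_similarity": 96.0,
    "max_hits": 10,
    "flank": 1000,
    "min_genic_overlap": 1,
    "ext_threshold": 50,
    "ambiguity": "assign_both",
    "count_confidence": "TG",
    "min_support": 1,
    "canonical_only": False,
    "alpha": 0.05,
    "reference_dataset": None,
}


@dataclass
class RunReport:
    """Per-dataset read accounting plus a full parameter echo."""

    params: Dict[str, object]
    version: str = __version__
    started: float = 0.0
    finished: float = 0.0
    datasets: Dict[str, Dict[str, int]] = field(default_factory=dict)
    global_counts: Dict[str, int] = field(default_factory=dict)
    failed_stage: Optional[str] = None

    def check_conservation(self) -> None:
        """Input reads must equal the sum over terminal buckets."""
        for dataset, c in self.datasets.items():
            terminal = (
                c["rejected_quality"]
                + c["unmapped"]
                + c["rejected_overlap"]
                + c["rejected_similarity"]
                + c["rejected_hits"]
                + c["extragenic"]
                + c["discarded_ambiguous"]
                + c["assigned_unique"]
                + c["assigned_resolved"]
                + c["shared"]
            )
            if terminal != c["total_reads"]:
                raise AssertionError(
                    f"dataset {dataset}: {c['total_reads']} input reads but "
                    f"{terminal} across terminal buckets"
                )

    def to_json(self, path: str) -> None:
        payload = {
            "version": self.version,
            "started": self.started,
            "finished": self.finished,
            "params": self.params,
            "global": self.global_counts,
            "datasets": self.datasets,
            "failed_stage": self.failed_stage,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str) -> None:
        rows = []
        for key, value in sorted(self.global_counts.items()):
            rows.append({"dataset": "*", "statistic": key, "value": value})
        for dataset in sorted(self.datasets):
            for key, value in sorted(self.datasets[dataset].items()):
                rows.append({"dataset": dataset, "statistic": key, "value": value})
        for key, value in sorted(self.params.items()):
            rows.append({"dataset": "*", "statistic": f"param:{key}", "value": value})
        write_table(rows, ["dataset", "statistic", "value"], path)


def _merged_params(config: Dict) -> Dict[str, object]:
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    return params


def run_pipeline(config: Dict, outdir: str) -> RunReport:
    """Run every stage on the inputs named in ``config``.

    Expected keys: ``genome`` (FASTA), ``annotation`` (GFF/GTF),
    ``alignments`` (SAM covering all datasets' reads), and either
    ``reads`` (dataset_id -> FASTQ path) or ``multiplexed_reads`` (one
    FASTQ) with ``params.barcodes`` (dataset_id -> barcode).
    """
    started = time.time()
    params = _merged_params(config)
    for key in ("genome", "annotation", "alignments"):
        if key not in config:
            raise ValueError(f"config is missing required input {key!r}")
        if not os.path.exists(str(config[key])):
            raise FileNotFoundError(f"{key} file not found: {config[key]}")
    if "reads" not in config and "multiplexed_reads" not in config:
        raise ValueError("config must name 'reads' or 'multiplexed_reads'")

    os.makedirs(outdir, exist_ok=True)
    report = RunReport(params=params, started=started)

    # ------------------------------------------------------------------ load
    genome = ReferenceGenome.from_fasta(str(config["genome"]))
    genes = load_annotation(str(config["annotation"]))
    annotated_introns = genes.annotated_introns()
    all_hits = read_sam(str(config["alignments"]))

    # ------------------------------------------------------------ preprocess
    log.info("stage=preprocess start")
    raw_per_dataset: Dict[str, List[RawRead]] = {}
    if "reads" in config:
        for dataset, path in config["reads"].items():
            raw_per_dataset[dataset] = [
                RawRead(rid, bases, quals) for rid, bases, quals in read_fastq(path)
            ]
        report.global_counts["unassigned_barcode"] = 0
    else:
        raw = [
            RawRead(rid, bases, quals)
            for rid, bases, quals in read_fastq(str(config["multiplexed_reads"]))
        ]
        barcodes = params.get("barcodes") or config.get("barcodes")
        if not barcodes:
            raise ValueError("multiplexed input requires a barcode table")
        bins, unassigned = demultiplex(
            raw, BarcodeSpec(dict(barcodes)), int(params["barcode_mismatches"])
        )
        raw_per_dataset = bins
        report.global_counts["unassigned_barcode"] = len(unassigned)
        report.global_counts["multiplexed_total"] = len(raw)

    adapters = None
    if params["adapter5"] or params["adapter3"]:
        adapters = AdapterSpec(
            five_prime=str(params["adapter5"]),
            three_prime=str(params["adapter3"]),
            max_mismatches=int(params["adapter_mismatches"]),
        )

    processed: Dict[str, Dict[str, RawRead]] = {}
    orientation: Dict[str, Dict[str, str]] = {}
    for dataset, raws in sorted(raw_per_dataset.items()):
        counts = {
            "total_reads": len(raws),
            "rejected_quality": 0,
            "processed_reads": 0,
        }
        kept: Dict[str, RawRead] = {}
        oriented: Dict[str, str] = {}
        for read in raws:
            if adapters is not None:
                read, is_oriented, strand = strip_and_orient(read, adapters)
                if is_oriented:
                    oriented[read.read_id] = strand
            trimmed, reason = trim_low_quality(
                read, float(params["qcut"]), int(params["min_len"])
            )
            if trimmed is None:
                counts["rejected_quality"] += 1
            else:
                kept[trimmed.read_id] = trimmed
        counts["processed_reads"] = len(kept)
        processed[dataset] = kept
        orientation[dataset] = oriented
        report.datasets[dataset] = counts
        write_fastq(
            ((r.read_id, r.bases, r.quals or [2] * len(r.bases)) for r in kept.values()),
            os.path.join(outdir, f"processed_{dataset}.fastq"),
        )

    # ---------------------------------------------------------------- filter
    log.info("stage=filter start")
    fparams = FilterParams(
        min_overlap=float(params["min_overlap"]),
        min_similarity=float(params["min_similarity"]),
        max_hits=int(params["max_hits"]),
    )
    kept_hits: Dict[str, Dict[str, list]] = {}
    for dataset, reads in processed.items():
        c = report.datasets[dataset]
        hits = {rid: all_hits[rid] for rid in reads if rid in all_hits}
        c["unmapped"] = len(reads) - len(hits)
        c["mapped_reads"] = len(hits)
        for rid, rhits in hits.items():
            strand = orientation[dataset].get(rid)
            if strand is not None:
                for h in rhits:
                    h.oriented = True
        kept, fcounts = filter_hits(hits, fparams)
        c.update(fcounts)
        c["filtered_reads"] = fcounts["accepted"]
        kept_hits[dataset] = kept
        rows = [{"statistic": k, "value": v} for k, v in sorted(fcounts.items())]
        write_table(rows, ["statistic", "value"], os.path.join(outdir, f"filter_{dataset}.tsv"))

    # ---------------------------------------------------------------- assign
    log.info("stage=assign start")
    aparams = AssignParams(
        flank_a=int(params["flank"]),
        min_genic_overlap_b=int(params["min_genic_overlap"]),
        ext_threshold=int(params["ext_threshold"]),
        ambiguity_policy=str(params["ambiguity"]),
    )
    results: Dict[str, AssignResult] = {}
    for dataset, hits in kept_hits.items():
        result = assign_dataset(hits, genes, aparams, genome, annotated_introns)
        results[dataset] = result
        report.datasets[dataset].update(result.counts())
        rows = [
            {
                "read_id": a.read_id,
                "gene_id": a.gene_id,
                "confidence": a.confidence,
                "ambiguity_class": ",".join(sorted(a.ambiguity_class)) or ".",
                "status": a.status,
            }
            for a in result.assignments
        ]
        write_table(
            rows,
            ["read_id", "gene_id", "confidence", "ambiguity_class", "status"],
            os.path.join(outdir, f"assignments_{dataset}.tsv"),
        )
        tags = {a.read_id: a.confidence for a in result.assignments}
        report.datasets[dataset]["genic"] = sum(1 for t in tags.values() if t in "TG")
        report.datasets[dataset]["classified_T"] = sum(1 for t in tags.values() if t == "T")
        report.datasets[dataset]["identified_genes"] = len(
            {a.gene_id for a in result.assignments}
        )

    # ---------------------------------------------------------------- splice
    log.info("stage=splice start")
    dataset_ids = sorted(kept_hits)
    observations = collect_introns(
        {d: (kept_hits[d], results[d]) for d in dataset_ids},
        genome,
        genes,
        annotated_introns,
    )
    observations = filter_introns(
        observations,
        min_support=int(params["min_support"]),
        canonical_only=bool(params["canonical_only"]),
    )
    write_intron_table(observations, dataset_ids, os.path.join(outdir, "introns.tsv"))
    novel = [o for o in observations if not o.annotated]
    report.global_counts["novel_introns"] = len(novel)
    report.global_counts["annotated_introns_observed"] = len(observations) - len(novel)

    # --------------------------------------------------------------- express
    log.info("stage=express start")
    confidences = str(params["count_confidence"])
    metrics_rows = []
    metrics_by_dataset: Dict[str, Dict[str, object]] = {}
    gene_counts: Dict[str, Dict[str, int]] = {}
    for dataset in dataset_ids:
        per_gene: Dict[str, object] = {}
        counts: Dict[str, int] = {}
        by_gene: Dict[str, list] = {}
        for a in results[dataset].assignments:
            if a.confidence in confidences:
                by_gene.setdefault(a.gene_id, []).append(a.read_id)
        for gene_id, read_ids in sorted(by_gene.items()):
            reads = [h for rid in set(read_ids) for h in kept_hits[dataset][rid]]
            m = gene_metrics(gene_id, dataset, reads)
            if m is not None:
                per_gene[gene_id] = m
                counts[gene_id] = m.coverage
                metrics_rows.append(
                    {
                        "dataset": dataset,
                        "gene_id": gene_id,
                        "coverage": m.coverage,
                        "depth": m.depth,
                        "focusing_index": f"{m.focusing_index:.6g}",
                    }
                )
        metrics_by_dataset[dataset] = per_gene
        gene_counts[dataset] = counts
    write_table(
        metrics_rows,
        ["dataset", "gene_id", "coverage", "depth", "focusing_index"],
        os.path.join(outdir, "gene_metrics.tsv"),
    )

    reference = params.get("reference_dataset") or (dataset_ids[0] if dataset_ids else None)
    de_gene_count = 0
    if len(dataset_ids) >= 2:
        totals = {d: report.datasets[d]["mapped_reads"] for d in dataset_ids}
        others = [d for d in dataset_ids if d != reference]
        gene_rows, intron_rows = [], []
        for other in others:
            gres = de_scan(gene_counts[reference], gene_counts[other], totals[reference], totals[other])
            intron_ref = {f"{o.locus.chrom}:{o.locus.start}-{o.locus.end}": o.support.get(reference, 0) for o in observations}
            intron_oth = {f"{o.locus.chrom}:{o.locus.start}-{o.locus.end}": o.support.get(other, 0) for o in observations}
            ires = de_scan(intron_ref, intron_oth, totals[reference], totals[other])
            for res, rows in ((gres, gene_rows), (ires, intron_rows)):
                for r in res:
                    rows.append(
                        {
                            "comparison": f"{reference}_vs_{other}",
                            "feature_id": r.feature_id,
                            "count_ref": r.count_ref,
                            "count_other": r.count_other,
                            "fold_change": f"{r.fold_change:.6g}",
                            "p_value": f"{r.p_value:.6g}",
                            "q_value": f"{r.q_value:.6g}",
                            "direction": r.direction,
                        }
                    )
            de_gene_count += sum(1 for r in gres if r.q_value < float(params["alpha"]))
        cols = ["comparison", "feature_id", "count_ref", "count_other", "fold_change", "p_value", "q_value", "direction"]
        write_table(gene_rows, cols, os.path.join(outdir, "de_genes.tsv"))
        write_table(intron_rows, cols, os.path.join(outdir, "de_introns.tsv"))
    report.global_counts["de_genes_at_alpha"] = de_gene_count

    # CDS/UTR positioning of T reads
    position_rows = []
    for dataset in dataset_ids:
        t_reads = [a for a in results[dataset].assignments if a.confidence == "T"]
        for a in t_reads:
            gene = genes.genes[a.gene_id]
            for hit in kept_hits[dataset][a.read_id]:
                tx_hit = next(
                    (
                        tx
                        for tx in gene.transcripts
                        if _compatible(hit, tx, int(params["ext_threshold"]))
                    ),
                    None,
                )
                if tx_hit is None:
                    continue
                breakdown = locate_on_transcript(hit.blocks, tx_hit)
                position_rows.append(
                    {
                        "dataset": dataset,
                        "read_id": a.read_id,
                        "transcript_id": tx_hit.transcript_id,
                        **breakdown,
                    }
                )
                break
    write_table(
        position_rows,
        ["dataset", "read_id", "transcript_id", "utr5", "cds", "utr3", "noncoding"],
        os.path.join(outdir, "transcript_position.tsv"),
    )
    report.global_counts["identified_transcripts"] = len(
        {r["transcript_id"] for r in position_rows}
    )

    report.finished = time.time()
    report.check_conservation()
    report.to_json(os.path.join(outdir, "report.json"))
    report.to_tsv(os.path.join(outdir, "report.tsv"))
    return report


def _compatible(hit, tx, ext_threshold: int) -> bool:
    from .assign import is_transcript_compatible

    return is_transcript_compatible(hit.blocks, tx, ext_threshold)
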