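"""Gene-level expression indices and pairwise differential expression.

Three per-gene indices are reported per dataset: *coverage* (number of
reads assigned to the gene), *depth* (maximum number of assigned reads
covering any single genic position) and the *focusing index* (depth /
coverage; values near 1 flag repeat-like read pile-ups, values near 0 an
even spread along the gene).

Differential representation between two datasets — of genes and of
introns alike — is assessed with a two-sided Fisher exact test on the
2x2 table of (feature count, remaining mapped reads) per dataset, i.e.
raw counts normalized only through the margins by the total number of
genome-mapped reads.  The two-sided p-value uses the minimum-likelihood
convention: the sum of the probabilities of all tables in the support
that are no more probable than the observed one, under the
hypergeometric null.  It is computed in exact integer arithmetic.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from scipy import stats as _scipy_stats

from .models import AlignedRead, DEResult, GeneMetrics, TranscriptModel

# ---------------------------------------------------------------------------
# Expression indices
# ---------------------------------------------------------------------------


def gene_metrics(
    gene_id: str, dataset_id: str, reads: Sequence[AlignedRead]
) -> Optional[GeneMetrics]:
    """Coverage / depth / focusing index for one gene in one dataset.

    Depth counts *reads* per genomic position: a spliced read covers only
    its exonic blocks, and one read never counts twice at a position.
    Returns ``None`` for uncovered genes (indices undefined).
    """
    if not reads:
        return None
    events: Dict[int, int] = {}
    for read in reads:
        for block in read.blocks:
            events[block.start] = events.get(block.start, 0) + 1
            events[block.end] = events.get(block.end, 0) - 1
    depth = 0
    running = 0
    for pos in sorted(events):
        running += events[pos]
        depth = max(depth, running)
    return GeneMetrics(
        gene_id=gene_id, dataset_id=dataset_id, coverage=len(reads), depth=depth
    )


# ---------------------------------------------------------------------------
# Fisher exact test (two-sided, exact integer arithmetic)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=200_000)
def _comb(n: int, k: int) -> int:
    return comb(n, k)


def fisher_two_sided(c1: int, t1: int, c2: int, t2: int) -> float:
    """Two-sided Fisher exact p for the table [[c1, t1-c1], [c2, t2-c2]].

    Exact: table probabilities are compared as integers (the common
    denominator C(t1+t2, c1+c2) cancels), and the final ratio is a single
    correctly rounded integer division.
    """
    if not (0 <= c1 <= t1 and 0 <= c2 <= t2) or t1 < 1 or t2 < 1:
        raise ValueError("counts must satisfy 0 <= count <= total, totals >= 1")
    k = c1 + c2
    lo = max(0, k - t2)
    hi = min(k, t1)
    n_obs = _comb(t1, c1) * _comb(t2, c2)
    num = 0
    for a in range(lo, hi + 1):
        n_a = _comb(t1, a) * _comb(t2, k - a)
        if n_a <= n_obs:
            num += n_a
    return num / _comb(t1 + t2, k)


def fold_change(c_ref: int, t_ref: int, c_other: int, t_other: int) -> float:
    """RPM-scale fold change with zero-to-one replacement on raw counts."""
    return (max(c_ref, 1) / t_ref) / (max(c_other, 1) / t_other)


def fisher_de(
    count_ref: int, total_ref: int, count_other: int, total_other: int
) -> Tuple[float, float]:
    """(two-sided p, fold change) for one feature between two datasets."""
    if count_ref > total_ref or count_other > total_other:
        raise ValueError("feature count exceeds dataset total")
    p = fisher_two_sided(count_ref, total_ref, count_other, total_other)
    return p, fold_change(count_ref, total_ref, count_other, total_other)


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    if len(pvalues) == 0:
        return []
    adjusted = _scipy_stats.false_discovery_control(pvalues, method="bh")
    return [float(q) for q in adjusted]


def de_scan(
    counts_ref: Dict[str, int],
    counts_other: Dict[str, int],
    total_ref: int,
    total_other: int,
) -> List[DEResult]:
    """Fisher-test every feature with a nonzero count in either dataset.

    BH adjustment runs over the scanned family only, so gene scans and
    intron scans must be adjusted separately (call once per family).
    Results come back sorted by raw p, ties by feature id.
    """
    if total_ref < 1 or total_other < 1:
        raise ValueError("dataset totals must be >= 1")
    features = sorted(set(counts_ref) | set(counts_other))
    rows = []
    for fid in features:
        c1 = counts_ref.get(fid, 0)
        c2 = counts_other.get(fid, 0)
        if c1 == 0 and c2 == 0:
            continue
        p, fc = fisher_de(c1, total_ref, c2, total_other)
        rows.append((fid, c1, c2, p, fc))
    qvals = bh_adjust([r[3] for r in rows])
    results = [
        DEResult(
            feature_id=fid,
            count_ref=c1,
            count_other=c2,
            total_ref=total_ref,
            total_other=total_other,
            fold_change=fc,
            p_value=p,
            q_value=q,
        )
        for (fid, c1, c2, p, fc), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.feature_id))
    return results


# ---------------------------------------------------------------------------
# Ranking queries
# ---------------------------------------------------------------------------

_INDEX_NAMES = ("coverage", "depth", "focusing_index")


def rank_genes(
    metrics: Dict[str, Dict[str, GeneMetrics]],
    criteria: Optional[Dict[str, Tuple[Optional[float], Optional[float]]]] = None,
    combine: str = "union",
    rank_by: str = "coverage",
) -> List[str]:
    """Filter and rank genes across datasets.

    ``metrics`` maps dataset_id -> gene_id -> GeneMetrics.  ``criteria``
    maps an index name to (min, max) bounds (either side may be None); a
    gene passes in a dataset when it is covered there and every bound
    holds.  ``combine="intersection"`` requires passing in all datasets,
    ``"union"`` in at least one.  Ranking is by the chosen index's best
    value across passing datasets, descending, ties by gene_id.
    """
    if rank_by not in _INDEX_NAMES:
        raise ValueError(f"unknown index {rank_by!r}; expected one of {_INDEX_NAMES}")
    for name in criteria or {}:
        if name not in _INDEX_NAMES:
            raise ValueError(f"unknown index {name!r} in criteria")
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")

    def passes(m: GeneMetrics) -> bool:
        for name, (lo, hi) in (criteria or {}).items():
            value = getattr(m, name)
            if lo is not None and value < lo:
                return False
            if hi is not None and value > hi:
                return False
        return True

    all_genes = sorted({g for per in metrics.values() for g in per})
    chosen = []
    for gene_id in all_genes:
        passing = [
            per[gene_id] for per in metrics.values() if gene_id in per and passes(per[gene_id])
        ]
        n_datasets = len(metrics)
        ok = (
            len(passing) == n_datasets if combine == "intersection" else len(passing) >= 1
        )
        if ok and passing:
            best = max(getattr(m, rank_by) for m in passing)
            chosen.append((gene_id, best))
    chosen.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in chosen]


# ---------------------------------------------------------------------------
# CDS / UTR positioning
# ---------------------------------------------------------------------------


def locate_on_transcript(
    read_blocks: Sequence, tx: TranscriptModel
) -> Dict[str, int]:
    """Partition a T-read's aligned bases among 5'UTR, CDS and 3'UTR.

    Read blocks are projected to transcript coordinates (terminal
    overhangs beyond the transcript are clipped away).  Transcripts with
    no CDS report every base as ``noncoding``.
    """
    pieces: List[Tuple[int, int]] = []
    for block in read_blocks:
        pieces.extend(tx.transcript_intervals_for(block))
    total = sum(b - a for a, b in pieces)
    if tx.cds_span is None:
        return {"utr5": 0, "cds": 0, "utr3": 0, "noncoding": total}
    cds_start, cds_end = tx.cds_span
    out = {"utr5": 0, "cds": 0, "utr3": 0, "noncoding": 0}
    for a, b in pieces:
        out["utr5"] += max(0, min(b, cds_start) - a)
        out["cds"] += max(0, min(b, cds_end) - max(a, cds_start))
        out["utr3"] += max(0, b - max(a, cds_end))
    return out
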