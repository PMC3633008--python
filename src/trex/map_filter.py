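"""Mapping-quality gate applied to aligned reads before annotation.

Three thresholds, checked in this fixed order: minimum overlap (percent
of the read length aligned), minimum similarity (percent of aligned bases
identical) and maximum number of genomic hits.  A rejected alignment
names the first failing criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .models import AlignedRead


@dataclass
class FilterParams:
    min_overlap: float = 70.0
    min_similarity: float = 96.0
    max_hits: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap <= 100):
            raise ValueError("min_overlap must be in (0, 100]")
        if not (0 < self.min_similarity <= 100):
            raise ValueError("min_similarity must be in (0, 100]")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


def alignment_metrics(aln: AlignedRead) -> Tuple[float, float]:
    """(overlap %, similarity %) of one alignment.

    overlap = 100 * aligned_bases / read_length;
    similarity = 100 * matches / aligned_bases.
    """
    if aln.read_length <= 0:
        raise ValueError(f"read {aln.read_id}: non-positive read length")
    if aln.aligned_bases <= 0:
        raise ValueError(f"read {aln.read_id}: similarity undefined (0 aligned bases)")
    return (
        100.0 * aln.aligned_bases / aln.read_length,
        100.0 * aln.matches / aln.aligned_bases,
    )


def passes_filter(aln: AlignedRead, params: FilterParams) -> Optional[str]:
    """``None`` when the alignment passes, else the first failing criterion
    among ``overlap``, ``similarity``, ``hits`` (in that order)."""
    overlap, similarity = alignment_metrics(aln)
    if overlap < params.min_overlap:
        return "overlap"
    if similarity < params.min_similarity:
        return "similarity"
    if aln.n_hits > params.max_hits:
        return "hits"
    return None


def filter_hits(
    hits_by_read: Dict[str, List[AlignedRead]], params: FilterParams
) -> Tuple[Dict[str, List[AlignedRead]], Dict[str, int]]:
    """Apply the gate to every hit of every read.

    All passing hits of a read are forwarded together — multi-hit reads
    are never reduced to a "best" hit here; downstream ambiguity
    resolution owns that decision.  A read whose hits all fail is dropped
    and counted once under its first hit's rejection reason.

    Returns (kept hits per read, counts: accepted / rejected_overlap /
    rejected_similarity / rejected_hits — read-level, each read counted
    exactly once).
    """
    kept: Dict[str, List[AlignedRead]] = {}
    counts = {
        "accepted": 0,
        "rejected_overlap": 0,
        "rejected_similarity": 0,
        "rejected_hits": 0,
    }
    for read_id, hits in hits_by_read.items():
        survivors = []
        reasons = []
        for hit in hits:
            reason = passes_filter(hit, params)
            if reason is None:
                survivors.append(hit)
            else:
                reasons.append(reason)
        if survivors:
            kept[read_id] = survivors
            counts["accepted"] += 1
        else:
            counts[f"rejected_{reasons[0]}"] += 1
    return kept, counts
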