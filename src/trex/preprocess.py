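"""Read preprocessing: quality trimming, adapter removal and orientation,
barcode demultiplexing.

The stage order is: barcode routing first (the barcode is the outermost
prefix on multiplexed runs), then adapter stripping and orientation, then
3' quality trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .models import reverse_complement


@dataclass
class RawRead:
    read_id: str
    bases: str
    quals: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(f"read {self.read_id}: quality length mismatch")

    def slice(self, start: int, end: int) -> "RawRead":
        quals = None if self.quals is None else self.quals[start:end]
        return RawRead(self.read_id, self.bases[start:end], quals)


@dataclass
class AdapterSpec:
    """5'/3' adapter sequences with an anchored Hamming matching model."""

    five_prime: str = ""
    three_prime: str = ""
    max_mismatches: int = 1
    min_adapter_overlap: int = 6

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class BarcodeSpec:
    """dataset_id -> barcode prefix; barcodes must be prefix-free."""

    barcodes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seqs = list(self.barcodes.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("barcodes must be pairwise distinct")
        for a in seqs:
            for b in seqs:
                if a != b and b.startswith(a):
                    raise ValueError(f"barcode {a} is a prefix of {b}")


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------

_TRIM_WINDOW = 5


def _smoothed_quals(quals: List[int]) -> List[float]:
    """Centered running mean of width 5 (shrinking at the read ends)."""
    n = len(quals)
    half = _TRIM_WINDOW // 2
    out = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out.append(sum(quals[lo:hi]) / (hi - lo))
    return out


def trim_low_quality(
    read: RawRead, q_threshold: float = 20, min_length: int = 30
) -> Tuple[Optional[RawRead], Optional[str]]:
    """Trim the 3' end down to the last base whose smoothed quality (window
    5 running mean) reaches ``q_threshold``.

    Returns ``(read, None)`` on success or ``(None, "too_short")`` when the
    surviving prefix is shorter than ``min_length``.  Reads without quality
    strings are length-checked only.
    """
    if read.quals is None:
        if len(read.bases) < min_length:
            return None, "too_short"
        return read, None
    smoothed = _smoothed_quals(read.quals)
    keep = 0
    for i in range(len(smoothed) - 1, -1, -1):
        if smoothed[i] >= q_threshold:
            keep = i + 1
            break
    if keep < min_length:
        return None, "too_short"
    return read.slice(0, keep), None


# ---------------------------------------------------------------------------
# Adapter stripping and orientation
# ---------------------------------------------------------------------------


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    if len(a) != len(b):
        return False
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def _match_prefix(bases: str, adapter: str, spec: AdapterSpec) -> int:
    """Length of adapter matched at the read start (0 = no match).

    The full adapter is tried first; then adapter *suffixes* down to
    ``min_adapter_overlap`` bases, covering reads that begin inside the
    adapter.
    """
    if not adapter:
        return 0
    for alen in range(min(len(adapter), len(bases)), spec.min_adapter_overlap - 1, -1):
        tail = adapter[len(adapter) - alen :]
        budget = spec.max_mismatches if alen == len(adapter) else min(spec.max_mismatches, alen // 8)
        if _hamming_leq(bases[:alen], tail, budget):
            return alen
    return 0


def _match_suffix(bases: str, adapter: str, spec: AdapterSpec) -> int:
    """Length of adapter matched at the read end (adapter prefixes allowed)."""
    if not adapter:
        return 0
    for alen in range(min(len(adapter), len(bases)), spec.min_adapter_overlap - 1, -1):
        head = adapter[:alen]
        budget = spec.max_mismatches if alen == len(adapter) else min(spec.max_mismatches, alen // 8)
        if _hamming_leq(bases[len(bases) - alen :], head, budget):
            return alen
    return 0


def strip_and_orient(read: RawRead, adapters: AdapterSpec) -> Tuple[RawRead, bool, str]:
    """Remove 5'/3' adapters and, when possible, orient the read.

    The read is inspected in both senses: the forward interpretation looks
    for the 5' adapter at the read start and the 3' adapter at the read
    end; the antisense interpretation looks for the same pattern on the
    reverse complement.  A hit in exactly one sense orients the read; the
    returned read is always in transcript sense with strand "+".  No hit
    leaves the read untouched with strand "?".

    Raises ``ValueError`` when both adapters are empty.
    """
    if not adapters.five_prime and not adapters.three_prime:
        raise ValueError("at least one adapter must be non-empty")

    def _scan(bases: str) -> Tuple[int, int, int]:
        p5 = _match_prefix(bases, adapters.five_prime, adapters)
        p3 = _match_suffix(bases, adapters.three_prime, adapters)
        return (int(p5 > 0) + int(p3 > 0), p5, p3)

    fwd_hits, f5, f3 = _scan(read.bases)
    rc_bases = reverse_complement(read.bases)
    rev_hits, r5, r3 = _scan(rc_bases)

    if fwd_hits == 0 and rev_hits == 0:
        return read, False, "?"
    if fwd_hits >= rev_hits:
        trimmed = read.slice(f5, len(read.bases) - f3)
        return trimmed, True, "+"
    # antisense: reverse-complement, then strip in forward sense
    rc_quals = None if read.quals is None else read.quals[::-1]
    rc_read = RawRead(read.read_id, rc_bases, rc_quals)
    trimmed = rc_read.slice(r5, len(rc_bases) - r3)
    return trimmed, True, "+"


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


def demultiplex(
    reads: Iterable[RawRead], spec: BarcodeSpec, max_mismatches: int = 0
) -> Tuple[Dict[str, List[RawRead]], List[RawRead]]:
    """Route reads by barcode prefix; strip the barcode on assignment.

    A read goes to the unique dataset whose barcode prefix matches with
    the minimum number of mismatches, provided that minimum is within
    ``max_mismatches``; ties and non-matches land in the unassigned bin.
    """
    bins: Dict[str, List[RawRead]] = {d: [] for d in spec.barcodes}
    unassigned: List[RawRead] = []
    for read in reads:
        best: List[str] = []
        best_mm = max_mismatches + 1
        for dataset_id, bc in spec.barcodes.items():
            if len(read.bases) < len(bc):
                continue
            mm = sum(1 for x, y in zip(read.bases, bc) if x != y)
            if mm < best_mm:
                best, best_mm = [dataset_id], mm
            elif mm == best_mm:
                best.append(dataset_id)
        if len(best) == 1:
            dataset_id = best[0]
            bins[dataset_id].append(read.slice(len(spec.barcodes[dataset_id]), len(read.bases)))
        else:
            unassigned.append(read)
    return bins, unassigned
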