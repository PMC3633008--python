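"""Read-to-gene assignment with tiered confidence and ambiguity resolution.

Every accepted genomic hit of a read is compared against the annotated
genes around it and tagged with one of four confidence levels:

* ``T`` — transcript read: splice-compatible with an annotated transcript
  and not extending it beyond a bounded terminal overhang;
* ``G`` — genic: overlapping the gene span by at least a minimum number
  of bases;
* ``P`` — proximal: within a flanking window around the gene;
* ``O`` — outside: beyond the flank (dropped from candidates, counted as
  extragenic when a read has no candidate at all).

Two ambiguity classes are distinguished: class I arises from overlapping
genes at a single locus, class II from reads mapping at several genomic
loci (paralogues, pseudogenes, gene clusters).  Ambiguities are resolved
by a fixed cascade — strand, confidence tier (T > G > P), annotated
splice support — and whatever survives unresolved is either shared among
the competing genes or discarded, per user policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .io_formats import GeneIndex, ReferenceGenome
from .models import (
    CONFIDENCE_ORDER,
    AlignedRead,
    Assignment,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)

log = logging.getLogger(__name__)


@dataclass
class AssignParams:
    """Knobs of the assignment stage.

    flank_a: extension of the "surrounding region" around each gene, in
    bases — reads inside it (but not genic) are tagged P.
    min_genic_overlap_b: minimum read-span/gene-span overlap, in bases,
    for a G tag.
    ext_threshold: maximum overhang past the annotated transcript ends
    still tolerated by a T tag.
    ambiguity_policy: what to do with reads the cascade cannot resolve —
    ``assign_both`` shares the read among all competing genes,
    ``discard`` drops it.
    """

    flank_a: int = 1000
    min_genic_overlap_b: int = 1
    ext_threshold: int = 50
    ambiguity_policy: str = "assign_both"

    def __post_init__(self) -> None:
        if self.flank_a < 0 or self.ext_threshold < 0:
            raise ValueError("flank_a and ext_threshold must be >= 0")
        if self.min_genic_overlap_b < 1:
            raise ValueError("min_genic_overlap_b must be >= 1")
        if self.ambiguity_policy not in ("assign_both", "discard"):
            raise ValueError("ambiguity_policy must be 'assign_both' or 'discard'")


@dataclass(frozen=True)
class Candidate:
    gene_id: str
    confidence: str
    hit_index: int
    gene_strand: str


# ---------------------------------------------------------------------------
# Strand inference from splice motifs
# ---------------------------------------------------------------------------


def infer_strand_from_splices(
    introns: Sequence[GenomicInterval], genome: ReferenceGenome
) -> str:
    """Guess the transcript strand of a spliced read from its intron motifs.

    GT..AG on the forward genomic strand at every intron implies "+";
    CT..AC at every intron (GT..AG on the reverse complement) implies
    "-"; any mixture, non-canonical motif, or intron under 4 bases yields
    "?".
    """
    if not introns:
        return "?"
    votes = set()
    for intron in introns:
        if intron.length < 4:
            log.warning("intron %s shorter than 4 bases; strand not inferable", intron)
            return "?"
        donor = genome.fetch(intron.chrom, intron.start, intron.start + 2)
        acceptor = genome.fetch(intron.chrom, intron.end - 2, intron.end)
        if donor == "GT" and acceptor == "AG":
            votes.add("+")
        elif donor == "CT" and acceptor == "AC":
            votes.add("-")
        else:
            return "?"
    return votes.pop() if len(votes) == 1 else "?"


# ---------------------------------------------------------------------------
# Per-gene classification
# ---------------------------------------------------------------------------


def is_transcript_compatible(
    read_blocks: Sequence[GenomicInterval], tx: TranscriptModel, ext_threshold: int
) -> bool:
    """True when the read's block structure matches the transcript.

    Requires (i) every gap between read blocks to coincide exactly with an
    annotated intron of the transcript, (ii) the read to stay within the
    exon chain except for terminal overhangs of at most ``ext_threshold``
    bases past the transcript ends, and (iii) no read block to run into an
    annotated intron without splicing it.
    """
    if read_blocks[0].chrom != tx.chrom:
        return False
    tx_introns = {(i.start, i.end) for i in tx.introns()}
    for a, b in zip(read_blocks, read_blocks[1:]):
        if b.start > a.end and (a.end, b.start) not in tx_introns:
            return False
    for block in read_blocks:
        for s, e in tx_introns:
            if block.start < e and s < block.end:
                return False
    if read_blocks[0].start < tx.start - ext_threshold:
        return False
    if read_blocks[-1].end > tx.end + ext_threshold:
        return False
    return True


def classify_against_gene(
    read: AlignedRead, gene: GeneModel, params: AssignParams
) -> str:
    """Tag one hit of a read against one gene: T, G, P or O."""
    span = read.span
    if span.chrom != gene.span.chrom:
        return "O"
    for tx in gene.transcripts:
        if is_transcript_compatible(read.blocks, tx, params.ext_threshold):
            return "T"
    if span.overlap_length(gene.span) >= params.min_genic_overlap_b:
        return "G"
    flank_start = max(0, gene.span.start - params.flank_a)
    flank_end = gene.span.end + params.flank_a
    if span.start < flank_end and flank_start < span.end:
        return "P"
    return "O"


# ---------------------------------------------------------------------------
# Candidate pooling and ambiguity classification
# ---------------------------------------------------------------------------


def candidate_assignments(
    hits: Sequence[AlignedRead], genes: GeneIndex, params: AssignParams
) -> Tuple[List[Candidate], frozenset]:
    """Pool gene candidates over all genomic hits of one read.

    Class I ambiguity: two or more candidate genes at one hit locus
    (overlapping genes).  Class II: candidates drawn from two or more
    distinct hit loci (multi-mapping read).
    """
    candidates: List[Candidate] = []
    for i, hit in enumerate(hits):
        span = hit.span
        lo = max(0, span.start - params.flank_a)
        for gene in genes.query(span.chrom, lo, span.end + params.flank_a):
            tag = classify_against_gene(hit, gene, params)
            if tag != "O":
                candidates.append(Candidate(gene.gene_id, tag, i, gene.strand))
    ambiguity = set()
    by_hit: Dict[int, set] = {}
    for c in candidates:
        by_hit.setdefault(c.hit_index, set()).add(c.gene_id)
    if any(len(g) >= 2 for g in by_hit.values()):
        ambiguity.add("I")
    if len(by_hit) >= 2:
        ambiguity.add("II")
    return candidates, frozenset(ambiguity)


# ---------------------------------------------------------------------------
# Ambiguity resolution cascade
# ---------------------------------------------------------------------------


def _hit_strand(hit: AlignedRead, genome: Optional[ReferenceGenome]) -> str:
    """Transcript strand of the read at this hit, if determinable.

    An oriented read's transcript strand is the strand it aligned to; an
    unoriented spliced read's strand can often be guessed from its
    donor/acceptor motifs.
    """
    if hit.oriented:
        return hit.read_strand
    if genome is not None and hit.spliced:
        return infer_strand_from_splices(hit.introns(), genome)
    return "?"


def resolve(
    hits: Sequence[AlignedRead],
    candidates: Sequence[Candidate],
    ambiguity: frozenset,
    annotated_introns: Dict[tuple, set],
    params: AssignParams,
    genome: Optional[ReferenceGenome] = None,
) -> List[Assignment]:
    """Resolve one read's candidate genes down to final assignments.

    The cascade stops at the first step that leaves exactly one candidate
    gene: (1) drop candidates on the strand opposite the read's (known or
    splice-inferred) transcript strand; (2) keep only the maximal
    confidence tier under T > G > P; (3) for spliced reads, keep only
    genes owning an annotated intron identical to a read gap.  A step that
    would eliminate every candidate is skipped as uninformative.  Whatever
    remains ambiguous is shared or discarded per policy.
    """
    if not candidates:
        raise ValueError("resolve() requires a non-empty candidate list")

    initial_genes = {c.gene_id for c in candidates}
    survivors = list(candidates)

    def finish(surv: List[Candidate], how: str) -> List[Assignment]:
        by_gene: Dict[str, List[Candidate]] = {}
        for c in surv:
            by_gene.setdefault(c.gene_id, []).append(c)
        status = how
        if how == "resolved" and len(initial_genes) == 1:
            status = "unique"
        out = []
        for gene_id in sorted(by_gene):
            best = max(by_gene[gene_id], key=lambda c: CONFIDENCE_ORDER[c.confidence])
            out.append(
                Assignment(
                    read_id=hits[0].read_id,
                    gene_id=gene_id,
                    confidence=best.confidence,
                    ambiguity_class=ambiguity,
                    status=status,
                )
            )
        return out

    if len({c.gene_id for c in survivors}) == 1:
        return finish(survivors, "resolved")

    # (1) strand
    strands = {i: _hit_strand(hits[i], genome) for i in {c.hit_index for c in survivors}}
    filtered = [
        c
        for c in survivors
        if strands[c.hit_index] == "?" or c.gene_strand == strands[c.hit_index]
    ]
    if filtered:
        survivors = filtered
    if len({c.gene_id for c in survivors}) == 1:
        return finish(survivors, "resolved")

    # (2) confidence tier T > G > P
    top = max(CONFIDENCE_ORDER[c.confidence] for c in survivors)
    survivors = [c for c in survivors if CONFIDENCE_ORDER[c.confidence] == top]
    if len({c.gene_id for c in survivors}) == 1:
        return finish(survivors, "resolved")

    # (3) annotated splice support
    if any(hits[c.hit_index].spliced for c in survivors):
        supported = []
        for c in survivors:
            gaps = {iv.key() for iv in hits[c.hit_index].introns()}
            owners = set()
            for key in gaps:
                owners |= annotated_introns.get(key, set())
            if c.gene_id in owners:
                supported.append(c)
        if supported:
            survivors = supported
        if len({c.gene_id for c in survivors}) == 1:
            return finish(survivors, "resolved")

    # (4) unresolved
    if params.ambiguity_policy == "assign_both":
        return finish(survivors, "shared")
    return []


# ---------------------------------------------------------------------------
# Dataset-level driver
# ---------------------------------------------------------------------------


@dataclass
class AssignResult:
    """Outcome of assigning one dataset's accepted reads."""

    assignments: List[Assignment] = field(default_factory=list)
    extragenic: List[str] = field(default_factory=list)
    discarded: List[str] = field(default_factory=list)

    def counts(self) -> Dict[str, int]:
        per_read: Dict[str, str] = {}
        for a in self.assignments:
            per_read[a.read_id] = a.status
        c = {
            "assigned_unique": sum(1 for s in per_read.values() if s == "unique"),
            "assigned_resolved": sum(1 for s in per_read.values() if s == "resolved"),
            "shared": sum(1 for s in per_read.values() if s == "shared"),
            "extragenic": len(self.extragenic),
            "discarded_ambiguous": len(self.discarded),
        }
        return c

    def reads_for_gene(self, gene_id: str, confidences: str = "TG") -> List[str]:
        return [
            a.read_id
            for a in self.assignments
            if a.gene_id == gene_id and a.confidence in confidences
        ]


def assign_dataset(
    hits_by_read: Dict[str, List[AlignedRead]],
    genes: GeneIndex,
    params: AssignParams,
    genome: Optional[ReferenceGenome] = None,
    annotated_introns: Optional[Dict[tuple, set]] = None,
) -> AssignResult:
    """Run classification + resolution for every accepted read."""
    if annotated_introns is None:
        annotated_introns = genes.annotated_introns()
    result = AssignResult()
    for read_id in sorted(hits_by_read):
        hits = hits_by_read[read_id]
        candidates, ambiguity = candidate_assignments(hits, genes, params)
        if not candidates:
            result.extragenic.append(read_id)
            continue
        final = resolve(hits, candidates, ambiguity, annotated_introns, params, genome)
        if not final:
            result.discarded.append(read_id)
        else:
            result.assignments.extend(final)
    return result
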