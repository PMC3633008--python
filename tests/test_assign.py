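import numpy as np
import pytest

from trex.assign import (
    AssignParams,
    Candidate,
    assign_dataset,
    candidate_assignments,
    classify_against_gene,
    infer_strand_from_splices,
    is_transcript_compatible,
    resolve,
)
from trex.io_formats import GeneIndex, ReferenceGenome
from trex.models import AlignedRead, GenomicInterval

from conftest import make_gene, make_transcript


def read_with_blocks(blocks, read_id="r", oriented=False, strand="+", n_hits=1):
    ivs = [GenomicInterval("chr1", s, e) for s, e in blocks]
    length = sum(e - s for s, e in blocks)
    return AlignedRead(
        read_id=read_id,
        blocks=ivs,
        read_length=length,
        matches=length,
        aligned_bases=length,
        n_hits=n_hits,
        oriented=oriented,
        read_strand=strand,
    )


class TestInferStrand:
    def genome(self, donor, acceptor):
        seq = list("A" * 400)
        seq[100:102] = list(donor)
        seq[198:200] = list(acceptor)
        return ReferenceGenome.from_dict({"chr1": "".join(seq)})

    def test_forward_motif(self):
        introns = [GenomicInterval("chr1", 100, 200)]
        assert infer_strand_from_splices(introns, self.genome("GT", "AG")) == "+"

    def test_reverse_motif(self):
        introns = [GenomicInterval("chr1", 100, 200)]
        assert infer_strand_from_splices(introns, self.genome("CT", "AC")) == "-"

    def test_non_canonical_motif_is_unknown(self):
        introns = [GenomicInterval("chr1", 100, 200)]
        assert infer_strand_from_splices(introns, self.genome("GC", "AG")) == "?"

    def test_mixed_motifs_are_unknown(self):
        seq = list("A" * 600)
        seq[100:102], seq[198:200] = list("GT"), list("AG")
        seq[300:302], seq[398:400] = list("CT"), list("AC")
        genome = ReferenceGenome.from_dict({"chr1": "".join(seq)})
        introns = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400)]
        assert infer_strand_from_splices(introns, genome) == "?"

    def test_tiny_intron_is_unknown(self):
        introns = [GenomicInterval("chr1", 100, 103)]
        assert infer_strand_from_splices(introns, self.genome("GT", "AG")) == "?"


class TestTranscriptCompatibility:
    # standard fixture transcript: exons [100,200) [300,400) [500,650)
    TX = make_transcript()

    def test_unspliced_read_inside_one_exon(self):
        assert is_transcript_compatible(
            [GenomicInterval("chr1", 120, 180)], self.TX, 0
        )

    def test_exact_junction_read(self):
        blocks = [GenomicInterval("chr1", 150, 200), GenomicInterval("chr1", 300, 350)]
        assert is_transcript_compatible(blocks, self.TX, 0)

    def test_shifted_junction_rejected(self):
        blocks = [GenomicInterval("chr1", 150, 201), GenomicInterval("chr1", 301, 350)]
        assert not is_transcript_compatible(blocks, self.TX, 0)

    def test_block_crossing_intron_rejected(self):
        assert not is_transcript_compatible(
            [GenomicInterval("chr1", 150, 250)], self.TX, 0
        )

    @pytest.mark.parametrize(
        "overhang,ext,ok",
        [(30, 20, False), (30, 50, True), (50, 50, True), (51, 50, False), (0, 0, True)],
    )
    def test_terminal_extension_boundary(self, overhang, ext, ok):
        # derived by boundary arithmetic: read ends overhang bases past the
        # 3' exon end at 650
        blocks = [GenomicInterval("chr1", 600, 650 + overhang)] if overhang else [
            GenomicInterval("chr1", 600, 650)
        ]
        assert is_transcript_compatible(blocks, self.TX, ext) is ok

    def test_read_in_intron_rejected(self):
        assert not is_transcript_compatible(
            [GenomicInterval("chr1", 220, 280)], self.TX, 0
        )


class TestClassifyAgainstGene:
    PARAMS = AssignParams(flank_a=500, min_genic_overlap_b=20, ext_threshold=0)

    def test_genic_read(self):
        gene = make_gene(exons=((1000, 2000),))
        read = read_with_blocks([(1200, 1300)])
        # inside the gene span but overlapping the single exon: that is T
        assert classify_against_gene(read, gene, self.PARAMS) == "T"

    def test_genic_but_not_transcript_compatible(self):
        gene = make_gene(exons=((1000, 1400), (1600, 2000)))
        read = read_with_blocks([(1300, 1450)])  # runs into the intron
        assert classify_against_gene(read, gene, self.PARAMS) == "G"

    def test_small_overlap_inside_flank_is_proximal(self):
        gene = make_gene(exons=((1000, 1400), (1600, 2000)))
        read = read_with_blocks([(1995, 2095)])  # 5 bases of overlap < b=20
        assert classify_against_gene(read, gene, self.PARAMS) == "P"

    def test_outside_flank_is_extragenic(self):
        gene = make_gene(exons=((1000, 2000),))
        read = read_with_blocks([(2600, 2700)])
        assert classify_against_gene(read, gene, self.PARAMS) == "O"

    def test_two_exon_junction_read_is_transcript_tag(self):
        gene = make_gene(exons=((1000, 1400), (1600, 2000)))
        read = read_with_blocks([(1350, 1400), (1600, 1650)])
        assert classify_against_gene(read, gene, self.PARAMS) == "T"


class TestCandidateAssignments:
    def test_single_gene_no_ambiguity(self):
        genes = GeneIndex([make_gene("geneA", exons=((1000, 2000),))])
        read = read_with_blocks([(1100, 1200)])
        cands, amb = candidate_assignments([read], genes, AssignParams())
        assert [c.gene_id for c in cands] == ["geneA"] and amb == frozenset()

    def test_overlapping_antisense_genes_are_class_one(self):
        a = make_gene("geneA", strand="+", exons=((1000, 2000),))
        b = make_gene("geneB", strand="-", exons=((1800, 2800),))
        genes = GeneIndex([a, b])
        read = read_with_blocks([(1850, 1950)])
        cands, amb = candidate_assignments([read], genes, AssignParams())
        assert {c.gene_id for c in cands} == {"geneA", "geneB"} and amb == {"I"}

    def test_two_loci_are_class_two(self):
        a = make_gene("geneA", exons=((1000, 2000),))
        b = make_gene("geneB", exons=((50000, 51000),))
        genes = GeneIndex([a, b])
        hits = [
            read_with_blocks([(1100, 1200)], n_hits=2),
            read_with_blocks([(50100, 50200)], n_hits=2),
        ]
        cands, amb = candidate_assignments(hits, genes, AssignParams())
        assert {c.gene_id for c in cands} == {"geneA", "geneB"} and amb == {"II"}


def brute_force_resolve(hits, candidates, policy, annotated_introns, hit_strands):
    """Literal enumeration of the cascade rules, kept independent of the
    implementation: apply each rule in order, stop when one gene is left."""
    order = {"T": 3, "G": 2, "P": 1}

    def genes_of(cs):
        return sorted({c.gene_id for c in cs})

    current = list(candidates)
    if len(genes_of(current)) > 1:
        # rule 1: strand
        step = [
            c
            for c in current
            if hit_strands[c.hit_index] == "?" or hit_strands[c.hit_index] == c.gene_strand
        ]
        if step:
            current = step
    if len(genes_of(current)) > 1:
        # rule 2: confidence
        best = max(order[c.confidence] for c in current)
        current = [c for c in current if order[c.confidence] == best]
    if len(genes_of(current)) > 1:
        # rule 3: annotated splice support
        if any(hits[c.hit_index].spliced for c in current):
            step = []
            for c in current:
                keys = {iv.key() for iv in hits[c.hit_index].introns()}
                if any(c.gene_id in annotated_introns.get(k, set()) for k in keys):
                    step.append(c)
            if step:
                current = step
    genes = genes_of(current)
    if len(genes) == 1:
        return genes, "one"
    return (genes, "shared") if policy == "assign_both" else ([], "discarded")


class TestResolve:
    PARAMS_BOTH = AssignParams(ambiguity_policy="assign_both")
    PARAMS_DISCARD = AssignParams(ambiguity_policy="discard")

    def test_confidence_order_wins(self):
        hits = [read_with_blocks([(100, 200)])]
        cands = [Candidate("geneA", "G", 0, "+"), Candidate("geneB", "P", 0, "+")]
        out = resolve(hits, cands, frozenset({"I"}), {}, self.PARAMS_BOTH)
        assert [(a.gene_id, a.status) for a in out] == [("geneA", "resolved")]

    def test_oriented_read_resolves_antisense_pair(self):
        hits = [read_with_blocks([(100, 200)], oriented=True, strand="+")]
        cands = [Candidate("geneA", "G", 0, "+"), Candidate("geneB", "G", 0, "-")]
        out = resolve(hits, cands, frozenset({"I"}), {}, self.PARAMS_BOTH)
        assert [(a.gene_id, a.status) for a in out] == [("geneA", "resolved")]

    def test_unoriented_tie_is_shared_or_discarded(self):
        hits = [read_with_blocks([(100, 200)])]
        cands = [Candidate("geneA", "G", 0, "+"), Candidate("geneB", "G", 0, "-")]
        both = resolve(hits, cands, frozenset({"I"}), {}, self.PARAMS_BOTH)
        assert sorted(a.gene_id for a in both) == ["geneA", "geneB"]
        assert all(a.status == "shared" for a in both)
        none = resolve(hits, cands, frozenset({"I"}), {}, self.PARAMS_DISCARD)
        assert none == []

    def test_annotated_splice_support_breaks_confidence_tie(self):
        hits = [read_with_blocks([(100, 200), (300, 400)])]
        annotated = {("chr1", 200, 300): {"geneA"}}
        cands = [Candidate("geneA", "G", 0, "+"), Candidate("geneB", "G", 0, "+")]
        out = resolve(hits, cands, frozenset({"I"}), annotated, self.PARAMS_BOTH)
        assert [(a.gene_id, a.status) for a in out] == [("geneA", "resolved")]

    def test_shared_annotated_intron_falls_through_to_policy(self):
        hits = [read_with_blocks([(100, 200), (300, 400)])]
        annotated = {("chr1", 200, 300): {"geneA", "geneB"}}
        cands = [Candidate("geneA", "G", 0, "+"), Candidate("geneB", "G", 0, "+")]
        out = resolve(hits, cands, frozenset({"I"}), annotated, self.PARAMS_DISCARD)
        assert out == []

    def test_empty_candidates_is_contract_violation(self):
        with pytest.raises(ValueError):
            resolve([read_with_blocks([(0, 10)])], [], frozenset(), {}, self.PARAMS_BOTH)

    def test_single_candidate_is_unique(self):
        hits = [read_with_blocks([(100, 200)])]
        out = resolve(hits, [Candidate("geneA", "T", 0, "+")], frozenset(), {}, self.PARAMS_BOTH)
        assert [(a.gene_id, a.status, a.confidence) for a in out] == [("geneA", "unique", "T")]

    def test_agrees_with_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(300):
            n_hits = int(rng.integers(1, 3))
            hits = []
            for h in range(n_hits):
                base = 1000 * h
                if rng.random() < 0.5:
                    blocks = [(base + 100, base + 200), (base + 300, base + 400)]
                else:
                    blocks = [(base + 100, base + 200)]
                oriented = bool(rng.random() < 0.5)
                hits.append(
                    read_with_blocks(
                        blocks,
                        oriented=oriented,
                        strand="+" if rng.random() < 0.5 else "-",
                        n_hits=n_hits,
                    )
                )
            n_cand = int(rng.integers(1, 5))
            gene_pool = ["gA", "gB", "gC", "gD"]
            cands = [
                Candidate(
                    gene_pool[int(rng.integers(0, 4))],
                    "TGP"[int(rng.integers(0, 3))],
                    int(rng.integers(0, n_hits)),
                    "+" if rng.random() < 0.5 else "-",
                )
                for _ in range(n_cand)
            ]
            annotated = {}
            for h in hits:
                for iv in h.introns():
                    owners = {g for g in gene_pool if rng.random() < 0.4}
                    if owners:
                        annotated[iv.key()] = owners
            policy = "assign_both" if trial % 2 else "discard"
            params = AssignParams(ambiguity_policy=policy)
            got = resolve(hits, cands, frozenset(), annotated, params)
            hit_strands = {
                i: (hits[i].read_strand if hits[i].oriented else "?")
                for i in range(n_hits)
            }
            want_genes, _ = brute_force_resolve(hits, cands, policy, annotated, hit_strands)
            assert sorted(a.gene_id for a in got) == want_genes, f"trial {trial}"

    def test_no_dropped_candidate_outranks_a_returned_one(self):
        rng = np.random.default_rng(7)
        order = {"T": 3, "G": 2, "P": 1}
        for _ in range(200):
            hits = [read_with_blocks([(100, 200)])]
            cands = [
                Candidate(
                    f"g{int(rng.integers(0, 4))}",
                    "TGP"[int(rng.integers(0, 3))],
                    0,
                    "+",
                )
                for _ in range(int(rng.integers(1, 5)))
            ]
            got = resolve(hits, cands, frozenset(), {}, self.PARAMS_BOTH)
            if not got:
                continue
            returned = max(order[a.confidence] for a in got)
            dropped = [c for c in cands if c.gene_id not in {a.gene_id for a in got}]
            assert all(order[c.confidence] <= returned for c in dropped)


class TestAssignDataset:
    def test_partition_of_accepted_reads(self):
        genes = GeneIndex(
            [
                make_gene("geneA", exons=((1000, 2000),)),
                make_gene("geneB", strand="-", exons=((1800, 2800),)),
            ]
        )
        hits = {
            "in_a": [read_with_blocks([(1100, 1200)], read_id="in_a")],
            "overlap": [read_with_blocks([(1850, 1950)], read_id="overlap")],
            "nowhere": [read_with_blocks([(50000, 50100)], read_id="nowhere")],
        }
        result = assign_dataset(
            hits, genes, AssignParams(flank_a=100, ambiguity_policy="discard")
        )
        c = result.counts()
        assert c["assigned_unique"] == 1
        assert c["discarded_ambiguous"] == 1
        assert c["extragenic"] == 1
        assert sum(c.values()) - c["assigned_resolved"] - c["shared"] == len(hits)
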