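import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trex.express import (
    bh_adjust,
    de_scan,
    fisher_de,
    fisher_two_sided,
    fold_change,
    gene_metrics,
    locate_on_transcript,
    rank_genes,
)
from trex.models import GenomicInterval

from conftest import make_transcript
from test_assign import read_with_blocks

# ---------------------------------------------------------------------------
# exact Fisher oracle: enumerate the whole support with an independently
# built Pascal-triangle table, compare probabilities as exact integers
# ---------------------------------------------------------------------------


def _pascal(n_max):
    rows = [[1]]
    for n in range(1, n_max + 1):
        prev = rows[-1]
        rows.append(
            [1] + [prev[i - 1] + prev[i] for i in range(1, n)] + [1]
        )
    return rows


_PASCAL = _pascal(140)


def oracle_fisher(c1, t1, c2, t2):
    k = c1 + c2
    numerators = {}
    for a in range(max(0, k - t2), min(k, t1) + 1):
        numerators[a] = _PASCAL[t1][a] * _PASCAL[t2][k - a]
    obs = numerators[c1]
    total = sum(v for v in numerators.values() if v <= obs)
    return total / _PASCAL[t1 + t2][k]


class TestFisher:
    def test_identical_empty_tables(self):
        p, fc = fisher_de(0, 1000, 0, 1000)
        assert p == 1.0 and fc == 1.0

    def test_symmetric_table_p_is_one(self):
        p, _ = fisher_de(5, 100, 5, 100)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_exhaustively_small(self):
        for t1, t2 in [(7, 9), (12, 12), (20, 5)]:
            for c1 in range(t1 + 1):
                for c2 in range(t2 + 1):
                    got = fisher_two_sided(c1, t1, c2, t2)
                    assert abs(got - oracle_fisher(c1, t1, c2, t2)) < 1e-12

    def test_large_margin_example_matches_float_enumeration(self):
        from scipy.stats import hypergeom

        c1, t1, c2, t2 = 10, 1000, 30, 1000
        k = c1 + c2
        dist = hypergeom(t1 + t2, k, t1)
        support = np.arange(max(0, k - t2), min(k, t1) + 1)
        pmf = dist.pmf(support)
        obs = dist.pmf(c1)
        want = pmf[pmf <= obs * (1 + 1e-9)].sum()
        p = fisher_two_sided(c1, t1, c2, t2)
        assert p == pytest.approx(want, abs=1e-10)
        assert p < 0.01

    def test_agrees_with_scipy_on_sampled_tables(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(150):
            t1, t2 = int(rng.integers(1, 80)), int(rng.integers(1, 80))
            c1, c2 = int(rng.integers(0, t1 + 1)), int(rng.integers(0, t2 + 1))
            ours = fisher_two_sided(c1, t1, c2, t2)
            table = [[c1, t1 - c1], [c2, t2 - c2]]
            theirs = fisher_exact(table, alternative="two-sided")[1]
            assert ours == pytest.approx(min(theirs, 1.0), abs=5e-7)

    @given(
        st.integers(1, 60), st.integers(1, 60), st.integers(0, 60), st.integers(0, 60)
    )
    @settings(max_examples=300, deadline=None)
    def test_swapping_datasets_preserves_p_and_inverts_fold(self, t1, t2, c1, c2):
        c1, c2 = min(c1, t1), min(c2, t2)
        p_ab = fisher_two_sided(c1, t1, c2, t2)
        p_ba = fisher_two_sided(c2, t2, c1, t1)
        assert math.isclose(p_ab, p_ba, rel_tol=1e-12)
        assert math.isclose(
            fold_change(c1, t1, c2, t2) * fold_change(c2, t2, c1, t1), 1.0
        )

    def test_count_above_total_is_contract_violation(self):
        with pytest.raises(ValueError):
            fisher_de(11, 10, 0, 10)

    def test_zero_replacement_in_fold_change(self):
        _, fc = fisher_de(0, 1000, 10, 1000)
        assert fc == pytest.approx(0.1)  # 0 -> 1 before the ratio


class TestDEScan:
    def test_planted_difference_detected(self):
        res = de_scan({"g": 100}, {"g": 25}, 100_000, 100_000)
        assert len(res) == 1
        assert res[0].p_value < 1e-3
        assert res[0].fold_change == pytest.approx(4.0)
        assert res[0].direction == "up"

    def test_identical_proportions_yield_q_of_one(self):
        counts = {f"g{i}": 10 for i in range(20)}
        res = de_scan(counts, counts, 10_000, 10_000)
        assert all(r.q_value == pytest.approx(1.0) for r in res)

    def test_absent_features_not_reported(self):
        res = de_scan({"g": 0, "h": 5}, {"g": 0, "h": 5}, 1000, 1000)
        assert [r.feature_id for r in res] == ["h"]

    def test_bh_adjustment_is_monotone_and_bounded(self):
        pvals = [0.001, 0.01, 0.02, 0.5, 0.9]
        qvals = bh_adjust(pvals)
        assert all(q >= p for p, q in zip(pvals, qvals))
        assert qvals == sorted(qvals)


class TestGeneMetrics:
    def test_stacked_reads_focus_completely(self):
        reads = [read_with_blocks([(100, 200)], read_id=f"r{i}") for i in range(10)]
        m = gene_metrics("g", "A", reads)
        assert (m.coverage, m.depth, m.focusing_index) == (10, 10, 1.0)

    def test_disjoint_reads_spread_out(self):
        reads = [
            read_with_blocks([(100 * i, 100 * i + 50)], read_id=f"r{i}")
            for i in range(1, 11)
        ]
        m = gene_metrics("g", "A", reads)
        assert (m.coverage, m.depth, m.focusing_index) == (10, 1, 0.1)

    def test_spliced_read_covers_only_exonic_blocks(self):
        a = read_with_blocks([(100, 200), (500, 600)], read_id="a")
        b = read_with_blocks([(300, 400)], read_id="b")
        m = gene_metrics("g", "A", [a, b])
        assert m.depth == 1

    def test_no_reads_returns_none(self):
        assert gene_metrics("g", "A", []) is None

    def test_matches_per_base_pileup_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            reads = []
            pileup = np.zeros(3000, dtype=int)
            for i in range(n):
                start = int(rng.integers(0, 2000))
                length = int(rng.integers(20, 120))
                if rng.random() < 0.3:
                    gap = int(rng.integers(60, 200))
                    blocks = [
                        (start, start + length),
                        (start + length + gap, start + length + gap + length),
                    ]
                else:
                    blocks = [(start, start + length)]
                reads.append(read_with_blocks(blocks, read_id=f"r{i}"))
                for s, e in blocks:
                    pileup[s:e] += 1
            m = gene_metrics("g", "A", reads)
            assert m.coverage == n
            assert m.depth == int(pileup.max())
            assert 0 < m.focusing_index <= 1.0


class TestRankGenes:
    def metrics(self):
        from trex.models import GeneMetrics

        return {
            "A": {
                "g1": GeneMetrics("g1", "A", coverage=50, depth=5),
                "g2": GeneMetrics("g2", "A", coverage=9, depth=9),
            },
            "B": {
                "g1": GeneMetrics("g1", "B", coverage=30, depth=2),
            },
        }

    def test_union_vs_intersection(self):
        m = self.metrics()
        assert rank_genes(m, combine="union") == ["g1", "g2"]
        assert rank_genes(m, combine="intersection") == ["g1"]

    def test_coverage_bound_excludes(self):
        got = rank_genes(self.metrics(), criteria={"coverage": (10, None)}, combine="union")
        assert got == ["g1"]

    def test_no_criteria_sorts_by_coverage_descending(self):
        assert rank_genes(self.metrics()) == ["g1", "g2"]

    def test_unknown_index_is_an_error(self):
        with pytest.raises(ValueError):
            rank_genes(self.metrics(), rank_by="entropy")


class TestLocateOnTranscript:
    # exons [100,200) [300,400) [500,650): spliced length 350; CDS (50, 250)
    TX = make_transcript(cds_span=(50, 250))

    def test_read_fully_within_cds(self):
        got = locate_on_transcript([GenomicInterval("chr1", 160, 200)], self.TX)
        assert got == {"utr5": 0, "cds": 40, "utr3": 0, "noncoding": 0}

    def test_read_straddling_cds_end(self):
        # transcript coords 240..290: 10 bases of CDS + 40 of 3'UTR
        blocks = self.TX.genomic_blocks_for(240, 290)
        got = locate_on_transcript(blocks, self.TX)
        assert got == {"utr5": 0, "cds": 10, "utr3": 40, "noncoding": 0}

    def test_noncoding_transcript(self):
        tx = make_transcript()
        got = locate_on_transcript([GenomicInterval("chr1", 150, 200)], tx)
        assert got == {"utr5": 0, "cds": 0, "utr3": 0, "noncoding": 50}

    def test_projection_matches_brute_force(self):
        rng = np.random.default_rng(5)
        tx = make_transcript(cds_span=(50, 250), strand="-")
        # brute force: walk every genomic base of each block through the
        # exon chain and classify its transcript coordinate
        exon_bases = []
        for e in reversed(tx.exons):
            exon_bases.extend(range(e.end - 1, e.start - 1, -1))
        coord_of = {g: i for i, g in enumerate(exon_bases)}
        for _ in range(50):
            t0 = int(rng.integers(0, 340))
            t1 = int(rng.integers(t0 + 1, 351))
            blocks = tx.genomic_blocks_for(t0, t1)
            got = locate_on_transcript(blocks, tx)
            want = {"utr5": 0, "cds": 0, "utr3": 0, "noncoding": 0}
            for b in blocks:
                for g in range(b.start, b.end):
                    t = coord_of[g]
                    if t < 50:
                        want["utr5"] += 1
                    elif t < 250:
                        want["cds"] += 1
                    else:
                        want["utr3"] += 1
            assert got == want
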