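# Methods

This note documents the models, conventions and design choices behind
the package, in the spirit of the methods documentation of mature
scientific Python packages: what each stage assumes, which knobs matter,
and what the synthetic benchmark does and does not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward genomic
strand; GFF/GTF and SAM (1-based inclusive) are converted at the file
boundary and nowhere else. Annotation is read with `gffutils`
(gene → mRNA/transcript → exon/CDS), alignments with `pysam` (plain SAM;
BAM works wherever pysam reads it transparently), genomes with
`pyfaidx`, FASTQ with Biopython. Orphan exons or transcripts and
mixed-strand exon chains are hard errors. CDS features are projected
into transcript coordinates at load time, so downstream UTR/CDS
positioning never re-derives them.

Alignment identity is taken from SAM tags rather than re-alignment: with
`NM`, mismatches = NM − inserted − deleted bases and matches =
aligned_bases − mismatches; with only `MD`, the matched-base runs are
summed; with neither, the alignment is assumed mismatch-free. Aligned
bases count M/=/X operations (read bases aligned to the reference). The
hit count comes from `NH` when present, otherwise from the number of
records sharing a read id.

## Preprocessing

Stage order: barcode demultiplexing (the barcode is the outermost
prefix), adapter stripping/orientation, then 3' quality trimming. Each
read's terminal bucket is recorded so the run report can assert read
conservation.

*Quality trimming.* The read is cut after the last base whose smoothed
quality — a centered running mean of window 5, shrinking at the read
ends — reaches the threshold (default Q20); reads shorter than
`min_length` (default 30) afterwards are rejected. The window is
centered because that is the only placement consistent with the
trimmer's contract on mixed-quality tails (a trailing window would keep
up to two low-quality bases, a forward-looking window would cut two
good ones). This is deliberately minimal: it models the effect, not the
implementation, of production FASTQ tools, and substitution of a fancier
trimmer changes nothing downstream.

*Adapters.* Matching is anchored (read ends only), Hamming distance, no
indels (default ≤ 1 mismatch). Partial adapters are allowed down to
`min_adapter_overlap` bases (default 6), with a proportionally reduced
mismatch budget (one mismatch per 8 matched bases) to keep short partial
matches from firing spuriously. A read is *oriented* when the 5'/3'
adapter pattern is found in exactly the forward or the reverse-
complement sense; antisense reads are flipped so the output read is
always in transcript sense. Orientation feeds the strand step of
ambiguity resolution.

*Demultiplexing.* A read routes to the unique barcode with minimum
Hamming distance within the allowed mismatches (default 0); ties and
misses go to an `unassigned` bin. Barcodes must be prefix-free.

## Mapping-quality gate

Accept iff overlap% ≥ `min_overlap` (default 70), similarity% ≥
`min_similarity` (default 96) and hits ≤ `max_hits` (default 10); the
rejection reason names the first failing criterion in that fixed order.
The 70/96 defaults are the thresholds used for long-read benchmarking of
this kind of engine; `max_hits = 10` is a conventional multi-mapping
cap. The overlap denominator is the *trimmed* read length — the read the
aligner actually saw. All passing hits of a multi-mapped read are
forwarded together; the gate never picks a "best" hit, because class II
resolution owns that decision.

## Assignment

Per gene, the tag is the best of T ≻ G ≻ P (every T read would also
qualify as G; one tag per gene per read). Transcript compatibility is
formalized as *exact intron-chain agreement plus bounded terminal
extension*: every read gap must equal an annotated intron exactly, no
block may overlap an annotated intron of that transcript, and the read
may extend at most `ext_threshold` bases (default 50) past the
transcript ends. Exactness is a deliberate, conservative reading of
"contiguous mapping to annotated transcripts": it is testable and never
credits a shifted junction.

Defaults `flank_a = 1000`, `min_genic_overlap_b = 1`, `ext_threshold =
50` are engine defaults for user-tunable knobs, echoed in every run
report.

The resolution cascade for a read with several candidate genes:

1. **Strand** — drop candidates on the strand opposite the read's
   transcript strand, which is known for oriented reads and inferable
   for unoriented spliced reads when *every* intron shows GT..AG on one
   strand (CT..AC on the forward strand means GT..AG on the reverse);
   any mixture or non-canonical motif yields "unknown" and the step is
   uninformative.
2. **Confidence** — keep the maximal tier under T > G > P.
3. **Annotated splice support** — for spliced reads, keep genes owning
   an annotated intron identical to a read gap. If two genes share that
   intron (overlapping isoform annotations) the tie stands.
4. **Policy** — `assign_both` shares the read among all survivors
   (status `shared`), `discard` drops it (counted discarded-ambiguous).

Each step stops the cascade when exactly one gene remains. A step whose
filter would eliminate *every* candidate (e.g. an oriented read between
two antisense genes on the wrong strand for both) is skipped as
uninformative rather than discarding the read — the cascade only ever
uses a criterion that can still distinguish candidates. Class II hits
of one gene at several loci collapse to a single assignment so a read
never counts twice in one gene's coverage. Hit-level similarity is not
used as a tie-break: the cascade criteria are orientation, confidence
and splice support only.

P-tagged reads are reported but excluded from expression counts by
default (`count_confidence = "TG"`): proximal reads are evidence of
nearby transcription, not of the annotated gene body.

## Splice-site catalog

Identity of an intron is its exact (chrom, start, end); there is no
fuzzy merging of near-identical junctions, matching the exactness used
for annotated-intron comparison. Donor/acceptor dinucleotides are read
from the genome and strand-adjusted (strand from the motif itself when
canonical, else from the owning gene). "Canonical" means GT..AG only;
GC..AG and AT..AC junctions keep their motif strings with
`canonical = false` so users can re-score. Reads discarded as
unresolvable do not contribute junction support (their locus is
unknown by definition); extragenic reads do, with no owning gene.
Intron retention is not called, and junctions are not assembled into
transcript models.

## Expression and differential expression

Depth counts *reads* per position (a spliced read covers only its
exonic blocks; a read never counts twice at a position), computed by an
event-sweep equivalent to a per-base pileup. The focusing index
depth/coverage lies in (0, 1] and equals 1 iff some position is covered
by every assigned read.

The Fisher two-sided p-value uses the minimum-likelihood convention —
the sum of hypergeometric probabilities of all tables in the support no
more probable than the observed one — computed in exact integer
arithmetic (binomial-coefficient numerators share a common denominator,
so table probabilities compare as integers and the final division is
one correctly-rounded float operation). This is implemented directly
rather than via `scipy.stats.fisher_exact` because scipy's tie rule
carries a 1e-7 relative tolerance that cannot guarantee the 1e-12
agreement with an exact enumeration oracle that the test suite demands;
scipy remains as an independent cross-check in the tests. Whether the
original convention was one- or two-sided is not recoverable; two-sided
is the standard exact choice and is what the oracle defines.

Normalization totals are the per-dataset counts of genome-mapped reads
passing the gate; raw counts remain the statistical substrate (the
Fisher margins) and RPM scaling (1e6/total) appears only in reported
fold changes, with zero→one replacement on raw counts before the ratio.
Benjamini–Hochberg q-values are reported next to raw p-values, adjusted
separately over the gene family and the intron family of each dataset
pair. Replicates are not modeled; each dataset pair is tested
separately, so the test detects differences in proportions, not
biological variability.

## Synthetic data

The generator is first-class, tested code; all randomness flows from one
integer seed through one `numpy` generator, and reruns are
byte-identical. It emulates: multi-exon genes with canonical GT..AG
introns planted into a random genome; overlapping antisense gene pairs;
paralogous gene copies at a configurable identity; un-annotated GT..AG
introns carved inside annotated exons with a fixed number of
junction-spanning supporting reads; barcoded, adapter-flanked,
optionally antisense-emitted reads; all-low-quality reads for the
trimming path; and per-gene abundance weights with planted fold factors
between datasets.

Choices worth knowing:

* **Antisense pairs are single-exon genes** overlapping by a window
  (default 400 nt of 900 nt genes, 10–20 dedicated window reads per
  gene). A window read is then transcript-compatible with *both* genes,
  so nothing except orientation (or policy) can separate them — the
  sharpest possible class I instance. Multi-exon pairs would let the
  confidence tier leak information and blur the orientation test.
* **Identity-1.0 paralog pairs emit two SAM records per read** (NH=2) at
  homologous coordinates, emulating an aligner reporting both hits;
  diverged copies emit one. Both copies keep canonical intron motifs.
* **Substitution errors only** (default 0): truth CIGARs stay exact and
  the truth SAM is correct by construction. Indel robustness is out of
  scope.
* **Planted DE in read simulation is a weight multiplier** within a
  fixed read total, so the realized RPM fold depends on composition (it
  converges to the planted factor as the gene count grows). For
  count-level DE studies, `simulate_de_counts` instead plants *absolute*
  expected counts: 10 genes at 100 vs 25 expected reads (a 4× RPM fold
  at equal totals of 1e5) among 200 null genes at 20 vs 20, the
  remainder of the probability mass going to an unreported background
  bucket. The null tier at 20 was fixed by design-time power analysis:
  it represents low-to-moderate background expression and keeps the
  expected number of null false discoveries per run well below one at
  the q < 0.01 working threshold.

What passing tests on this generator show — and what they do not: the
engine's bookkeeping (tag logic, cascade, junction identity, conservation)
is exact on reads whose alignments are correct, and its statistics
behave as designed on multinomial counts. Real data add alignment
errors near junctions, indels, soft-clipped adapter residue, non-uniform
coverage and overdispersion between replicates; none of these is
emulated, so recovery rates on real libraries will be lower than the
100% figures the truth-table tests report.

## Problem sizes and numerics

The shipped test suite and the acceptance script use desk-scale studies
(50–100 genes, 2 000–5 000 reads per dataset, 20-seed DE batches,
exhaustive Fisher enumeration over all margin pairs up to 60); the
whole suite runs in well under a minute on one core. Exact integer
arithmetic makes the Fisher path independent of problem scale up to the
caching of binomial coefficients (`math.comb` memoized per (n, k)).
Degenerate inputs are contracts, not silent fixes: empty candidate
lists, counts above totals, exons without parents and intron ends past
the chromosome all raise with the offending object named. Ordering
rules (descending support with locus tie-break for introns, p-value
then feature id for DE tables, gene id for assignment output) make
every output file deterministic.

## Known limitations

Paired-end reads are not supported (they can be analysed as single
ends). No probabilistic/EM reallocation of multi-mappers, no dispersion
modeling, no intron-retention calls, no SNP calling, no transcript
assembly. Annotation must provide exon structure in the GFF/GTF; the
engine does not map transcript sequences itself.
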