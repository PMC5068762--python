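# Methods

`broaddomain` analyses the upper tail of an H3K4me3 peak-length distribution
("broad domains") downstream of broad-peak calling. This note records the
statistical procedures, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions.

## Coordinate and overlap conventions

All intervals are 0-based half-open (BED). Two intervals overlap iff they
share at least `min_bp` bases (`min_bp = 1` by default, the BEDTools
convention); abutting intervals do not overlap. Peak-to-anchor distances are
measured from the peak midpoint `floor((start + end) / 2)` and signed in gene
orientation (negative = 5' of the TSS). Midpoint rather than edge distance
matches the convention of the common peak-annotation tools; chromosome names
are matched verbatim, because silent `chr` aliasing corrupts cross-species
joins. Browser-style 1-based fully-closed input can be read with
`one_based=True`; internally a single convention prevents off-by-one drift.

## Breadth selection

`select_broadest` uses the nearest-rank percentile: the cutoff is the
`ceil((1 - f) * n)`-th order statistic of the lengths and membership is
*strictly greater than* the cutoff, with all ties excluded. With `f = 0.05`
this lands at or just below 5% of the universe (realized fractions of
4.99%-5.00% on heavy-tailed length distributions), and it is deterministic.
Alternative percentile estimators differ by at most a couple of peaks at
cohort scale. Selection is scale-equivariant and nested: the top 1% is a
subset of the top 5%.

## Cell-type specificity and enrichment

A peak is cell-type specific when no peak of any other cell type's pooled
set overlaps it (presence/absence; quantitative differential binding is out
of scope). Enrichment of specificity among the broadest peaks is the rate
ratio `(a/b)/(c/d)` (a/b specific/total among the broadest, c/d among all
peaks), tested two-sided with Fisher's exact test on `[[a, b-a], [c, d-c]]`
(scipy). The sample odds ratio is reported alongside. On the published
cohort tables this reproduces the 1.9- and 2.2-fold enrichments from
(743/1428 vs 7879/28573) and (606/1259 vs 5412/25212).

## Shuffle null

`shuffle_intervals` re-places each peak uniformly in `[0, L - length]` on
its own chromosome (default) or on a chromosome drawn proportional to its
placement capacity `L - length + 1`, which makes the cross-chromosome null
uniform over all valid genome-wide placements. Lengths are preserved
exactly; shuffled intervals may overlap each other — no rejection step, so
the null stays exactly uniform. The association test counts query peaks
overlapping the reference (each query peak at most once), compares with
`n_perm` shuffles of the query set only, and reports
`p = (1 + #{permuted >= observed}) / (1 + n_perm)` (add-one estimator; p is
never 0 and never below `1/(n_perm + 1)`) and fold = observed / mean
permuted count. This is a deliberate simplification of segment-association
tools that correct for gene density, isochore/GC content and chromosomal
segments: against real annotation tracks the enrichment folds will differ
from such corrected nulls, and conclusions about GC-confounded tracks should
not be drawn from this null.

## Annotation

Gene models are a reduced refFlat-style table (gene id, chromosome, strand,
TSS, transcription end, exon blocks). Each peak is classified against its
nearest gene (smallest absolute midpoint-to-TSS distance; equidistant ties
break lexicographically by gene id) with fixed priority
promoter-TSS > TTS > 5'UTR > exon > intron > 3'UTR > intergenic, with
promoter window +/-4 kb and TTS window +/-1 kb by default. Without CDS
coordinates the UTR categories are unresolvable and fold into "exon".
TSS-window fractions are monotone non-decreasing in the window by
construction.

## Conservation

Species peak sets are consumed pre-mapped into one reference frame
(liftOver itself is out of scope). `shared_across` keeps peaks of the first
set overlapped in every other set (simultaneous, not pairwise-then-merged,
intersection); `conservation_summary` reports the percentage of those
shared peaks matching the human broadest set.

## Network topology

The gene network is an undirected simple graph (directed input is
symmetrized, self-loops dropped). On the largest connected component, for
every node: degree; stress (number of shortest paths between other node
pairs passing through the node, unordered pairs); betweenness (pair-averaged
fraction of shortest paths through the node, normalized by `(n-1)(n-2)/2`);
eccentricity; and mean shortest-path distance — all on unweighted hops,
computed in one Brandes-style dependency pass per source. Group-vs-rest
comparison uses the two-sided Wilcoxon rank-sum test: exact null when both
samples are tie-free and the smaller has <= 10 members, otherwise the
normal approximation with tie and continuity correction. The exact
small-sample path exists because the normal tail is too coarse below ~10
observations per group (deviations ~0.02 from the permutation p).

## Paired compartment expression test

Per gene, FPKM is averaged across subjects separately for gray and white
matter (only subjects contributing both compartments); the two-sided
Wilcoxon matched-pairs signed-rank test is then taken over genes, dropping
zero differences. Exact null for <= 25 tie-free nonzero differences, normal
approximation with continuity and tie correction otherwise. The effect
summary is the median log2(gray/white) with pseudocount 0.1. Fewer than two
nonzero differences is reported as "no signal" rather than p = 1. Sample QC
is the pairwise Spearman rank correlation over any samples x features
matrix; `peak_coverage_features` builds a read-free feature matrix (peak-bp
per gene +/-4 kb) so the QC runs without alignment data.

## Synthetic data generator

The generator emulates the study conditions so the whole pipeline is
testable offline:

* **Genome** — 5 chromosomes x 10 Mb. Small enough for seconds-scale
  permutation testing, large enough that placement is easy. For
  20,000-peak runs (used for enrichment-recovery checks) the genome is
  scaled to 5 x 30 Mb so the peak footprint stays a small fraction of the
  genome.
* **Lengths** — log-normal body (median 1.2 kb, sigma 0.45 log-bp) with a
  5% broad tail (median 5.3 kb, sigma 0.28), calibrated so the all-peak
  mean is ~1.5 kb and the top-5% mean ~5.2-5.4 kb (a ~3.6-fold breadth
  ratio), the magnitudes typical of neuronal H3K4me3.
* **Placement** — peaks occupy non-overlapping slots along each chromosome
  (Dirichlet-split random gaps with a minimum gap larger than twice the
  re-detection jitter), so presence/absence logic is exact by construction.
  Infeasible fills raise before generation.
* **Cohorts** — two replicate NeuN+ cohorts share one master locus list;
  each re-detects loci with length-preserving positional jitter (<= 150 bp,
  capped at a quarter of the peak length) and drops 15% of broad peaks.
  Length preservation keeps breadth ranks stable across replicates, which
  is what makes planted parameters recoverable through each cohort's own
  top-5% selection.
* **Specificity** — planted conditional on realized breadth rank: peaks in
  the union of the master and both cohorts' top-5% classes are specific
  with probability `rho * f`, the remainder with the rate that keeps the
  overall specific fraction at `f` (default f = 0.25, rho = 2). Counts are
  planted exactly (sampling without replacement), not per-peak Bernoulli,
  so recovered enrichment is free of planting noise. Non-specific peaks get
  an overlapping counterpart in at least one other cell type; other cell
  types also carry their own peaks in inter-locus gaps.
* **Genes** — 85% of broad-class peaks get a TSS within +/-3 kb of their
  midpoint; the rest are kept gene-free within a 4.5 kb guard zone, so the
  planted TSS-proximity fraction is recoverable to within sampling noise.
  Background genes anchor at typical peaks.
* **Species** — non-human species share `n_shared` loci (default 500), of
  which 24% are drawn from the human broadest set and the rest from fresh
  inter-peak loci; species-only extras occupy per-species disjoint gaps so
  no locus is shared by accident. Pseudo-liftOver noise is a <= 200 bp
  shift.
* **Network** — preferential-attachment growth (new node attaches to `m`
  existing nodes with probability proportional to degree + 1 from an
  `(m+1)`-clique seed); the earliest nodes are the planted hub group.
* **Expression** — per-gene log2 baseline N(3, 1.5), per-subject random
  effect N(0, 0.3), N(0, 0.5) sample noise, and a +1 log2 shift in gray
  matter for target genes over 6 subject pairs.

What the generator does **not** emulate: read-level noise, non-uniform
peak-length autocorrelation along chromosomes, GC/gene-density confounding,
mapping asymmetries between species, or network edge uncertainty. Passing
recovery tests therefore demonstrates the correctness of the statistics and
plumbing under the planted model, not robustness to those real-data
complications.

All randomness flows from a single seed through named substreams
(SeedSequence spawning), so every stage is individually reproducible and a
fixed seed yields byte-identical output files.

## Problem sizes used in the shipped checks

Default universe: 8,000 peaks per cohort on 50 Mb, ~400 broad peaks, 500
shared species loci, 1,000-node network, 6 expression pairs — the chained
pipeline runs in a few seconds. Enrichment recovery uses 20,000 peaks on
150 Mb. Permutation calibration uses 2,000 repetitions of a 200-query /
500-reference test at n_perm = 199 with dense (5 kb) peaks so the overlap
count is non-degenerate; sparse configurations tie at zero overlap and make
the empirical p conservative by construction.

## Known limitations

* The shuffle null is chromosome-constrained uniform placement only; no
  gap/assembly masks and no composition corrections.
* Specificity is presence/absence at 1 bp; a reciprocal-overlap fraction is
  not currently applied to the published-count reproductions because the
  upstream toolchain's default is 1 bp.
* The annotation model is transcript-unaware (one TSS/TES per gene) and
  cannot resolve UTRs without CDS bounds.
* Stress centrality is reported as an integer count; on graphs with ~10^4
  nodes the per-source accumulation is exact but O(nm) in pure Python, so
  very large networks are slow.
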