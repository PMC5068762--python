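# broaddomain

Analysis of **broad H3K4me3 chromatin domains** — the upper tail (top 5% by
base-pair length) of a trimethyl-H3K4 peak-length distribution. Typical
H3K4me3 forms sharp ~1-1.5 kb peaks at active promoters; the rare peaks
that stretch across many kilobases mark cell-identity genes, and in sorted
neuronal (NeuN+) chromatin they are enriched for cell-type-specific
regulation, TSS proximity, cross-species conservation and central positions
in gene-regulatory networks. `broaddomain` implements the statistics of
that analysis as a tested, reusable pipeline operating downstream of a
broad-peak caller, for epigenomicists who have peak BED files, a gene
table, an expression matrix and a network edge list — no read-level data
required.

## What it computes

* **Breadth ranking** — nearest-rank percentile selection: with lengths
  `l(1) <= ... <= l(n)` and fraction *f*, the cutoff is `l(ceil((1-f)n))`
  and peaks strictly longer are selected (ties excluded), so the realized
  fraction lands at or just under *f*.
* **Cell-type specificity** — a peak is specific when no other cell type's
  pooled peak set overlaps it (>= 1 bp, half-open intervals). Enrichment
  among the broadest peaks is the rate ratio `(a/b)/(c/d)` with a two-sided
  Fisher exact p on `[[a, b-a], [c, d-c]]`.
* **Shuffle null** — length-preserving uniform re-placement of intervals
  within chromosomes; empirical overlap association with fold
  `observed/E[shuffled]` and add-one p
  `(1 + #{perm >= obs}) / (1 + n_perm)`.
* **Annotation** — peak classification against the nearest gene
  (promoter-TSS > TTS > exon > intron > intergenic; +/-4 kb promoter
  window) and TSS-window proportion curves.
* **Conservation** — simultaneous intersection of pre-mapped species peak
  sets and the percentage matching the human broadest set.
* **Network topology** — degree, stress, normalized betweenness,
  eccentricity and mean shortest-path distance per node (unweighted hops,
  Brandes-style pass), with Wilcoxon rank-sum group-vs-rest comparison.
* **Paired expression** — Wilcoxon matched-pairs signed-rank test of gray-
  vs white-matter means over genes, plus Spearman sample-correlation QC.
* **Synthetic universes** — a generator that plants every parameter above
  (length mixture, specificity enrichment rho, TSS proximity, conservation
  fraction, network hubs, expression effect) and writes a truth manifest,
  so the full pipeline is exercisable and checkable offline.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Published count tables reproduce directly through the statistics:

```python
>>> from broaddomain import specificity_enrichment, ConservationSummary
>>> res = specificity_enrichment(743, 1428, 7879, 28573)   # cohort 1
>>> round(res.fold, 1), res.p_value < 2.2e-16
(1.9, True)
>>> round(specificity_enrichment(606, 1259, 5412, 25212).fold, 1)  # cohort 2
2.2
>>> round(ConservationSummary(544, 131).percent_matched)
24
```

The broadest 5% of neuronal peaks are 1.9-2.2x more likely to be
neuron-specific than the average peak, and 24% of the cross-species shared
broad peaks match the human broadest set.

The chained pipeline on a synthetic universe (simulate -> broadest ->
specificity -> shuffle test -> annotate -> conserve -> netstats ->
expression):

```bash
$ broaddomain all --seed 1 --out-dir runs/demo --n-perm 999
{
  "specificity_fold_cohort1": 1.9805471465410922,
  "planted_rho": 2.0,
  "tss_fraction_4kb": 0.851010101010101,
  "planted_tss_fraction": 0.85,
  "conserved_percent": 23.98989898989899,
  "planted_conserved_percent": 23.98989898989899,
  "hub_degree_ratio": 4.333333333333333,
  "hub_degree_p": 1.2162211606916024e-13,
  "gray_white_p": 1.798207435892475e-66,
  "cohort_overlap_p": 0.001
}
```

Reading the output: the planted specificity enrichment (rho = 2) is
recovered as a 1.98-fold excess; 85.1% of the broadest peaks sit within
4 kb of a TSS (85% planted); 24.0% of cross-species shared peaks match the
human broadest set; the planted hub genes have 4.3x the median degree of
the rest (rank-sum p ~ 1e-13); gray-matter expression of broad-domain
genes exceeds white matter (signed-rank p ~ 1e-66); and the two replicate
cohorts' broad specific peaks overlap far beyond the shuffle null
(empirical p = 0.001, the add-one floor at 999 permutations).
`runs/demo/sim/` holds the BED/TSV inputs and `truth.json` the planted
values; `results.json` holds every stage's full output.

Individual stages are also subcommands over plain files, e.g.

```bash
broaddomain broadest --bed peaks.bed --fraction 0.05 --out top.bed --summary summary.json
broaddomain shuffle-test --query top.bed --reference enhancers.bed \
    --genome genome.chrom.sizes --n-perm 1000 --seed 7 --out perm.json
```

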