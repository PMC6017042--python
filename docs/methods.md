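# Methods

## The scan model

`bsrscan` assumes a bulked-segregant RNA-seq design on a de novo
transcriptome: four sequencing pools — male parent T01, female parent T02,
and two bulks T03/T04 of phenotypically extreme F1 individuals — with SNPs
called per unigene and summarized as per-pool counts of A/C/G/T reads.
Because the coordinate system is the unigene set rather than chromosomes,
no sliding-window or loess smoothing of the signal is attempted; evidence
is aggregated per unigene instead.

The per-SNP statistic is the Euclidean distance between the bulks' base
frequency vectors. Frequencies (not depths) make the statistic invariant
to depth differences between the pools; the ED^k transform (default k = 5)
is monotone, so it changes no ranking, only the visual contrast between
background and signal. Candidate status is decided by comparing a
statistic against a fixed threshold, default 0.74 applied to raw ED.
The threshold is treated as a plain tunable parameter: 0.74 lies inside
the raw-ED range [0, sqrt(2)], whereas 0.74 on ED^5 would correspond to
raw ED ~ 0.94, so the raw scale is the default and
`threshold_on='ed_powered'` is available for users who want the transform
thresholded instead. The comparison is inclusive (>=): a knife-edge
equality should not flip with float rounding. Per-unigene enrichment is
the upper-tail hypergeometric probability of the unigene's Y candidates
among its N SNPs given K candidates among M filtered loci genome-wide,
followed by Benjamini–Hochberg adjustment across all tested unigenes
(including those with Y = 0) and a strict FDR < 0.01 call.

## Filtering

Filters run in a fixed order and their counts are reported per stage:

1. **Read support** (default 3): every pool must reach the minimum total
   depth, because the ED needs defined frequencies in both bulks and the
   Mendelian filter needs parental frequencies. `support_scope='bulks_only'`
   relaxes the requirement to T03/T04.
2. **Parent-discrepant**: a locus is removed when a bulk shows an allele
   not drawable from the parents. The default pairing `both_parents`
   checks each bulk against the union of both parents' observed alleles —
   the weakest assumption that is always valid for an F1 and therefore the
   one that never over-filters; `as_printed` (T03 vs T01, T04 vs T02) and
   `phenotype_matched` (T03 vs T02, T04 vs T01) are provided for users who
   want a single-parent pairing.
3. **Bulk-consistent**: removed when the bulks have identical observed
   allele sets and ED < 1e-6 — such loci carry no mapping information.
   The epsilon exists only to absorb float noise in exactly-equal
   frequency vectors.

An allele is "observed" when its frequency reaches the minor-allele floor
(default 0.1). The floor absorbs sequencing error without a base-quality
model; at the default it tolerates up to ~10% miscalls per pool, and it is
configurable for datasets with different error characteristics.

## Numerical choices

* The hypergeometric tail is computed by exact integer/rational arithmetic
  for M <= 1,000 (the upper tail summed directly, avoiding 1 - (1 - tiny)
  cancellation) and by scipy's log-space survival function above; both are
  clamped to [tiny, 1] where tiny is the smallest positive double. A tail
  probability of exactly 0 is never emitted — it is impossible for finite
  M — and clamped rows carry a `p_underflow` flag.
* BH adjustment is the standard step-up with monotone enforcement from the
  largest rank; tied p-values share their block's value. It is checked
  against statsmodels in the test suite.
* Canonical output order is unigene id lexicographic, then position
  ascending; with fixed `%.10g` float formatting this makes result files
  byte-stable for identical input and configuration.
* Indels and multi-nucleotide variants in VCF input are skipped and
  counted, never converted; positions are 1-based inclusive everywhere.

## The synthetic data generator

`simulate_dataset` emulates the statistical structure of the study design
rather than reads: at every SNP one parent is heterozygous ref/alt and the
other homozygous ref (pseudo-testcross), so a bulk's expected alternate
allele frequency is 0.25. Realized bulk frequencies are binomial draws of
2 x `bulk_size` chromosomes (default bulk size 20 individuals) around that
expectation — finite-bulk sampling is the dominant null variance of ED and
must be present for realistic false-positive behaviour. Causal unigenes
shift the two bulks' expectations apart by ±`causal_divergence`/2 (clipped
to [0, 1]); divergence is flat within the causal unigene because no
linkage map exists on a transcriptome to model decay with distance. Read
depths are Poisson per pool (default mean 50) and base calls multinomial
on the true frequencies perturbed by a uniform miscall error (default 1%).

Randomness is counter-based: each unigene owns a Philox substream keyed by
`(seed, unigene index)` with a fixed draw layout, so datasets reproduce
exactly across runs and platforms and appending unigenes does not shift
the draws of existing ones. Per-unigene (rather than per-locus) substreams
were chosen so draws within a unigene vectorize; this keeps a
100-replicate experiment at the default problem size (1,000 unigenes x 5
SNPs) under a minute on one CPU.

What the generator does *not* model: linkage decay, locus-specific error
rates, mapping bias toward the reference allele, overdispersed depths, and
correlated loci within a unigene haplotype. Passing recovery tests on this
generator therefore demonstrates that the pipeline's statistics behave as
designed under clean segregation and sampling noise — not that the fixed
0.74 threshold is optimal for any particular real dataset.

`inject_filter_fodder` replaces chosen fractions of loci with the three
removable classes (sub-threshold depth, an allele absent from both
parents, exactly-equal bulk vectors) and relabels the truth table, so
filter recall is measurable; in the noise-free regime recall is exactly 1
for all three classes under the `both_parents` pairing.

## Expression helpers

FPKM is `count * 1e9 / (length * library_fragments)` on fragment counts;
the effective-length convention is the caller's (plain transcript length
is accepted through the same field). The DEG screen retains genes with
FDR < 0.01 and fold change >= 2 in either direction, partitioned into
up/down relative to the first-named group. 2^-ddCt uses a single reference
gene; geometric averaging over multiple reference genes is out of scope.
Ct values outside (0, 45) cycles trigger a warning, not an error.

## Problem sizes and verification

The acceptance checks run the study design at 1,000 unigenes x 5 SNPs per
unigene with one causal unigene, 100 replicates for both the recovery and
the null experiment — sizes at which the binomial/Poisson structure of the
generator is fully expressed while a complete verification pass stays
under two minutes on a single CPU. The hypergeometric implementation is
compared against exhaustive PMF enumeration for every valid (M <= 30, K,
N, y) combination (~1.3e5 cases), and the BH adjustment against an
independent reference on 1,000 random p-vectors of lengths 1–500.

## Known limitations

* The 0.74 threshold's provenance is opaque (fixed constant, not a
  quantile of the null); users with genome-scale data may prefer a
  permutation-calibrated threshold, which this package does not provide.
* The per-unigene hypergeometric test conditions on K and M and ignores
  depth differences between loci; very low-depth candidate loci and
  very deep ones count equally.
* The DE model behind fold-change/FDR tables (e.g. empirical-Bayes count
  models) is upstream of this package; `deg_screen` only applies the
  thresholds to an existing table.
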