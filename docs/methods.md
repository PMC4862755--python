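# Methods

This note documents the statistical models implemented in `subloci`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Coordinate conventions

Interval annotations (BED) are 0-based half-open; variant positions in
tables are 1-based (VCF-like). A SNP overlaps an interval iff its single
base lies inside it — no padding. All readers/writers round-trip these
conventions and the tests assert agreement with linear-scan oracles.

## Locus construction

A locus is a lead SNP plus all SNPs with r² strictly greater than 0.8
(partners at exactly 0.8 are excluded). r² is computed from haplotype
frequencies, r² = D²/(p_A(1−p_A)p_B(1−p_B)), when a haplotype matrix is
supplied; a precomputed pairwise table bypasses estimation, with absent
pairs treated as r² = 0. Loci whose leads are in LD are merged; a member
shared between two non-merged loci is assigned to exactly one uniformly
at random (seeded), so output loci are disjoint.

Independent sub-threshold loci are defined by restricting to p < 10⁻⁴
and pruning at r² > 0.2. The pairwise rule — remove the weaker-p SNP of
any correlated pair — is realized as the standard greedy clumping: sort
by (p ascending, id), keep a SNP iff r² ≤ 0.2 with every SNP already
kept. This is order-deterministic and matches exhaustive pairwise
pruning (property-tested on permuted inputs). Ties in p break
lexicographically by SNP id. The ±1 Mb exclusion around known loci is
inclusive (≤ 1 Mb removed), the conservative reading of "within 1 Mb".
Candidate causal members of a locus are those whose −log₁₀ p is at least
80% of the locus maximum (equality retains).

## Matched-control permutation enrichment

The observed statistic is the number of loci with ≥ 1 member SNP inside
≥ 1 annotation interval; a locus counts once however many members
overlap. The null resamples, per test lead and permutation, one control
lead uniformly from the pool of array SNPs matching every covariate
window — LD block size ±5 SNPs, MAF ±0.1, nearest-gene distance ±25 kb
(only when the lead is outside a gene), gene count within ±500 kb ±3 —
and expands it by the same r² > 0.8 rule. Sampling is with replacement
across permutations and independent per lead; matching is genome-wide.
GC-content matching is not applied. z uses the sample standard deviation
(n−1); the empirical p carries the +1 correction and is never zero. A
zero-variance null is flagged degenerate (z reported 0 at equality, ±inf
otherwise).

The motif variant counts loci containing a member SNP inside an enhancer
that also falls within a motif instance of an expressed TF (RPKM > 1 in
the reference tissue). "Disruption" is positional overlap with an
instance, not an allele-specific score change — a deliberate
simplification, flagged to users. The shuffled-motif negative control
re-maps instances to uniform random positions preserving instance count
and lengths; with no genome sequence in the synthetic setting this
realizes "shuffled and re-mapped" at the positional level.

Calibration: with annotations assigned at random, empirical p is uniform
up to the discreteness of the count statistic. Calibration holds when
test leads are independent signals (one per LD block); drawing two test
leads from one block correlates their overlap indicators and inflates
the observed variance relative to the per-lead-independent null. The
acceptance checks therefore sample one lead per block, mirroring the
merged, disjoint locus catalog the enrichment is designed for.

## Enhancer features

Signal scores are per-base means over the enhancer with bases absent
from the (bedGraph-sparse) track counted as 0. Group comparisons report
the ratio of medians (foreground/background) and a two-sided
Mann–Whitney p — exact enumeration when n₁·n₂ ≤ 400 and the pooled
sample is tie-free, tie-corrected normal approximation with continuity
correction otherwise.

Tissue-specific methylation calls require the reference tissue to differ
from the mean of the comparison tissues by **both** ≥ 2 sample standard
deviations (computed over the comparison tissues only) and ≥ 15
percentage points; both thresholds are inclusive.

Conservation uses the 100-bp window of each enhancer with greatest mean
score (1-bp step, leftmost tie, whole-enhancer fallback for short
enhancers). The group statistic is the median best-window score of the
foreground, compared against null sets that sample one background
enhancer within ±1 kb of each foreground enhancer's length — longer
enhancers are mechanically favored in a best-window statistic, so size
matching is essential.

## Enhancer–gene linking

Candidate targets of an enhancer are genes with TSS within ±500 kb of
the enhancer midpoint (midpoint-to-TSS is the single well-defined
distance per pair) and expression ≥ 1 RPKM in both the reference tissue
and the differentiated-cardiomyocyte column. Tissues are split by
presence/absence of the enhancer (≥ 1 bp overlap with that tissue's
calls) and a one-sided rank test asks whether the gene is more expressed
where the enhancer is active; p < 0.05 links. All-active or all-inactive
splits are skipped with an explicit reason — every candidate is linked,
not linked, or skipped-degenerate. Rank-test p-values are invariant to
monotone transformations of expression, so RPKM vs log-RPKM is
immaterial. The nearest-gene baseline returns the k nearest TSS within
1 Mb, optionally expression-filtered, ties lexicographic.

## Allelic imbalance

A sample is heterozygous at a SNP when reads carrying each allele map to
≥ 3 unique positions (read alignment itself is out of scope; counts are
inputs). SNPs with strictly more than 21 total reads receive an exact
two-sided binomial test against 0.5 — doubled smaller tail capped at 1,
identical to the minimum-likelihood rule at p₀ = 0.5 (verified against
full enumeration for n ≤ 30). BH correction is applied across the
family of heterozygous enhancer-overlapping SNPs.

## 4C-seq peak calling

Coverage is smoothed with a centered running mean over 21 fragment ends,
truncated (not padded) at profile edges. Upstream and downstream of the
viewpoint are fitted independently with least-squares non-increasing
(isotonic) regression of smoothed signal on distance — contact
probability decreases monotonically in an unstructured fiber. Residual
distributions are pooled per side, matching the independent fits, and
fragends with residual > Q3 + q·IQR (q = 5.0) are significant;
consecutive significant fragends merge into one peak (no gap tolerance).
Significance is scale-equivariant: rescaling counts rescales residuals
and threshold together. Peaks intersecting a strand-aware promoter
window (TSS plus 2.5 kb upstream) within ±500 kb of the viewpoint are
reported as enhancer–promoter interactions. Non-unique fragends are
assumed removed upstream.

## Power / cohort projection

The association z-statistic is modeled Normal(NCP, 1), NCP ∝ √n. From a
current power β at two-sided level α: NCP = z_{α/2} − Φ⁻¹(1−β)
(neglecting the far tail), the target NCP for power β* is z_{α/2} +
Φ⁻¹(β*), and n_req = n·(NCP_target/NCP_current)². With α = 5×10⁻⁸,
β = 12.76%, n = 68,900 and β* = 80% this gives n_req ≈ 146,644 (≈146.6k;
the third significant digit is sensitive to rounding of the input
power). The implied NCP ≈ 4.313 reproduces the 12.76% detection rate in
Monte-Carlo simulation, closing the loop between the generator's planted
signals and the projection. A `bayes_interval` helper (uniform-prior
equal-tailed Beta posterior) is provided for proportions but is not
calibrated to any particular published interval, whose prior is
unstated.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the conditions under which the test suite
and acceptance checks run:

- **Genome**: 2 chromosomes × 10 Mb; 4,000 SNPs uniform over the
  interior, with a 500 kb SNP-free margin at each chromosome end so
  every SNP sees a full ±500 kb gene window (genotyping arrays carry no
  probes in such margins; without this, edge SNPs have covariate values
  so rare that matched-control sampling starves at desk scale).
- **Genes**: 160 per chromosome on a jittered grid (spacing ~62 kb).
  The grid keeps nearest-gene distances within the ±25 kb matching
  window's reach; gene deserts wider than the window would again starve
  the sampler. Alternating SNPs are "on array".
- **LD**: exchangeable blocks — all pairs within a 20 kb block share one
  r² (0.9 by default), zero across blocks. This makes exact oracles for
  expansion (r² > 0.8) and pruning (r² > 0.2) trivial, at the cost of
  realism (no distance decay within blocks, no inter-block leakage).
- **GWAS**: z ~ Normal(NCP, 1), two-sided p. Planted leads carry the
  stated NCP; block partners receive r·z_lead + √(1−r²)·ε (the standard
  single-causal-variant approximation, r = √r²); null blocks share an
  exchangeable z-correlation of r. Null p-values pass a KS uniformity
  check at n = 10⁴.
- **Tissue panels**: 59 tissues; every enhancer is active in the
  reference tissue and shared with each other tissue with probability
  0.3. Each enhancer up-shifts its linked gene's log₂ expression by
  3 noise SD (noise SD = 1) in active tissues. H3K27ac/DHS elevated and
  methylation depressed inside enhancers.
- **Allele counts**: Poisson depth (mean 50–60 in tests), balanced SNPs
  Binomial(depth, 0.5), imbalanced Binomial(depth, ratio); unique
  positions ~90% of reads, capped by reads.
- **4C**: Poisson counts with λ(d) = scale·(1+d)^(−exp) (200, 0.7 by
  default), fragend spacing 264 nt (the DpnII median), planted contacts
  multiply λ by a fold over a 5 kb window.

Not emulated: coalescent LD structure, genotype-level data, sequence
content (motif shuffling is positional), eQTL effects, overdispersed 4C
counts, and real chromatin-state segmentations. Passing tests therefore
demonstrate correctness of the statistical machinery and recovery of
planted effects under the stated models — not performance on real
Roadmap/1000 Genomes-scale data, whose headline counts (e.g. numbers of
loci or linked genes) depend on those datasets.

## Problem sizes

Default test and acceptance runs use 4,000 SNPs, 150 enhancers, 59
tissues, 112 test loci, 200 calibration replicates × 999 permutations,
10⁵ power draws, and 4C profiles of 1,600 fragends — sizes chosen so the
complete suite exercises every stage end to end in well under a minute
per component on a single CPU while keeping Monte-Carlo error small
relative to the tolerances asserted.
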