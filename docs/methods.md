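# Methods

`crmkit` estimates genetic relatedness between genotyped individuals from
the output sizes of a lossless compressor, embeds the resulting matrices in
standard quantitative-genetic machinery (REML variance components, BLUP
breeding values), and applies the same compression statistic in sliding
windows to detect selection signatures. This note records the models, the
numerical choices, and what the synthetic data do and do not establish.

## Compression statistics

Genotypes are alternate-allele dosages coded `0/1/2`, one ASCII byte per
locus (missing calls become `'3'` so string length is conserved). For a
byte string of raw size S_B compressing to S_A:

* **CE** (compression efficiency) = (S_B − S_A)/S_B. By default S_A is net
  of container overhead — the size of compressing the empty string under
  identical settings — because at toy scale (tens of bytes) the gzip
  header/trailer would otherwise dominate and drive CE negative. At chip
  scale the correction is negligible.
* **Het** = proportion of non-missing calls equal to 1 (heterozygous).
* **CEh** = CE / Het. Dividing by heterozygosity de-emphasises
  compressibility that comes purely from runs of homozygosity. Rows or
  windows with Het = 0 are flagged undefined (NaN), never silently zero.
* **NCD** (normalised compression distance) between strings x and y =
  (Z(xy) − min{Z(x), Z(y)}) / max{Z(x), Z(y)}, with Z the *raw* compressed
  size (container included, as the formula is written) and Z(xy) the size
  of the concatenation. DEFLATE is order-sensitive on concatenation, so by
  default both orders are compressed and averaged; the matrix is therefore
  exactly symmetric. Tiny negative values (DEFLATE shaving a byte under
  min{Z}) are clamped to 0, the metric floor.

The compressor is DEFLATE via zlib, configurable by level (1–9) and
container (`gzip` framing without filename/timestamp, or a raw stream), so
identical inputs give bit-identical sizes on any machine.

### Two hard limits of DEFLATE that shape all NCD work

1. **32 KiB history window.** A match can only reference the previous
   32 768 bytes. For strings longer than that, the second member of a
   concatenated pair cannot reference the first, so even a self–self
   distance saturates near 1. NCD is therefore only informative when the
   per-animal string (and ideally the concatenated pair) stays within the
   window — practically, up to ~16k loci per string. For larger panels,
   compute NCD per chromosome (each under the limit) or thin the markers.
2. **Bounded match search.** On a three-letter alphabet nearly every
   3-byte seed hashes to a handful of buckets, and the default level-6
   search (chain depth 128) effectively never finds matches more than a
   few hundred bytes back. Level 9 (depth 4096) does. The package default
   stays at level 6 for CE statistics, which are local and unaffected; all
   NCD-based relatedness should use level 9, and the NCD examples and
   tests do.

Both facts are asserted by tests (`test_self_ncd_small_positive_within_match_horizon`,
`test_self_ncd_saturates_beyond_match_horizon`).

## Relationship matrices

* **NRM** — pedigree expectation by the tabular method:
  a_jj = 1 + a(sire,dam)/2, a_ij = (a(i,sire_j) + a(i,dam_j))/2 in an order
  where parents precede offspring. Ancestry can be truncated at a given
  number of generations (a study choice, default unlimited); truncated
  ancestors are treated as non-inbred founders.
* **GRM** — VanRaden: ZZ′ / (2 Σ p_i(1−p_i)), where Z is the dosage matrix
  column-centred by twice the sample allele frequency. Centring is
  essential: the worked toy example's entries (0.35, 0.67, −0.67) are
  reproducible only with centred genotypes, and negative values (pairs
  less alike than HWE expectation) cannot arise from raw codes.
  Monomorphic loci contribute zero to numerator and denominator and are
  retained; missing calls are replaced by the locus mean dosage
  (equivalently, contribute zero after centring).
* **CRM1** — Shepard's distance-to-similarity law s = a·e^(−b·d) applied
  element-wise to the NCD matrix, defaults a = 2.5, b = 5. Un-scaled
  diagonal; kept mainly for comparison.
* **CRM2** — linear rescaling: diagonal mean(d_self)/d_self (averages
  exactly 1, with spread reflecting inbreeding), off-diagonal
  c·[1 − (d − Min d)/(Max d − Min d)] with c = 1.75. The Min/Max scope
  defaults to all pairs including the diagonal: because self–self
  distances are the smallest, this keeps off-diagonal values within
  [0, 0.75] on realistic data; an off-diagonal-only scope (which can reach
  1.75) is available as an option.
* **CRM3** — an NCD-free route: per-animal CE in consecutive-SNP windows
  (default 50, final partial window retained), then the product-moment
  correlation of window-CE profiles between animals (Spearman optional).
  Diagonal exactly 1. An animal whose profile is constant has no defined
  correlation; its pairwise entries are NaN and the animal is logged.
  CRM3 is invariant to permuting whole windows but not to permuting loci —
  unlike the GRM — because it reads within-window order.

`summarize_by_pedigree_class` groups any matrix's entries by the distinct
NRM values (1, 0.5, 0.25, …) and reports count/mean/SD/min/max per class.

## Mixed model

y = Xβ + Σ_r Z_r u_r + e, with u_r ~ N(0, C_r σ²_r) for each relationship
matrix C_r and e ~ N(0, I σ²_e). The restricted log-likelihood

−2 l_R = (n−p)·log 2π + log|V| + log|X′V⁻¹X| + y′Py,  V = Σ_r Z_r C_r Z_r′ σ²_r + I σ²_e

is maximised over log-variances with L-BFGS-B (bounds keep every variance
positive; a boundary estimate shows up as a vanishingly small component).
For a single random term, V is diagonalised once by an eigendecomposition
of ZCZ′, making each likelihood evaluation O(n·p²); multi-term models use
a Cholesky factorisation of the dense V per evaluation. Convergence is the
optimiser's criterion (relative likelihood change 1e-8, gradient tolerance
1e-6, 200 iterations); a fit is never reported below its starting
likelihood, and non-convergence is flagged, never silent. Rank-deficient
fixed-effect designs are reduced by pivoted QR with a warning; aliased
random terms (identical Z C Z′) trigger an identifiability warning.
Non-positive-semidefinite relationship matrices — possible for CRM1/CRM2 —
are bent (eigenvalue floor 1e-6) with a warning, or rejected if bending is
disabled.

BLUP solutions at given components: β̂ by GLS and
u_r = σ²_r C_r Z_r′ V⁻¹(y − Xβ̂), defined for every animal in C_r including
un-phenotyped relatives. When C rows sum to a constant and X contains an
intercept, each term's EBVs sum to zero.

**Missing heritability**: C_miss = 1 − σ²_u/(σ²_a + σ²_u) from a
two-component fit with the pedigree matrix (σ²_a) and one marker matrix
(σ²_u) — the fraction of pedigree-defined additive variance the markers do
not capture.

**Cross-validation accuracy**: per split a random 20 % of phenotypes is
set to missing, the model is refit on the remainder, and accuracy is the
correlation between held-out animals' summed EBVs and their phenotypes
adjusted by the *training* fixed effects (y − Xβ̂; the conventional reading
of "adjusted phenotypes"). The mean and SD over 20 seeded splits are
reported; degenerate splits are skipped with a log entry.

## Selection-signature scan

Loci are partitioned into non-overlapping windows of 50 consecutive SNPs
(the count convention is ceiling; 71 726 loci → 1435 windows). Per window
and population, the pooled genotype string (animals concatenated in id
order) is compressed; CEh is that CE divided by the window's mean observed
heterozygosity. Window FST is the arithmetic mean of per-SNP values, by
default the two-population Weir–Cockerham variance-components estimator
(observed heterozygote proportions; HWE expectations when unavailable;
negative estimates retained). Hudson and Nei G_ST are selectable. A
genome-wide `multilocus_fst` uses the standard ratio-of-summed-components
combination, since averaging per-SNP ratios is biased toward zero.
Outliers are ranked by |CEh difference| with ties broken in genomic order;
the FST rank annotates each window (rank 1 = largest). Zero-heterozygosity
windows are flagged and excluded from ranking.

## Synthetic data

The generator provides the statistical structure the methods assume, fully
determined by its seed:

* **Pedigreed populations** — founders in Hardy–Weinberg proportions with
  allele frequencies uniform on [0.05, 0.95]; offspring by Mendelian
  gene-dropping of phased haplotypes. Loci are unlinked by default (the
  0.5/0.25 sib expectations hold either way and Monte-Carlo variance is
  minimal). Options: a per-interval recombination fraction (small values
  give long IBD segments) and founder haplotypes drawn as block mosaics of
  a finite ancestral haplotype pool (simple linkage disequilibrium).
* **Diverged populations** — Balding–Nichols frequency draws at a target
  FST; a sweep region pushes population A's frequencies toward fixation of
  the locally major allele by a configurable intensity (default 0.9),
  reproducing a hard sweep's loss of diversity.
* **Phenotypes** — y = Xβ + u + e at a target heritability, with u drawn
  from a relationship-matrix covariance (or from 100 random causal loci
  when genotypes are supplied), fixed effects an intercept plus one
  3-level contemporary group, and phenotypic variance 100 (arbitrary trait
  units). Realised components are returned for oracle checks.

### What the synthetic experiments do and do not show

A finding of this package's validation worth stating plainly: **pairwise
NCD on genotype strings reads exact substring sharing, which at the
family scale means IBD2 tracts.** Full sibs (25 % of the genome IBD2)
separate strongly from everyone else under any real compressor. Half sibs
share IBD1 only; with unlinked loci and exchangeable founders their
genotype strings contain *no* compressor-visible signal, and their mean
NCD is indistinguishable from unrelated pairs (measured difference
0 ± 0.004 across DEFLATE, bzip2 and LZMA). The full-sib > half-sib >
unrelated ordering of compression relatedness emerges once the population
carries haplotype structure — linked loci (recombination fraction 0.002
between adjacent loci) and founders drawn from a 10-haplotype ancestral
pool — because then IBD1 segments do produce long exact genotype tracts
whenever the untransmitted haplotypes also coincide. That is the regime
of real livestock data (strong LD, small effective population size), and
it is the regime in which the ordering tests run. Passing them shows the
CRM2 pipeline resolves sib classes *given* haplotype structure; it says
nothing about panels of independent markers, where only the GRM carries
the half-sib signal.

The generators also do not emulate genotyping error, imputation artefacts,
ascertainment bias, or realistic chromosome-scale LD maps; conclusions
about those aspects of real data are out of reach of this test-bed.

## Problem sizes used in the standard checks

Simulation-based checks run at desk scale, chosen to keep Monte-Carlo
error well inside the stated tolerances: relatedness means use 5000
unlinked loci with 200–400 sib pairs (mean GRM within ±0.02); heritability
recovery uses 20 replicates of n = 800 animals at 2000 loci (mean
recovered h² within ±0.05 of 0.3); the compression-ordering experiment
uses 20 replicates of 39 animals at 6000 linked loci; the sweep scan uses
20 replicates of two 50-animal populations at 1000 loci with one 50-SNP
swept window. The toy worked example (5 animals × 30 SNPs) is embedded in
the package and reproduces its printed GRM entries exactly.

## Known limitations

* NCD requires per-animal strings within DEFLATE's 32 KiB window; the
  package does not yet automate per-chromosome chunking.
* The compressed-size cache is per-call; an NCD matrix at n animals costs
  O(n²) compressions (each pair, both orders).
* The REML engine targets desk-scale n (dense algebra); it is not an
  AI-REML implementation for national evaluations.
* CRM1's un-scaled diagonal biases variance-component estimates (its
  documented scaling issue); it is retained for completeness, with CRM2 as
  the recommended compression matrix.
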