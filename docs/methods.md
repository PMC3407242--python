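# Methods

This note defines every statistic the package computes, the estimators
chosen, and the conventions (sample sizes, missing data, rounding, seeding)
that make the outputs reproducible.

## Data model and quality control

Genotypes are biallelic, diploid, and unphased. Internally each genotype is
a code in {0, 1, 2} counting copies of allele B, with −1 for missing. PED/MAP
input assigns allele A to the first allele encountered for each SNP while
reading (ties within a single genotype broken lexicographically), so the A/B
assignment is deterministic for a given file. Half-missing genotypes and
loci with more than two alleles are rejected with the offending SNP named.

QC removes, in order: SNPs below a call-rate threshold (computed over all
samples), SNPs below a minor-allele-frequency threshold, then samples below
a call-rate threshold computed over the retained SNPs. The operation is
idempotent and its report records counts removed at each step.

## Drift model and simulator

Populations diverge from a common ancestor by pure drift, parameterised as
in Balding & Nichols. For a SNP with ancestral allele frequency *p*, each
population *j* draws

  p_j ~ Beta( p(1−c_j)/c_j , (1−p)(1−c_j)/c_j ),

giving E[p_j] = p and Var(p_j) = c_j·p(1−p); c_j = 0 means no drift. The
drift parameter equals the expected pairwise F_ST of two symmetric
populations (see below). Diploid genotypes are binomial(2, p_j) draws —
Hardy–Weinberg within population — with optional uniform missingness.
Ancestral frequencies are uniform on a configurable minor-allele-frequency
interval (default (0.05, 0.5)), SNPs are laid out on a configurable
chromosome map, and the full generating truth is returned for validation.

A haplotype block can be injected into a window of *m* SNPs on one
chromosome: for each population a frequency vector over the 2^m haplotypes
(indexed by binary strings, most significant bit = first window SNP,
allele A = 0) replaces the window genotypes by drawing two haplotypes per
individual from that vector. This provides known truth for the EM
estimator.

## Allele sharing and clustering

For samples *i*, *j*, IBS0/IBS1/IBS2 count loci where the genotypes share
0, 1, or 2 alleles, over pairwise-complete loci only. The sharing
similarity is

  A_s(i,j) = (IBS2 + 0.5·IBS1) / N_pairs,

a value in [0, 1] with A_s = 1 for identical genotypes. A pair with no
jointly called locus is an error, not a silent NaN. Heatmap ordering uses
average-linkage agglomerative clustering of the distance 1 − A_s.

## Principal coordinates and separation score

Classical scaling (Gower): given D = 1 − A_s, the centred Gram matrix
G = −½·J·D²·J (J the centring projector) is eigendecomposed; coordinates
are eigenvectors scaled by the square roots of non-negative eigenvalues.
The number of negative eigenvalues (non-Euclidean part) is reported, and
axis signs are fixed by making the largest-magnitude loading positive. A
direct genotype PCA with Patterson normalisation (centring by 2p̂ and
scaling by √(p̂(1−p̂))) serves as a cross-check; the two agree on strongly
structured data up to sign and scale.

The separation score of a labelled embedding is the mean silhouette
coefficient over samples in the first *d* coordinates (d = 2 by default):
+1 for perfectly separated groups, ≈ 0 for unstructured data. SNP-subset
embeddings (a random fraction, an explicit list, or the top-F_ST panel)
quantify how much marker information the observed structure requires.

## F_ST

Per SNP, with allele frequencies p₁, p₂ estimated from n₁, n₂ *called
chromosomes* (twice the called diploids):

  N̂ = (p₁ − p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
  D̂ = p₁(1−p₂) + p₂(1−p₁).

This is the Hudson-form moment estimator; N̂/D̂ is the per-SNP value and the
global estimate is the **ratio of sums** Σ N̂ / Σ D̂ across loci, which is
far less biased than averaging per-SNP ratios. SNPs with fewer than two
called chromosomes in either population, or with D̂ = 0 (jointly
monomorphic), are flagged uninformative and excluded. Under the drift model
above, E[N̂] per SNP is (c₁+c₂)·p(1−p) and E[D̂] is 2p(1−p)·(1 + O(c)), so
the global estimate recovers (c₁+c₂)/2 — the basis of the simulation
acceptance test. Uncertainty is a bootstrap over loci: SNPs are resampled
with replacement, the ratio of sums recomputed, and the SD over replicates
reported. Tables print F_ST × 100 (percent, one decimal) above the diagonal
and bootstrap SD × 1000 below.

## Outlier ranking and enrichment

The top fraction *q* of SNPs by per-SNP F_ST is selected with a ceiling
rule: k = ⌈q·L⌉ (a 49,034-SNP panel at 1% keeps 491). NaN (uninformative)
SNPs rank last; ties break by SNP identifier for determinism. Chromosome
enrichment of the selected set uses the hypergeometric tail: for a
chromosome carrying n of the L panel SNPs and k_c of the k selected,
P = P(X ≥ k_c), X ~ Hypergeom(L, n, k), alongside the observed/expected
ratio (k_c/k)/(n/L).

## Haplotype frequencies by EM

For a window of m SNPs (one chromosome), haplotype frequencies are
estimated from unphased genotypes by expectation–maximisation
(Excoffier–Slatkin). Each individual's genotype is compatible with 2^h
ordered haplotype pairs (h = number of heterozygous window SNPs); the
E-step weights pair (a,b) by f_a·f_b renormalised within the individual,
and the M-step sets f to expected haplotype counts over 2n gametes.
Individuals with any missing window genotype are excluded and counted.
The log-likelihood is asserted monotone every iteration. Because the
likelihood can be multimodal, the EM restarts from the product-of-marginals
initialisation plus Dirichlet-random starts and keeps the best final
likelihood. Tests compare against an independent direct maximiser
(softmax-parameterised L-BFGS, multi-restart) and against exhaustive
analytic solutions on tiny instances. Reports print per-population sample
size, number of estimated haplotypes above a frequency floor, named
haplotype frequencies (two decimals) and the remaining "Other" mass.

## Diversity

Gene diversity per population is the small-sample-corrected expected
heterozygosity He = 2p̂(1−p̂)·n/(n−1) averaged over SNPs with at least two
called chromosomes; Pn is the fraction of those SNPs polymorphic in the
population. Individual inbreeding F compares observed homozygosity with
its Hardy–Weinberg expectation over loci: F = (O_hom − E_hom)/(L − E_hom).

Allelic richness uses rarefaction to a common number of gene copies g: the
probability an allele with count N_i out of N copies appears in a
no-replacement draw of g copies is 1 − C(N−N_i, g)/C(N, g) (computed via
log-gamma), and Ar(g) sums this over the (at most two) alleles, averaged
over SNPs. Private allelic richness pAr(g) multiplies presence in the
focal population by the probability of absence from *independent* rarefied
draws of every other population. SNPs where any population has fewer than
g called copies are excluded (count reported); g defaults to twice the
smallest population size.

## Calibration ladder and verdict

The package ships a pairwise F_ST reference matrix over 14 recognised breed
populations (percent above the diagonal, SD × 1000 below) and defines
comparison categories over it: two selection-line pairs within one breed,
all 15 pairs among six breeds of common regional origin, two sets of pairs
involving geographically isolated breeds (6 and 14 comparisons), and a
single candidate new-breed pair. Category averages are computed from
unrounded cell values and printed with half-up rounding at one decimal:
1.7, 4.2, 11.4, 13.6 and 6.2 percent respectively — a monotone ladder from
line-level to continental-level divergence.

A candidate pairwise F_ST (percent) is classified *breed-level divergence*
iff it is at or above the recognised-breed-pair category average (boundary
inclusive), otherwise *within-breed-scale divergence*; the verdict reports
the ratios to the line-level and breed-level averages computed from
unrounded values.

## Reproducibility

All randomness flows from NumPy `default_rng` seeded explicitly. The
pipeline derives fixed per-stage child seeds from the single run seed
(simulation, block injection, subset draws, bootstrap, EM restarts), so a
given config and seed reproduce every output file byte for byte; the run
manifest records the seed, SHA-256 input hashes and per-stage outputs and
timings. Estimator correctness is enforced by oracle tests: brute-force IBS
recounts, Gower distance reconstruction, exhaustive and independent-
maximiser EM comparisons, Monte-Carlo rarefaction, exhaustive
hypergeometric enumeration, simulator moment checks, and recovery of
generating drift and haplotype parameters within sampling error.
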