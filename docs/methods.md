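# Methods

This note documents the statistical machinery behind `herddiv`, the
defaults it ships with, the choices made where the design was genuinely
open, and what the synthetic-data generators do and do not emulate.

## Setting and data model

The package targets panels of many breeds — often dozens to a hundred —
genotyped on a medium-density SNP array, with per-breed sample sizes
ranging from 4 to 50 diploids. Inputs are phased, imputed, biallelic
autosomal genotypes (phasing and imputation are upstream of this
package and out of scope); coordinates are 1-based base pairs and no
operation reorders markers. Missing genotypes are allowed only in the
pre-QC `GenotypeMatrix`; a `HaplotypeMatrix` is complete by contract.

## Quality control

The cascade order is fixed and re-running it on its own output is a
no-op:

1. sample call rate: keep individuals with non-missing fraction
   strictly above 0.95;
2. SNP call rate: remove SNPs genotyped in less than 90% of samples
   (a SNP at exactly 90% is retained);
3. MAF: remove SNPs with pooled (cohort-wide) MAF below 0.025 — pooled
   rather than per-breed, because the analysis-ready marker set must be
   a single shared panel;
4. Hardy–Weinberg: remove a SNP if the exact test gives p ≤ 0.01 in at
   least one breed with at least `min_n = 10` genotyped animals at that
   SNP.

The HWE test is the conditional exact test: given the observed allele
counts, every possible heterozygote count is enumerated with weight
(multinomial coefficient × 2^het), and the two-sided p-value sums the
probabilities of all configurations no more probable than the observed
one. An exact test is required because breeds as small as 4 diploids
are routine and the chi-square approximation is useless there. The
"fails in any sufficiently large breed" removal rule is a design
choice (any/all/majority are all defensible); `min_n` guards the
smallest breeds from deciding marker fate on a handful of genotypes,
and both `alpha` and `min_n` are configurable.

## Relatedness and inbreeding

The unified additive relationship (UAR) matrix uses centered dosages
over markers k with alternate-allele frequency p_k:

    UAR_ij = mean_k (x_ik − 2p_k)(x_jk − 2p_k) / (2p_k(1−p_k))    (i ≠ j)
    UAR_ii = 1 + mean_k (x_ik² − (1+2p_k)x_ik + 2p_k²) / (2p_k(1−p_k))

and the individual inbreeding coefficient is F_i = UAR_ii − 1. The
diagonal uses its own estimator (not the squared standardized dosage)
because it is unbiased for the within-individual allele correlation.
Centering frequencies are computed once on the full post-QC cohort, so
one genome-wide matrix covers all breeds; residual missing dosages are
mean-imputed (2p_k) and logged. F estimated this way is relative to the
cohort-wide allele frequencies: genuinely divergent outgroup taxa can
show F well above 1, which is expected behavior, not an error.

Outlier screening (mis-sampled or heavily admixed animals) works per
breed: the within-breed UAR sub-matrix is embedded by principal
coordinates (it is already an inner-product matrix), each of the top
`k_dims = 5` axes is robustly standardized by median and scaled MAD,
and the squared robust distance is compared with the chi-square(k)
upper 0.025 quantile. When the MAD of an axis collapses (near-clonal
breeds) the plain SD substitutes; an axis with zero spread carries no
signal. Breeds under 5 members are skipped and logged. The chi-square
reference is approximate for robust distances; in simulation the false
flag rate sits at or below the nominal alpha.

Relatedness pruning is a greedy loop over within-breed pairs above the
threshold (default 0.45, just under the 0.5 expectation for
first-degree relatives): remove the individual with the most
above-threshold partners, breaking ties by larger mean relationship to
its partners and then by id. Most-connected-first minimizes removals on
star-shaped family structures (one sire, many offspring). The
post-condition — no surviving within-breed pair above threshold — is
asserted in tests.

## Haplotype blocks

Blocks are runs of exactly 4 consecutive SNPs spanning < 150 kb with
every adjacent gap < 50 kb (both strict, per the rule's wording),
tiled by a greedy left-to-right scan per chromosome: if the next 4
unconsumed SNPs satisfy both constraints they become a block and are
consumed; otherwise the window start advances by one SNP. A variant
that jumps past the whole failing window is available behind a flag
(`slide=False`); greedy slide-by-one is the default because it forms
blocks as early as possible and is deterministic. Blocks never overlap
and never span chromosomes. Each haplotype's 4 alleles concatenate (map
order, first SNP most significant) into one of ≤ 16 block alleles.

## Diversity statistics

All multi-allelic statistics run on the `BlockAlleleTable`: per breed
and block, gene-copy counts of each block allele (summing to 2·Nd).

* H_E uses Nei's unbiased small-sample estimator
  (2N/(2N−1))(1 − Σp²) — essential at Nd = 4; H_O is the observed
  heterozygote fraction; the heterozygote deficit is (H_E − H_O)/H_E.
* Allelic richness rarefies each block to g gene copies:
  AR_g = Σ_u [1 − C(N−N_u, g)/C(N, g)], averaged over blocks. The
  default g = 2·min(Nd) lets every breed be rarefied to a common depth
  (g = 8 for a design whose smallest breed has 4 animals). Binomial
  ratios are computed in log space.
* An allele's identity is the (block, word) pair. Private = observed in
  exactly one breed, semi-private = exactly two (counted for both
  carriers), common = observed in all breeds; fpA is the mean
  within-breed frequency of that breed's private alleles (NaN when a
  breed has none).
* Group summaries are Nd-weighted means; a breed missing a statistic
  (e.g. Ne for small samples) drops out of that statistic's weighting
  only. This weighting scheme reproduces the published group rows of
  the packaged reference table to printed precision.
* The correlations r(F, fpA) and r(F, npA) are Pearson correlations
  across breeds and by default exclude outgroup taxa: a distant
  outgroup is an extreme outlier in both F (≈1.06 against cohort-wide
  frequencies) and npA (hundreds of species-private alleles) and
  single-handedly flips the sign of r(F, npA). With outgroups excluded
  the packaged table gives r = 0.722 and −0.213.

## Differentiation and projection

Jost's D_EST between two breeds uses sample-size-corrected components
per block, with Ñ the harmonic mean of the two diploid sizes:

    Ĥ_S = (2Ñ/(2Ñ−1)) (1 − mean_deme Σp²)
    Ĥ_T = 1 − Σ(mean_deme p)² + Ĥ_S/(4Ñ)
    D   = 2 (Ĥ_T − Ĥ_S) / (1 − Ĥ_S)

Multi-block aggregation averages the Ĥ components across blocks
(default) rather than averaging per-block D values; the mean-of-
components form is much stabler when many blocks are near-monomorphic
in a pair. The per-block-mean variant is available
(`per_locus_mean=True`). Slightly negative finite-sample estimates are
clamped to 0 and logged. D_EST is preferred over G_ST-family measures
here because block gene diversities are high (often > 0.7), the regime
where G_ST compresses toward 0 regardless of differentiation.

The allele-sharing distance between two individuals is
D_PS = 1 − mean_blocks(shared/2), where shared is the multiset
intersection size (0, 1, 2) of the two unordered allele pairs.
Classical (Torgerson) MDS double-centers −D²/2 and scales the top
eigenvectors by the square roots of their eigenvalues; the sign of each
axis is fixed by making its largest-magnitude loading positive, so runs
are reproducible although the configuration is inherently defined only
up to rotation/reflection. Breed dispersion on the 2-D plane is the SD
of members' Euclidean distances to their breed center.

## Phylogeny

Nei's D_A = 1 − (1/L) Σ_blocks Σ_u √(x_u y_u) on block-allele
frequencies (the uncorrected form; a small-sample variant could be
slotted in but is not implemented). Neighbor joining is the classical
Saitou–Nei agglomeration; ties on the Q-criterion resolve to the
lexicographically smallest taxon pair, so degenerate (ultrametric)
inputs give deterministic output. Negative branch-length estimates are
clamped to zero with the deficit transferred to the sister edge, the
standard practice. On additive input the tree reproduces the input
distances exactly (property-tested up to 8 taxa against randomly
generated trees). Rooting places a degree-2 root at the midpoint of the
outgroup's pendant edge and never changes leaf-to-leaf path lengths.

## LD-based Ne(t)

For one breed's phased haplotypes, r² is the squared Pearson
correlation of allele indicators across haplotype rows, for all
intra-chromosomal pairs 20 kb–10 Mb apart (monomorphic SNPs skipped).
Physical distance maps to recombination fraction linearly at 1 cM/Mb by
default (a Haldane option exists); the sample-size correction subtracts
1/(βn) with β = 2 for phased data from n diploids; the mutation
constant α defaults to 2 (mutation ignored; 2.2 available). Pairs are
grouped into 30 log-spaced distance bins — log spacing matches the
hyperbolic r²–c relation — and each bin's harmonic-mean c gives

    t = 1/(2c)  generations ago,   Ne(t) = (4c)⁻¹ (E[r²_adj]⁻¹ − α).

Ne_5 / Ne_50 / Ne_2000 are read from the bins whose t is nearest 5, 50
and 2000. Per-breed Ne is reported only for breeds with Nd > 8; group
Ne values are Nd-weighted means over eligible breeds. The estimator has
a known upward finite-sample bias in the most recent bins (convexity of
1/E[r²] plus noise in small adjusted r² values); in the shipped
recovery experiment (true Ne = 100, 50 replicates) the median estimate
lands within ±30% of truth. Bins whose mean adjusted r² implies Ne ≤ 0
are reported as undefined, not clamped.

## D-statistics

For (((P1,P2),P3),O) with per-SNP alternate-allele frequencies, the
population form is used:

    D = Σ (p2 − p1)(p3 − pO)  /  Σ (p1 + p2 − 2p1p2)(p3 + pO − 2p3pO)

with the sign fixed so a pure ABBA site (p1=0, p2=1, p3=1, pO=0) gives
D = +1; positive D therefore flags P2–P3 allele sharing (e.g. indicine
introgression into the tested branch when P3 is the indicine
representative). At fixed (0/1) frequencies numerator and denominator
reduce exactly to ABBA−BABA and ABBA+BABA pattern counts (tested).
Standard errors come from a weighted delete-one block jackknife over
genomic windows (default 5 Mb, beyond typical cattle LD range; window
size configurable), weights proportional to per-window site counts,
reducing to the textbook delete-one formula for equal windows. |Z| > 3
marks significance. At least 20 non-empty windows are required;
numerically zero jackknife variance reports Z = ±inf.

## Synthetic-data generators

The generators stand in for real multi-breed array data, which for this
kind of study is typically available only on request. They emulate the
study-scale design (`STUDY_DESIGN`): on the order of 100 breeds in ~10
geographic groups, 4–50 diploids per breed, tens of thousands of mapped
autosomal SNPs; tests and the acceptance script run scaled-down
versions of the same structure to stay desk-sized.

* `simulate_hierarchical`: ancestral frequencies Uniform(0.05, 0.95) —
  mimicking array ascertainment against rare variants — with per-breed
  Balding–Nichols drift Beta(p(1−F)/F, (1−p)(1−F)/F), optional
  frequency-level admixture (row-stochastic mixing matrix), and
  within-individual allele correlation equal to a per-breed inbreeding
  parameter. Markers sit on a uniform 10 kb map so haplotype blocks can
  always form. Sites are exchangeable and unlinked: this substrate
  exercises drift, admixture and inbreeding, but deliberately carries
  no LD, so it cannot test Ne estimation or within-block recombination.
* `simulate_wright_fisher`: a discrete-generation forward population of
  2·Ne haplotypes on one chromosome; each offspring haplotype is a
  gamete of a random diploid parent built by a Markov crossover-switch
  process with Haldane-mapped adjacent-site switch probabilities
  (equivalent to Poisson crossovers). Initial frequencies are
  Uniform(0.05, 0.95); at output, sites fixed in the sample are dropped
  (they carry no LD information). This is the truth-known substrate for
  Ne recovery.
* `simulate_dstat_graph`: frequencies evolve by per-branch
  Balding–Nichols drift along (((P1,P2),P3),O); with probability equal
  to the introgression fraction a site's P2 frequency is replaced by
  its P3 value. Null and power behavior of the D machinery is
  calibrated on this graph.

All randomness flows from a single integer seed; equal seeds give
bit-identical output. What passing tests on these substrates shows is
that the estimators recover the generating parameters under their own
model assumptions; real array data add ascertainment quirks, uneven
maps, genotyping error and pedigree structure that the generators do
not emulate.

## Numerical choices

* Beta draws in the generators are clipped to [1e-9, 1−1e-9] so later
  frequency arithmetic never divides by zero.
* Rarefaction and the exact HWE test work in log-gamma space.
* The D_EST clamp (negatives → 0) and the NJ branch-length clamp
  (negative → 0, deficit to sister edge) are both logged.
* MDS eigenvalues below 1e-12 of the largest are treated as
  non-positive; requesting more axes than positive eigenvalues reduces
  the dimensionality with a warning.
* PED input carries no ref/alt, so the alternate allele is the
  lexicographically larger observed allele — arbitrary but
  deterministic, and documented in the loader.
* The packaged reference table is checksummed (sha256) at load time.

## Known limitations

* The exact tiling rule of the original block definition, the original
  outlier method and relatedness cut-off, and the original D_EST
  locus-aggregation variant are not recoverable from their published
  descriptions; the implemented choices are documented above and the
  plausible alternatives are exposed behind flags (`slide`,
  `per_locus_mean`, `threshold`, `k_dims`, `alpha`).
* Ne(t) assumes a linear genome-wide recombination map by default;
  chromosome-specific maps and confidence intervals are out of scope.
* No LD-based (Gabriel-style) block definition, no model-based
  clustering, no maximum-likelihood admixture graphs, no bootstrap
  support values on trees — these are external-tool territory in the
  workflow this package implements.
* Correlations and group means computed from the packaged reference
  table inherit its printed rounding (3 decimals for most columns).
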