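# Methods

`hybridzone` implements the bespoke computations of a two-taxon hybrid-zone
genomics workflow — the kind used to characterise the far-west *Anopheles
coluzzii* / *A. gambiae* contact zone — as a tested library plus a synthetic
study that exercises every stage end-to-end. This note records the models,
the parameters that matter, and the design choices made where the design was
genuinely open.

## The synthetic study

The generator (`hybridzone.simulate`) emulates the statistical structure the
analyses assume, not the biology of any particular dataset.

**Genome.** Five arms with fixed lengths approximating the reference
assembly (X 24 Mb, 2R 61 Mb, 2L 49 Mb, 3R 53 Mb, 3L 42 Mb), one
pericentromeric island of divergence per chromosome (4 Mb on X, 2 Mb
elsewhere, placed at the centromeric end of each arm), and the four
polymorphic inversions 2Rj, 2Rb, 2Rd and 2La at approximately their
cytological coordinates. All internal coordinates are 0-based half-open;
VCF I/O converts to 1-based positions at the boundary only.

**Parental panels.** Each locus carries an allele frequency in two parental
panels, speciesA (the introgressing donor) and speciesB (the resident
species). Island loci draw from a reflected Beta pair — by default
Beta(50, 1) for the donor and Beta(1, 50) for the resident, which puts ~96%
of island loci above the 0.9 frequency-difference threshold used for marker
selection. Background loci share a single draw (Beta(2, 2) by default), so
the panels are identical outside the islands; this isolates the divergence
signal in the islands, which is the structure the enrichment and
marker-selection stages are designed to detect. Both divergence settings
also accept a single float as a point mass; `island_divergence=1.0` gives
fully fixed interspecific differences, which is what a pericentromeric
island of divergence represents and what the intact-X-tract property is a
statement about. Islands are over-sampled (25% of each arm's loci by
default) so that marker panels of a realistic size (hundreds) exist at desk
scale.

**Ancestry.** Each haplotype is a mosaic of ancestry blocks from an
alternating-exponential (Markov switch) process with state mean lengths
2·L·α and 2·L·(1−α), giving a stationary donor-ancestry fraction α; L
(`block_length_bp`) defaults to 5 Mb. The autosomal and X fractions are set
separately (`alpha_autosome` 0.7, `alpha_x` 0.1 by default), mirroring the
asymmetric-introgression signature: heavy donor ancestry on the autosomes,
little on X. `forced_island_ancestry` overwrites the island interval of an
arm on both haplotypes, emulating an introgression-resistant island; truth
records keep an exact tiling. No quantitative block length is available to
copy, so L is a free parameter: it controls the variance of per-individual
realized ancestry (long blocks, as in recent hybrids, give noisy individual
fractions; 1 Mb blocks emulate an old zone with many generations of
recombination and are used in the ordination test for that reason).

**Annotations.** Site-level MQ ~ Normal(50, 5), QD ~ Gamma(4, 5),
HRun ~ Geometric(0.7)−1; per-call DP ~ Poisson(30) and
GQ ~ min(99, round(Normal(60, 15))). These are plausible shapes chosen so
that every filter rule fires at a non-trivial rate; every distribution is
configurable, including point masses (`clean_annotation_model()` places all
annotations safely above the thresholds, which the filter contract test
uses). Note the GQ model is deliberately harsh: at 24 samples only ~10% of
sites survive the missingless reduction, so the pipeline's downstream
stages run on a few hundred sites.

**Karyotypes.** Per-inversion genotypes are drawn independently under
Hardy–Weinberg at given inverted-arrangement frequencies and composed into
labels in the conventional grammar (letters j, b, d on 2R, a on 2L, "+" for
all-standard; heterozygous letters are assigned to a random haplotype).
Labels round-trip exactly through the parser.

Everything is a pure function of the configuration; the seed fully
determines the output (verified bit-wise in tests).

**What the generator does not model** — and hence what passing tests do not
show about real data: no coalescent history, recombination map, selection or
mutation; no genotyping error beyond the annotation model; background loci
carry no interspecific divergence at all, so genome-wide drift structure is
absent; X hemizygosity in males is ignored (all individuals are diploid).

## Variant hard filtering

Thresholds: GQ < 40, DP < 14, DP < median/2 or DP > median×2 (median per
sample over all its calls, midpoint convention for even counts), MQ < 40,
QD < 5, HRun > 3. All comparisons are strict, so boundary values pass.
The annotation rules (MQ, QD, HRun) are properties of the site and remove
it entirely; the quality/depth rules are properties of one genotype and
mask only that call. A subsequent missingless reduction removes any site
with a masked or uncalled genotype in any sample. This two-stage reading
makes the filter idempotent and the rejection accounting exact: input
sites = retained sites + site-level rejections, with each removed site
counted once under the first failing rule in the fixed order MQ, QD, HRun
(masked genotypes are counted per rule in the order GQ, DP-min, DP-median).
Masking versus dropping is indistinguishable after the missingless step,
which is why the two-stage reading is safe. Multiallelic records are
excluded at VCF read time with a logged count; dosage coding downstream
assumes biallelic sites.

## Differentiation (FST)

Per site, the Weir–Cockerham (1984) two-level variance components for two
diploid population samples: a (among populations), b (among individuals
within populations), c (within individuals), from the sample sizes, allele
frequencies and observed heterozygote proportions; FST = a/(a+b+c),
undefined when the denominator is zero (sites monomorphic across both
samples). Negative estimates are retained, a numerical guard clamps the
ratio at 1, and each population must contribute at least two called
genotypes. The implementation is checked against an independent longhand
transcription of the estimator on random small cases.

Windows tile each arm from coordinate 0 in non-overlapping 50-kb spans
("stepping" read as step = width; the step is configurable). The window
summary is the arithmetic mean of defined per-site estimates, because that
is what a "mean FST" track plots; the weighted ratio-of-sums
Σa/Σ(a+b+c) is computed alongside in an extra column since tools differ on
this point. Empty windows are reported with `n_sites = 0`.

The top-q threshold is the smallest observed value whose upper set has
fraction ≤ q; when ties at the maximum make that impossible the maximum and
all its ties form the top set (the realized fraction may then exceed q).
Region enrichment classifies a window as inside a labelled region set if
its midpoint falls in a labelled interval (unambiguous for straddling
windows) and tests the 2×2 top/not-top × inside/outside table with
Pearson's chi-square, no continuity correction. A degenerate margin (all
windows inside) yields a zero statistic rather than an error. Calibration:
under random permutation of window values the test's empirical type-I
error at α = 0.05 is ~0.045 over 1000 genome-scale permutations (recomputed
in the acceptance suite).

## Ancestry-informative markers

A marker is selected when the panel frequency difference is strictly
greater than 0.9 (a difference of exactly 0.9 is excluded); the
donor-diagnostic allele is whichever allele is more frequent in the donor
panel. Markers are defined from frequency tables, not from an external chip
file, so any panel pair in the same format can drive the analysis.
Genotypes score 1 (donor homozygote), 0.5 (heterozygote), 0 (resident
homozygote); alleles matching neither diagnostic allele score missing.
Composition is summarised separately for the autosomes and X, with missing
scores excluded from denominators (stacked-bar proportions sum to 1 over
scored markers).

Tract detection finds, per individual and arm, the maximal genomic span of
markers at the target score containing at most `max_het` heterozygous
markers and no opposite-homozygote; missing scores also break runs
(conservative). Runs begin and end on a target-homozygous marker and the
span is measured marker-to-marker, not extended into flanking intervals;
ties break to the leftmost start. The implementation is verified against
exhaustive enumeration of all start/end pairs.

## LD pruning and PCA

Singletons (minor-allele count ≤ 1, monomorphic loci included) are removed
first. Pruning is greedy keep-first within windows of 500 SNPs advancing by
100 SNPs: any ordered pair of still-retained loci with squared Pearson
dosage correlation above 0.1 drops the later locus, permanently.
Zero-variance loci are uncorrelatable and treated as r² = 0 (logged).
Windows are counted in loci, per arm, so at sparse simulated densities a
500-SNP window can span a whole arm; tests that need the window to have its
real-data genomic extent scale the SNP count down accordingly.

PCA uses Patterson scaling — centre each locus by its mean dosage and
divide by √(p(1−p)), p = mean/2 — with plain centering available.
Eigenvalues come from the locus-averaged sample covariance (the genetic
relationship matrix X·Xᵀ/m), whose trace is the total scaled variance;
coordinates are the eigenvector projections scaled by √eigenvalue, with a
deterministic sign convention (the largest-magnitude coordinate on each
axis is positive, which is stable under sample permutation). No
outlier-removal iterations or eigenvalue significance statistics.

## Karyotypes as biallelic loci

A karyotype label lists phase-alternative readings ("jbd/+, j/bd, jb/d") of
one arm's arrangement pair; each inversion letter is a biallelic locus whose
inverted-copy count is the number of haplotypes carrying the letter. The
parser validates the grammar and requires all alternatives of a label to
decompose identically. The undocumented arrangement letter 'u' is treated as
unscored: in a label containing 'u', loci whose letters appear are scored
with 'u' as standard, loci whose letters appear nowhere are tallied as
unscored for that individual. Printed percentage columns are converted to
integer counts by nearest-integer rounding with a largest-remainder
fallback (warned); all four published columns (totals 12, 76, 114, 58)
round exactly without correction, and the resulting genotype tables
reproduce the published coast-versus-inland chi-squares for 2La (92.12) and
2Rb (126.28) to the printed precision. The published grouping behind the
printed 2Rd statistic could not be reconstructed from the frequency table
under the same genotype decomposition and is left unreproduced.

## Contingency and interval statistics

Pearson chi-square without continuity correction (the printed statistics
imply none was used), two-sided Fisher exact tests, and Wilson score
intervals for proportions. The published confidence intervals' method is
not stated; Wilson is used throughout and its output is close to, but not
asserted against, the printed intervals. Cluster assignment at membership
threshold T_q = 0.5: an individual belongs to the cluster with q ≥ T_q and
is "admixed" when all q < T_q; an exact tie resolves deterministically to
the lowest-index cluster with a warning. For the human blood index, mixed
meals (human plus another host) count as human-positive, since the index
measures proportionate feeding on humans; the per-group human/non-human
table feeds the cross-group chi-square.

## Problem sizes and determinism

The test suite and the acceptance script run the synthetic study at desk
scale: cohorts of 12–50 individuals, 300–600 loci per arm (~500 diagnostic
markers at the recovery settings), 1000 label permutations for the
calibration check. Every stochastic step takes an explicit seed; identical
configurations produce bit-identical outputs, which the pipeline manifest
records as SHA-256 checksums.

## Known limitations

- The estimator suite covers two populations; multi-population FST is out
  of scope.
- No probabilistic local-ancestry inference: the marker scoring is
  deterministic per site, as in the workflow it reproduces.
- Tract spans depend on marker density; with few markers on an arm the
  reported span understates the underlying ancestry block.
- The published enrichment percentages and their chi-squares (and the
  pooled marker-class comparisons) depend on the real sequence data and are
  represented here by calibration and recovery properties, not by value
  reproduction.
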