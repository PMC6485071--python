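# Methods

## Overview

`diffscan` implements a population-differentiation selection scan for
small-sample whole-genome data, together with the cross-coalescence-rate
conventions used to report divergence times between populations. The scan
is designed for settings with few diploid genomes per group — where
site-frequency-spectrum and haplotype-homozygosity methods lack power —
and therefore works entirely from per-site allele frequencies with
explicit small-sample corrections.

## The selection scan

### Per-site F_ST

For each unordered pair of meta-ancestry groups, every biallelic SNP gets
a Hudson-type per-site F_ST with unbiased within-group heterozygosity:

    F_ST = [ (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1) ]
           / [ p1(1−p2) + p2(1−p1) ]

with p the alternate-allele frequency and n the number of called alleles
(2 × non-missing diploids). The (n−1) corrections remove the upward bias
of the naive squared frequency difference at small n, which is the reason
per-site values can be negative at undifferentiated sites; those negative
values are deliberately retained, because the d statistic standardizes
each pair against its own genome-wide mean and standard deviation and
clipping would bias both moments. Sites monomorphic for the same allele in
both groups have a zero denominator and are undefined for that pair.
Allele counts are the sufficient statistic: missingness enters only
through n.

A site enters the scan only if, within *every* group, at most 20% of
genotype calls are missing. The criterion is per group, not overall.

### The d statistic

For focal group *i*, at each retained site,

    d_i = Σ_{j≠i} ( F_ST(i,j) − E[F_ST(i,j)] )² / sd[F_ST(i,j)]

where the mean and standard deviation are taken over all retained sites
for that pair. The numerator is squared; the standard deviation in the
denominator is not. The classic unsquared standardized sum
(Σ (F−E)/sd) is available behind a `squared=False` switch for comparison,
but the squared form is the default. A site is dropped for a focal group
whenever any of its pairs is undefined there; a pair with zero genome-wide
sd aborts that group's scan with a diagnostic rather than silently
producing infinities.

Outliers are sites strictly above the (1 − 0.001) empirical order
statistic of the group's defined d values — the top 0.1%; ties at the
threshold are all excluded (conservative). The percentile column reports
the percent of variants with a strictly higher d.

### LD clumping and selection windows

r² is the squared Pearson correlation of genotype dosages over
pairwise-complete samples (composite LD on unphased calls). This is a
documented deviation from EM haplotype-frequency r²; on unphased diploid
data with the modest LD of the test fixtures the two agree closely, and
all oracle tests target the dosage definition.

Clumping is greedy: candidate index variants passing the stringent cutoff
(percentile < 0.001) are visited in order of decreasing d (increasing
percentile, ties broken by lower genomic coordinate); each unclaimed index
claims as members all unclaimed variants passing the lenient cutoff
(< 0.01) within 1000 kb of the index and with r² > 0.5 to it. The tag is
the index — by construction the highest-d member. Distances are measured
tag-to-member.

Selection windows are a separate pass over the tags: for each tag, the
interval spanning all variants within 1 Mb and r² > 0.8 with it (the tag
included); overlapping intervals are merged. Intervals are emitted as
0-based half-open BED; a tag with no partners yields a 1-bp interval.
Under the half-open convention, intervals that merely touch do not merge.

### Annotation-shift enrichment

Each locus is a tag plus its strong-LD partners, with the partner span
padded by 50 kb on each side so the null has room to move; the padding
default is declared, not inferred from any external tool. A category's
observed score is the number of loci with at least one SNP inside an
annotation interval. The null preserves local annotation structure:
within each locus span the clipped annotation intervals are circularly
shifted by an independent uniform offset, and the score is recomputed;
10,000 permutations by default. The empirical P is the fraction of
permuted scores ≥ the observed one, floored at 1/n_perm — "≥" with a
floor rather than ">" because an exact-zero permutation P is invalid.
A locus whose clipped annotation covers its whole span overlaps under
every shift and is therefore shift-invariant by construction.
Family-wise error across categories is Bonferroni: 0.05 divided by the
number of categories (nine in the canonical annotation list, giving
P < 5.56 × 10⁻³).

## RCCR divergence times

MSMC-style rate tables carry time in scaled (per-site mutation) units and
rates on the matching inverse scale. With a per-year mutation rate ν and
generation time g, the per-generation rate is μ = νg; times convert to
years as t/ν and scaled rates to diploid effective sizes as (1/λ)/(2μ).
The defaults ν = 4.3 × 10⁻¹⁰ and g = 29 give μ = 1.25 × 10⁻⁸ and
2μ = 2.5 × 10⁻⁸. (Some sources describe ν as per-generation in passing;
only the per-year reading is consistent with μ = νg, and that is what is
implemented.)

The relative cross-coalescence rate per time bin is
RCCR = 2λ_cross/(λ_within1 + λ_within2): ≈1 while the two populations
still behave as one ancestral pool, →0 after complete separation.
Divergence time is the first present-to-past upcrossing of 0.5, located
by linear interpolation between bin-midpoint representative times (the
last bin of an open-ended curve is represented by its left boundary). The
0.25 and 0.75 crossings bracket the estimate, reported as
"~t50 (t75–t25) kya". Non-monotone curves report the first upcrossing and
log the rest; RCCR values above 1 (estimation noise) are retained, not
clipped; thresholds that are never crossed are reported as undefined, not
fabricated — in particular, a never-diverged pair (no split) has RCCR ≈ 1
everywhere and no crossing.

## Synthetic data

### Balding–Nichols genotypes

Each site draws an ancestral frequency p uniformly from (0.05, 0.95)
(avoiding near-fixed sites, which stabilizes per-site F_ST moments); each
group's frequency is Beta with mean p and variance p(1−p)F
(α = p(1−F)/F, β = (1−p)(1−F)/F), and genotypes are Binomial(2, q).
Missingness is independent per call. Spike-ins add a configured shift to
the focal group's frequency at randomly chosen sites (clamped to [0,1])
before genotypes are drawn; the truth table records exactly the spiked
sites with their pre- and post-shift frequencies. A single seed fans out
to per-stage substreams, so runs are bit-reproducible.

The generator has no linkage: sites are exchangeable and independent. LD
fixtures are built separately by block-copying a site's genotype column
with controlled per-call flip noise, which creates r² blocks of known
strength. Consequences for interpretation: passing tests demonstrate
correctness of the estimators and procedures under a clean exchangeable
null with known differentiation, but say nothing about background
selection, real LD structure, admixture, or call-quality artifacts in
real genomes.

Default study conditions used by the validation suite, chosen once:
6 groups × 25 diploids with per-group F = 0.03 — a typical level of
between-group differentiation for continental meta-ancestry groups, with
the per-group sample size matched to the two-group F_ST-recovery setting
(25 diploids, F = 0.1, 50,000 sites).

### Clean-split pair coalescent

Within a deme, a pair of lineages coalesces at rate 1/(2N_deme) per
generation until the split time T, then at 1/(2N_anc) in the merged
ancestor; a cross-deme pair cannot coalesce before T and is a shifted
exponential after it. Binned hazards are estimated as coalescences per
unit lineage-pair exposure, with exact within-bin survival accounting (a
pair coalescing mid-bin contributes partial exposure), which makes the
estimator unbiased per bin; zero-exposure bins are flagged undefined.
The writer emits the MSMC-style text layout (times × μ, hazards / μ), so
synthetic and real rate tables are consumed identically.

## Numerical choices and edge cases

- Outlier threshold: order statistic with strict inequality; all-tied d
  yields zero outliers; fewer than 1/top_fraction defined values warns.
- Clump candidate ordering: (percentile, chromosome, position) lexicographic.
- r² guards: fewer than 2 complete pairs or numerically constant vectors
  (variance ≤ 1e-12 on the dosage scale) are undefined, never 0 or 1.
- Coordinates: 1-based positions for variant tables (VCF), 0-based
  half-open for intervals (BED); conversions centralized in the I/O layer;
  chromosome names pass through verbatim.
- Validation problem sizes: F_ST recovery at 50,000 sites; d calibration
  and power at 100,000 sites; permutation calibration at 500 permutations
  × 200 replicates; divergence recovery at 100,000 pairs with 32
  log-spaced bins to 60,000 generations.

## Known limitations

- Power of the planted-outlier benchmark is modest at the default
  conditions: with 20 spiked loci shifted by 0.4, the median spiked d sits
  close to the null 99.9th percentile (ratio roughly 0.9–1.4 across
  seeds). The fixed-seed validation batch passes; the effect size is near
  the detection boundary by construction, which is worth knowing when
  using the generator for power studies.
- The dosage-correlation r² can differ from haplotype r² when phase
  matters (strong repulsion LD in small samples).
- The shift-permutation null assumes annotations are locally exchangeable
  within a padded locus span; very long annotation blocks relative to the
  span are shift-invariant and carry no signal.
- The clean-split simulator has no migration, growth, or bottlenecks; it
  exists to validate the RCCR conventions, not to emulate realistic
  demographies (an external coalescent simulator serves as an independent
  cross-check in the tests).
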