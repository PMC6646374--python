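# Methods

## Model

`lethalscan` tests, per bi-allelic SNP and per genotype class, the null
hypothesis that the class's complete absence from every sampled population
is a sampling accident. The model has three layers:

1. **Random-mating expectation.** Within each population, every
   male–female pairing is taken as equiprobable. Under that assumption the
   next generation's genotype distribution is the Hardy–Weinberg transform
   of the current one: with P = [p0, p1, p2] over (major-hom, het,
   minor-hom) and allele frequencies f_A = p0 + p1/2, f_a = p2 + p1/2,
   the next generation is P* = [f_A², 2 f_A f_a, f_a²]. The transform is
   idempotent (HWE in one generation) and conserves allele frequencies;
   both are enforced as property tests. P* is used as the expected
   distribution of the *current* sample — valid when the population is not
   undergoing rapid change.

2. **Zero-observation probability.** The number of class-i individuals in
   a sample of n is binomial(n, p_i*), so the probability that none is
   seen is (1 − p_i*)^n, computed as `n·log1p(−p_i*)`. Evidence is
   combined across populations by multiplying these probabilities, which
   treats populations as independent samples and relies on the genotype
   classes being identically labelled everywhere — the reason allele roles
   (major/minor) are assigned from pooled counts, not per population.

3. **Multiplicity.** A chromosome with k retained SNPs yields 3k
   class-absence hypotheses; the flag threshold is α/(3k) (α = 0.05
   default). Correction is per chromosome by default; a genome-wide option
   uses k = total retained SNPs and can only shrink the flagged set. k
   counts *retained* SNPs (post-harmonization), since only those generate
   hypotheses.

The test is only evaluated when the class count is zero in every
population (the absence event occurred); each of the three classes is
tested independently, so one SNP can in principle contribute two testable
classes. Monomorphic SNPs are retained but their impossible classes have
p* = 0 and p-value 1, so they are never flagged.

### Estimation caveat

P is estimated from the same sample in which the zero is observed, with no
pseudo-count: a population with zero minor homozygotes estimates q from
heterozygotes alone, which couples the estimate to the event being tested
and generally makes the screen conservative. Hidden stratification inside
a population cuts the other way: substructure inflates homozygote classes
relative to panmictic HWE, so an absent-heterozygote signal can be
anti-conservative, while absent-homozygote signals become harder to
detect. No stratification correction is attempted — the strict Bonferroni
threshold is the mitigation.

## Harmonization

A SNP enters the test only if it is present (by rsid) and consistently
bi-allelic in every population. Allele-set conflicts are reconciled by
reverse-complementing a population's calls when that makes its allele set
compatible with the consensus (taken from the population with the most
called genotypes; ties broken by label for order-invariance). Palindromic
A/T and C/G sets are never complemented — a strand flip is undetectable
there — and unresolvable SNPs are dropped, each with a logged reason
(absent-in-population, tri-allelic, strand-ambiguous, no-calls) written to
the QC table. Any call containing `N` is fully missing; there are no
half-calls. Two sample-size conventions are exposed for n_j: the called
count at the SNP (default — missing calls carry no observation) or the
full panel size; with no missing data they coincide.

## Synthetic panels

The generator emulates the HapMap phase-3 structure: 11 populations with
sizes (ASW 87, CEU 174, CHB 139, CHD 109, GIH 101, JPT 116, LWK 110,
MEX 86, MKK 184, TSI 102, YRI 209; 1417 individuals), one genotype file
per population. Per SNP, each population draws its minor-allele frequency
q independently from a configurable range (default U(0.05, 0.5),
emulating real between-population frequency differences) or uses a fixed
value; genotypes are drawn at HWE proportions [(1−q)², 2q(1−q), q²].

A lethal class (i, s) is imposed by **rejection to a fixed number of
survivors**: a drawn individual of class i survives with probability s and
non-survivors are redrawn until the panel size is reached. This models
ascertainment of living adults — the screen's premise — rather than
thinning the sample. Redraws are bounded (10⁴ rounds) and a configuration
whose surviving-genotype probability is zero errors out. Missingness masks
each emitted call to `NN` independently. Output is deterministic given the
config seed (numpy PCG64; per-population streams derived from the master
seed), so fixtures are reproducible byte-for-byte.

What the generator does *not* emulate: linkage between SNPs, relatedness
or pedigree structure, within-population stratification, genotyping error,
and non-random missingness. Passing calibration tests therefore shows the
statistic behaves as designed under its own assumptions, not that real
panels satisfy those assumptions.

## Numerical choices

- All probability products are in log space; a combined p-value below
  exp(−746) is reported as 0 with the log retained. TSV output renders
  p-values in 3-significant-digit scientific notation (`3.05E-16`).
- Simplex inputs to the random-mating update are validated to 1e-9;
  its output sums to 1 to 1e-12 (algebraic identity, property-tested).
- Major/minor ties (pooled counts equal) break to the lexicographically
  smaller character; p-value ties in result ordering break by
  (chromosome, position, rsid) for reproducible output.
- A chromosome with zero retained SNPs reports a NaN threshold and no
  flags rather than erroring.

## Validation problem sizes

The test suite measures the family-wise error rate over 50 replicates of
2000 null SNPs (q ~ U(0.05, 0.5), full 11-population panel, α = 0.05),
asserting the generous bound FWER ≤ 0.1 — the statistic is expected to be
conservative because P is estimated in-sample. Power uses 20 replicates of
a 2000-SNP chromosome with a fully lethal minor homozygote at q = 0.3
everywhere (pooled expected count ≈ 75, combined p ≈ e^−75), where
detection must be universal. The end-to-end golden test plants three fully
lethal SNPs with q ∈ [0.2, 0.5] — chosen so every planted class has a
pooled expected count far above the Bonferroni bar analytically, making
exact recovery a correctness check rather than a power statement. The
Monte-Carlo oracle for the zero-observation probability uses 2×10⁵
binomial draws per grid point over p ∈ {0.01, 0.05, 0.1} ×
n ∈ {50, 200, 1000}, with agreement within three standard errors.

## Known limitations

- The screen only sees *complete* absence; a lethal genotype with even one
  surviving (or miscalled) carrier in any population is invisible.
- Population panels of a few hundred give adequate power only for common
  alleles; rare lethal homozygotes (q ≲ 0.05) have expected counts below
  one per population and cannot be distinguished from sampling zeros.
- The binomial model ignores relatedness among sampled individuals, which
  reduces the effective sample size and makes printed p-values slightly
  optimistic for panels with cryptic kinship.
- X/Y/MT sites are excluded: their inheritance breaks the diploid
  random-mating model.
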