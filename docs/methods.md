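# Methods

This note records the models, estimators and numerical choices behind
sweepkit, and what the synthetic-data validation does and does not
demonstrate about real data.

## Population model of the synthetic generator

Genotypes are generated under the Balding–Nichols model. Per site, an
ancestral allele frequency p is drawn from Beta(a, b) (default a = b = 1,
i.e. uniform); each deme d then draws its frequency from

    p_d ~ Beta(p (1-F_d)/F_d, (1-p)(1-F_d)/F_d),

which has mean p and variance F_d · p(1-p). The drift parameter F_d equals
the expected fixation index of the deme against the ancestral pool, so two
demes simulated at the same F have expected pairwise Hudson Fst ≈ F — the
closed-form handle that parameter-recovery tests rely on. Diploid calls are
Binomial(2, p_d) per sample; optional missingness is applied uniformly at
random (default 0).

The default configuration is three demes of 11, 11 and 6 diploid samples
with F = (0.02, 0.02, 0.15): two closely connected populations and one
diverged population with restricted gene flow — the sampling structure the
scan is designed for. These values are illustrative; the model makes no
claim about any particular river system's demography.

A selective sweep is emulated by its two observable footprints only:

- **differentiation** — inside the sweep region [start, end) the target deme
  draws frequencies with F_sweep > F instead of its background drift;
- **diversity loss** — each in-region site is, with probability
  1 − pi_reduction, monomorphized in the target deme (all calls set to the
  homozygote nearest the deme frequency).

No selection dynamics, hitchhiking or recombination are simulated: the scan
statistics only see differentiation and diversity, so this is the minimal
sufficient signal for validating the caller. Consequences: synthetic sweeps
have rectangular edges rather than the decaying shoulders of real sweeps,
background LD is absent (sites are independent given frequencies), and there
is no mutation-rate or coverage heterogeneity along the chromosome. Passing
recovery tests therefore demonstrates that the caller finds the
differentiation-plus-diversity-loss signature where it exists; it does not
calibrate power against coalescent or forward simulations of real sweeps.

Site positions are a uniform draw without replacement, sorted; ref/alt are
fixed A/T because the statistics treat alleles as labels.

## Diversity and differentiation estimators

Per-site diversity uses the unbiased pairwise estimator
π = 2a(n−a)/(n(n−1)); window θπ is the sum of site values divided by the
window's length in bp (invariant positions count in the denominator, which
is what a between-population ratio requires). Windows are half-open 1-kb
tiles by default; the trailing partial window keeps its true length. A
per-site-count normalization is easy to compute from the emitted table
(`pi * effective_bp / n_sites`) but the per-bp form is primary.

Between populations, Hudson's Fst estimator is used, aggregated ratio-of-
sums within windows. Its denominator is the mean between-population pairwise
difference and denominator − numerator equals the average of the two
unbiased within-population diversities, so a window's value is algebraically
1 − π_within/π_between; the tests exploit this identity against brute-force
pair enumeration. Hudson's form was chosen because it is insensitive to
unequal sample sizes (6 vs 11 individuals) and needs no variance-component
bookkeeping. Negative window values (expected when true differentiation is
~0) are retained unclamped so the Z-transform sees the honest empirical
distribution. Sites with fewer than 4 called allele copies in a population
are dropped for that population (configurable `min_copies`).

Z(Fst) uses the sample standard deviation (denominator N−1). An effectively
constant Fst vector (σ below 1e−12 relative) aborts the scan rather than
emitting infinities.

Genotype PCA standardizes each polymorphic site by its binomial standard
deviation sqrt(2p(1−p)) after centering at 2p, mean-imputes missing calls per
site, and takes the SVD of the sample matrix; variance fractions are the
normalized squared singular values.

## Outlier calling

Cutoffs are empirical quantiles: the k-th most extreme value with
k = ceil(qN), all ties at the cutoff included — deterministic and
order-independent. The default rule is the intersection of the top-q
Z(Fst) tail with the top-q tail of the log2 diversity ratio, each ratio tail
(high ⇒ diversity loss in population B, low ⇒ in population A) evaluated
separately; a union rule is available. Intersection was preferred because a
joint criterion is what keeps the called fraction well below q under the
null, matching the small outlier-region counts such scans report in
practice. Windows where either population's θπ is zero are excluded from
the ratio ranking (count logged) instead of being patched with a pseudocount
that would dominate the tail; a consequence, visible in the recovery
simulations, is that a sweep window whose diversity hits exactly zero cannot
be called under the intersection rule. At realistic marker densities this is
rare; the recovery simulation uses 150 variant sites per 1-kb window so the
ratio is defined in essentially every window and the measured sensitivity
reflects the caller, not the exclusion rule.

Gene overlap is any shared bp under half-open semantics, computed by a
sorted bounded-lookback sweep over window starts and verified in tests
against an all-pairs oracle.

## Variant filtering

Hard-filter inequalities are strict, exactly as written (QUAL > 30 fails at
30). A record whose INFO lacks a metric fails that metric's filter — the
conservative choice, preventing unannotated records from leaking through.
Failure names are written to the FILTER column and counted per filter.

LD pruning is the standard windowed greedy scheme (window 50 sites, step 5,
r² > 0.8 drops the later site), with r computed on 0/1/2 calls over
pairwise-complete samples; monomorphic sites have undefined r and are never
pruned for LD. This is a generic substitute for any specific tool's internal
pruning pass — retained sets will differ from e.g. SNPhylo's in detail while
enforcing the same r² bound. The per-genotype minimum-depth mask (depth < 5
⇒ missing) applies only when per-sample depths are supplied; otherwise it is
skipped with a warning.

The scan defaults to the hard-filtered (unpruned) SNP set — pruning away LD
would erase exactly the local structure a sweep creates — while PCA should
use the pruned set.

## K-mer genome-size estimation

The estimator is G = (L − K + 1) · n_base/(C_kmer · L) with the revision
G_revised = G · (1 − error_rate); error_rate is a user input, not estimated
internally. Depths below min_freq = 3 are trimmed before peak finding (the
sequencing-error peak), leaving n_base untouched since bases come from
reads.

C_kmer ("expectation of k-mer depth") is located as follows: 3-bin moving-
average smoothing on the dense depth grid (edge bins use truncated windows),
take the maximal bin, then return the count-weighted mean depth over
[mode/2, 2·mode]. The local first moment matters: the raw integer mode of a
Poisson-shaped peak sits about half a depth-bin below the expected depth,
a 2–3% genome-size bias at 20–30× that the local moment removes (measured
recovery error ≤ 0.5% across genome sizes 1e5–1e6 and coverages 20–40). A
tie between smoothed bins returns the lower depth with a warning; a global
count-weighted mean is available as `method="mean"`. The local window also
keeps distant repeat-peak mass (at multiples of the main peak) out of the
moment, though heterozygosity and repeat fractions themselves are out of
scope — no mixture model is fitted.

The simulated spectrum is idealized: every genomic k-mer distinct, depths
Poisson with mean coverage·(L−k+1)/L·(1−e)^k, error-containing k-mer
instances as distinct singletons. Real spectra add heterozygous half-peaks,
repeat shoulders and GC-coverage bias; recovery on the idealized spectrum
validates the trimming/peak/formula chain, not robustness to those features.

## Assembly reporting

N50 is the smallest length ℓ with cumulative length of sequences ≥ ℓ at
least half the total. Percentages round half-even (Python `round`) at the
precision of the figure being matched; megabases convert at 1 Mb = 1e6 bp.

## Formats and conventions

Internal coordinates are 0-based half-open everywhere; VCF (1-based) and GFF
(1-based inclusive) convert at the I/O boundary only. Only biallelic SNPs
flow downstream; multiallelic records are skipped with a logged count by
default (splitting into per-alt records is available), indels are dropped by
default. K-mers are counted canonically (lexicographic min of k-mer and
reverse complement). VCF I/O goes through pysam/htslib.

## Problem sizes used in validation

Test and acceptance runs use deliberately small instances chosen so the
checked property is well-resolved: drift recovery at 2×30 samples and 5,000
sites; sweep recovery on a 1-Mb chromosome with 1,000 1-kb windows, 150
sites/window and an 8-window sweep; null calibration over 20 seeds of
200-window scans; genome-size recovery at G = 1e5–1e6 and 20–40×. These
scales resolve each property cleanly while keeping the full validation run
in the tens of seconds.

## Known limitations

- The windowed statistics assume unphased diploid biallelic genotypes;
  haplotype-based sweep statistics (iHS, XP-EHH) and Tajima's D are out of
  scope.
- The intersection rule's sensitivity depends on marker density through the
  zero-diversity exclusion (above).
- The LD pruner is a greedy approximation; it guarantees no retained pair
  within a window exceeds r², not a maximal retained set.
- PCA mean-imputation shrinks samples with much missingness toward the
  origin.
- No attempt is made to model reference bias, mapping artifacts, or indel
  realignment; the pipeline starts from a called VCF.
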