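# Methods

This note documents the statistical models implemented in `rufus`, the
conventions and numerical choices they rely on, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Ancestry states, blocks, and switch counts

Local-ancestry dosages (red wolf allele count expectations in [0, 2], as
produced by two-source ancestry HMMs and averaged over replicate runs) are
discretised with fixed thresholds: d < 0.8 → homozygous coyote,
0.8 ≤ d ≤ 1.8 → heterozygous, d > 1.8 → homozygous red wolf. Both band
boundaries classify as heterozygous; this inclusive convention is pinned by
tests. Readers reject out-of-range dosages (beyond 1e-6) with their
location rather than clamping them.

Blocks are maximal runs of equal state per chromosome. Block span is
first-to-last SNP of the run, 1-based inclusive internally and 0-based
half-open in BED export. A single-SNP block has length 0 Mb — conservative
and independent of the SNP map's density; no extension toward midpoints
between flanking SNPs is attempted. Missing-dosage SNPs are transparent: a
run continues across them, and they are excluded from ancestry proportions
(never imputed).

The diploid switch count B sums, over adjacent block pairs within each
chromosome, the state distance |Δ| ∈ {1, 2}; a direct coyote↔red-wolf
junction costs 2 because both haplotypes must change. This equals the
minimal number of per-haplotype ancestry changes over all phasings
consistent with the unphased state sequence (verified exhaustively against
a dynamic-programming oracle for all sequences up to length 8). Chromosome
ends contribute nothing.

## Admixture timing

Under a single pulse of proportion z followed by T generations of random
mating, each haplotype accumulates crossovers at T·L/100 per genome of L
centimorgans, and a crossover joins segments of different ancestry with
probability 2z(1 − z); summing two haplotypes gives
**B = 0.04·T·L·z(1 − z)**. The estimator inverts this exactly;
`estimate_generations(expected_switches(T, L, z), L, z) = T` holds to
1e-12 over a wide grid by construction, and is asserted.

Conventions:

* L = 2085 cM (autosomes) and 111 cM (X) by default, configurable.
* z for timing is the dosage-based proportion (mean dosage / 2), not a
  block-length fraction — one definition, used everywhere.
* Calendar years = 3T, the mean of 2- and 4-year generation times.
* z exactly 0 or 1 makes T undefined (no admixture signal): reported as a
  flagged null, with an optional compatibility mode rendering it "0.0" as
  the published cohort table does. No guess is substituted.
* Years are reported to 1 decimal at the reporting layer only.

The estimator assumes a single pulse, unbounded population size, uniform
recombination, and error-free ancestry assignment. Block-size inflation
from reduced-representation genotyping (and any residual dosage noise,
which only ever adds switches) biases T̂ upward — i.e. toward more recent
admixture dates; no correction is applied.

## Genotype QC chain

The chain reproduces a standard RADseq filtering recipe with its defaults:
drop singletons and private doubletons (minor-allele count 1, or 2 carried
by one homozygote — two heterozygous carriers are not private doubletons);
drop loci with missingness strictly above 0.90, then individuals strictly
above 0.20 recomputed on retained loci; keep loci with MAF ≥ 0.03
(boundary inclusive). The "neutral and unlinked" subset additionally
applies sliding-window LD pruning (50 SNPs, step 5, r² > 0.5) and an exact
Hardy-Weinberg test at α = 0.001. A final rare-allele pass keeps the chain
idempotent after sample removal, and the neutral/unlinked set is nested in
the full set.

Numerical/tie-break choices, since external tools differ and bit-for-bit
agreement with them is not a goal:

* LD pruning drops, from the worst over-threshold pair in a window, the
  locus with the lower MAF (the later one on ties) — deterministic.
* Genotype correlations use mean-imputed missing values.
* The HWE test is exact and two-sided: conditioning on allele counts, it
  sums hypergeometric-weighted probabilities of heterozygote counts no
  more probable than the observed one, in log space with a 1 + 1e-12 tie
  tolerance; monomorphic loci return p = 1. It matches full enumeration
  for every genotype configuration with n ≤ 20.

## Private alleles and rarefaction

A private allele is present in one population and absent in all others at
a locus; missing genotypes are excluded, so gene-copy counts are
locus-specific. The rarefied expectation standardises to g sampled copies
via absence probabilities Q_ij(g) = C(N_j − N_ij, g)/C(N_j, g), computed in
log space (stable for copy counts to ~1e4). Loci where any population has
fewer than g called copies are skipped at that g and the skip count
reported; the default standardised size is G = 100 gene copies.

At g equal to every population's full copy count the rarefied value equals
the observed private count exactly. The expectation is *not* monotone in g
in general: a truly private allele's contribution rises with g, but an
allele shared among populations is less likely to look sample-private in
larger subsamples, so its contribution falls. Both behaviours are covered
by tests, and the formula is validated against a 10⁵-resample Monte-Carlo
subsampling oracle.

## Cohort statistics and morphology models

Regional summaries report n, mean, sample SD (n − 1 denominator — pinned
by the published northwestern-Cameron block SD, which the n denominator
cannot reproduce), min and max; rounding to table precision happens only
at the reporting layer. Group contrasts use Welch's unequal-variance
two-sided t test with Welch–Satterthwaite degrees of freedom — chosen as
the robust default since the source analysis does not name its variant.
PCA-ancestry correlations report signed r and |r| (PC signs are
arbitrary), and accept either per-sample or group-mean ancestry vectors.

The morphology analysis fits weight (kg) against eight a priori candidate
fixed-effect structures — {1}, {auto}, {X}, {auto+X}, {auto+sex},
{auto+age}, {auto+sex+age}, {X+sex} — each with a trapping-region random
intercept, by maximum likelihood so AICs are comparable across structures.
The candidate set is this package's assumption: the source analysis states
eight a priori models without printing them, so a hierarchy around the
autosomal-ancestry hypothesis plus sex/age covariates was fixed once.
Significance is a 95% Wald CI excluding zero. When the random-intercept
variance converges to the zero boundary the mixed likelihood degenerates
(non-finite AIC); such fits fall back to the identical fixed-intercept OLS
model and are flagged.

## Synthetic data: what it emulates, and what it does not

The pulse simulator implements the timing model's own assumptions:
founder haplotypes wholly red wolf with probability z; each later
generation recombines two independently drawn parental haplotypes with
Poisson(cM/100) crossovers at uniform positions (random-union mating in an
effectively infinite population — no drift, no inbreeding). The genealogy
is realised lazily on inherited intervals only, so cost scales with
junction count rather than 2^T, while preserving founder identity (and
hence the within-meiosis back-and-forth correlation a real pedigree has).
The default karyotype is 38 autosomes + X scaled to 2085/111 cM with
linear 1 cM/Mb maps; per-chromosome lengths decline linearly, since only
the totals enter any statistic.

Dosages are haplotype sums at SNPs on a regular grid (default 25 SNPs/Mb,
matching the density of a ~60k-SNP RAD panel on a ~2.2 Gb genome) plus
Gaussian noise clipped to [0, 2]. The default noise SD of 0.05 reflects
that averaged HMM dosages are smooth rather than per-SNP noisy; with SD
0.15, states 0.2 from a band edge (heterozygous and homozygous red wolf)
are misclassified at Gaussian-tail rates (~9%), so aggregate error stays
below 5% only when those states are a minority. Noise only creates
switches, never removes them, so noisy dosages bias timing slightly
recent — visible, documented behaviour rather than hidden.

Not emulated: genotype calling error, RADseq locus dropout and block-size
inflation, finite-population drift, selection, sex-biased demography on X,
male X hemizygosity, or non-uniform recombination. Passing recovery tests
therefore validates the estimators under the model's own assumptions, not
robustness to those real-data features.

Population genotypes draw Binomial(2, f) genotypes with per-locus shared
frequencies ~ Uniform(0.1, 0.9) or planted population-private alleles at a
stated frequency, recording realized private status (a planted allele can
fail to be sampled). Morphology tables use weight = 12.0 + 7.42·z_auto +
2.1·I(male) + region intercept + N(0, 2) kg by default — the reported
effect sizes as generator truth, an intercept and residual spread giving
realistic 10–20 kg coyotes, and N(0, 1) region intercepts.

## Problem sizes used in the test and acceptance runs

Simulation recovery uses 200 diploid genomes per condition at the full
38+X karyotype and default SNP density for T ∈ {5, 10}, z ∈ {0.38, 0.5};
the mean pipeline switch count on noiseless dosages is compared to
0.04·T·L·z(1 − z) within 3 standard errors, and the median estimated T
through the noisy default pipeline must land within 15% of truth.
Morphology recovery runs 200 replicates at n = 200 (asserting ≥90%
top-model selection and per-coefficient CI coverage) and 200 replicates at
the study-sized n = 24 (asserting coverage; selection power is reported
only). Oracle-equivalence checks are exhaustive where stated (state
sequences to length 8; HWE configurations to n = 20).

## Known limitations

* The timing estimator is single-pulse; continuous migration or multiple
  pulses are out of scope and will be absorbed into a single effective T.
* Switch counts from unphased states can undercount when both haplotypes
  change between adjacent SNPs; at realistic SNP densities this is
  negligible, but it is another recent-ward bias source.
* The LD pruner is a deterministic reimplementation of a greedy windowed
  heuristic; it is not intended to match any external tool exactly.
* Raw-data-dependent published numbers (SNP counts after filtering,
  absolute private-allele counts, PCA correlations, regression
  coefficients) require the study's sequence data and are covered by
  property-based simulation tests instead of value reproduction.
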