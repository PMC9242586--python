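# rufus

Downstream population-genomic analysis of **red wolf (*Canis rufus*) ghost
ancestry in Gulf Coast coyotes**: from per-SNP local-ancestry dosages and
biallelic genotype matrices to ancestry blocks, admixture-timing estimates,
private-allele rarefaction, regional cohort summaries, and the body-mass ~
ancestry regression — together with a pulse-admixture simulator that
generates every input with known ground truth.

The package is aimed at conservation and hybrid-zone genomicists who have
local-ancestry output (e.g. averaged ELAI-style dosage matrices) and RADseq
genotypes for an admixed population, and want reproducible, tested
implementations of the block/ timing/ diversity statistics used to argue
that admixed genomes are a reservoir of an extirpated species' variation.

## The model

Each SNP in a two-source admixed diploid carries a **red wolf allele
dosage** d ∈ [0, 2] (0 = homozygous coyote, 2 = homozygous red wolf).
Dosages are discretised into three ancestry states — d < 0.8 homozygous
coyote, 0.8 ≤ d ≤ 1.8 heterozygous ("joint"), d > 1.8 homozygous red wolf —
and maximal runs of equal state form **ancestry blocks**. Adjacent blocks
contribute ancestry **switches**: 1 per single-haplotype change, 2 for a
direct coyote↔red-wolf transition; the diploid total B equals the minimal
number of per-haplotype ancestry changes consistent with the unphased
states.

Under a single admixture pulse of proportion *z* followed by *T*
generations of random mating, the expected diploid switch count over a
genetic map of *L* centimorgans is

> B = 0.04 · T · L · z(1 − z)

applied with L = 2085 cM for the canid autosomes and L = 111 cM for X.
Inverting gives T̂ = B / (0.04 · L · z(1 − z)); calendar years are 3T
(average of 2- and 4-year canid generation times). The genome-wide
proportion z is mean dosage / 2 per compartment.

Private-allele richness across population sets is standardised by
ADZE-style rarefaction: with N_j gene copies in population j and N_ij
carrying allele i, the probability a subsample of g copies misses the
allele is Q_ij(g) = C(N_j − N_ij, g) / C(N_j, g), and the expected count of
alleles private to j at g is Σ (1 − Q_ij) Π_{j′≠j} Q_ij′ (G = 100 by
default). Body mass (kg) is modelled with linear mixed models (ancestry,
sex, age as candidate fixed effects; trapping region as a random
intercept) over eight a priori structures ranked by maximum-likelihood AIC.

## Worked example

Simulate a small cohort ten generations after a 50/50 pulse, convert the
tract genomes to dosages, and date the admixture:

```python
from rufus import (SimConfig, simulate_pulse_admixture, make_snp_map,
                   tracts_to_dosage, ancestry_summary, timing_report)

cfg = SimConfig(t=10, z=0.5, n=3, seed=42)
cohort = simulate_pulse_admixture(cfg)
snp_map = make_snp_map(cfg.karyotype, cfg.snp_per_mb)
dosage = tracts_to_dosage(cohort, snp_map, cfg.dosage_noise_sd, seed=43)
report = timing_report(ancestry_summary(dosage))
print(report[["sample", "z_auto", "b_auto", "t_auto", "years_auto"]]
      .round(3).to_string(index=False))
```

```
 sample  z_auto  b_auto  t_auto  years_auto
sim0000   0.472     189   9.093      27.279
sim0001   0.476     220  10.576      31.729
sim0002   0.487     212  10.175      30.525
```

Each genome's autosomal red wolf proportion sits near the founding z = 0.5,
its ~200 ancestry switches match the expectation 0.04·10·2085·0.25 ≈ 208.5,
and the inverted estimates recover T = 10 generations (≈ 30 years).

The published cohort tables are bundled; `rufus summarize --out summary.tsv`
(or `rufus.cohort_stats.published_cohort_summary()`) recomputes the
regional numbers — e.g. overall autosomal ancestry mean 0.38, northwestern
Cameron Parish red wolf block mean 56.2 ± 49.4 Mb and block-size ratio 3.5.
The other stages are available as `rufus qc|ancestry|timing|diversity|run`.

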