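"""Synthetic inputs with known ground truth for every pipeline stage.

The centrepiece emulates the admixture model behind the timing equation:
a single pulse in which each founder haplotype is wholly red wolf with
probability ``z`` (else coyote), followed by ``T`` generations of random
mating in an effectively infinite population. Each meiosis draws a
crossover count ~ Poisson(chromosome cM / 100) with uniform crossover
positions and stitches two independently simulated parental haplotypes.
The genealogy is simulated lazily — parental haplotypes are only realised
on the intervals the offspring actually inherits — so cost grows with the
number of inherited junctions, not with 2^T. Founder identity is preserved:
segments inherited from the same founder share one ancestry draw, keeping
the back-and-forth correlation a real pedigree would have.

Tract genomes convert to SNP dosage matrices through a linear cM<->bp map
per chromosome (uniform recombination; 1 cM per Mb by default) with SNPs on
a regular grid and optional Gaussian dosage noise clipped to [0, 2] —
mimicking averaged local-ancestry HMM output, which is smooth rather than
noisy per SNP, hence the small default noise.

Also here: multi-population biallelic genotypes with a controllable
private-allele plan, and morphology tables generated from a known linear
model (weight = intercept + slope * ancestry + sex effect + region shift +
noise). All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import PopulationSet
from .formats_io import DosageMatrix, GenotypeMatrix, Karyotype, SnpMap

__all__ = [
    "ChromosomeSpec",
    "SimConfig",
    "default_karyotype",
    "simulate_pulse_admixture",
    "make_snp_map",
    "tracts_to_dosage",
    "true_ancestry_fraction",
    "true_switch_count",
    "simulate_population_genotypes",
    "simulate_morphology",
]


@dataclass(frozen=True)
class ChromosomeSpec:
    """One simulated chromosome: name, genetic length (cM), physical length (bp)."""

    name: str
    cm: float
    bp: int

    def __post_init__(self):
        if self.cm <= 0 or self.bp <= 0:
            raise ValueError("chromosome lengths must be positive")


def default_karyotype() -> list[ChromosomeSpec]:
    """38 autosomes + X scaled to 2085 / 111 cM totals, 1 cM per Mb.

    Autosome lengths decline linearly (canid autosomes are acrocentric and
    span roughly 120 down to 25 Mb); exact per-chromosome lengths do not
    matter for any statistic the pipeline computes, only the totals do.
    """
    raw = np.linspace(85.0, 25.0, 38)
    cm = raw * (2085.0 / raw.sum())
    chroms = [ChromosomeSpec(str(i + 1), float(c), int(round(c * 1e6)))
              for i, c in enumerate(cm)]
    chroms.append(ChromosomeSpec("X", 111.0, 111_000_000))
    return chroms


@dataclass(frozen=True)
class SimConfig:
    """Pulse-admixture simulation settings.

    ``t`` generations since the pulse, ``z`` founding red wolf proportion,
    ``n`` diploid individuals. ``snp_per_mb`` sets the regular SNP grid
    density (the study genotyped ~60k RAD SNPs over a ~2.2 Gb genome, about
    25 per Mb); ``dosage_noise_sd`` perturbs dosages before clipping to
    [0, 2]. The seed is mandatory: every run is reproducible.
    """

    t: int
    z: float
    n: int
    seed: int
    karyotype: tuple[ChromosomeSpec, ...] = tuple(default_karyotype())
    snp_per_mb: float = 25.0
    dosage_noise_sd: float = 0.05

    def __post_init__(self):
        if self.t < 0 or self.n <= 0 or self.snp_per_mb <= 0 or self.dosage_noise_sd < 0:
            raise ValueError("simulation sizes/rates must be positive")
        if not 0 <= self.z <= 1:
            raise ValueError("z must lie in [0, 1]")

    @property
    def base_karyotype(self) -> Karyotype:
        return Karyotype(tuple(c.name for c in self.karyotype))


# A haplotype is (ends_cm, anc): tract right-ends in cM (last == chrom length)
# and per-tract ancestry (1 = red wolf, 0 = coyote), same-ancestry neighbours
# merged. A TractGenome is {chrom name: (hap0, hap1)}.
Haplotype = tuple[np.ndarray, np.ndarray]
TractGenome = dict[str, tuple[Haplotype, Haplotype]]


def _simulate_node(rng: np.random.Generator, length_cm: float, t: int, z: float,
                   intervals: list[tuple[float, float]]) -> list[tuple[float, float, int]]:
    """Tracts (start, end, ancestry) covering ``intervals`` of one haplotype
    at generation ``t``, simulating ancestors only where inherited."""
    if t == 0:
        anc = 1 if rng.random() < z else 0
        return [(lo, hi, anc) for lo, hi in intervals]
    k = rng.poisson(length_cm / 100.0)
    cuts = np.sort(rng.uniform(0.0, length_cm, size=k))
    first = int(rng.integers(2))
    # meiosis segments alternate between the two parents
    bounds = np.concatenate(([0.0], cuts, [length_cm]))
    need = [[], []]  # intervals required from each parent
    for lo, hi in intervals:
        for s in range(len(bounds) - 1):
            a, b = max(lo, bounds[s]), min(hi, bounds[s + 1])
            if b > a:
                need[(first + s) % 2].append((a, b))
    out: list[tuple[float, float, int]] = []
    for p in range(2):
        if need[p]:
            out.extend(_simulate_node(rng, length_cm, t - 1, z, need[p]))
    out.sort(key=lambda seg: seg[0])
    return out


def _merge(segments: list[tuple[float, float, int]], length_cm: float) -> Haplotype:
    ends, anc = [], []
    for lo, hi, a in segments:
        if anc and anc[-1] == a:
            ends[-1] = hi
        else:
            ends.append(hi)
            anc.append(a)
    ends[-1] = length_cm  # guard FP drift at the terminal boundary
    return np.asarray(ends, float), np.asarray(anc, np.uint8)


def simulate_pulse_admixture(cfg: SimConfig) -> list[TractGenome]:
    """Simulate ``cfg.n`` diploid tract genomes under the single-pulse model.

    At T=0 every haplotype is one tract; the cohort's expected diploid
    switch count per genome is 0.04 * T * L * z * (1 - z).
    """
    rng = np.random.default_rng(cfg.seed)
    cohort = []
    for _ in range(cfg.n):
        genome: TractGenome = {}
        for chrom in cfg.karyotype:
            haps = tuple(
                _merge(_simulate_node(rng, chrom.cm, cfg.t, cfg.z,
                                      [(0.0, chrom.cm)]), chrom.cm)
                for _ in range(2)
            )
            genome[chrom.name] = haps
        cohort.append(genome)
    return cohort


def make_snp_map(karyotype: tuple[ChromosomeSpec, ...],
                 snp_per_mb: float = 25.0) -> SnpMap:
    """Regular-grid SNP map: evenly spaced sites, linear cM positions."""
    chroms, pos_bp, pos_cm = [], [], []
    for c in karyotype:
        spacing = 1e6 / snp_per_mb
        n = max(1, int(c.bp / spacing))
        bp = (np.arange(n) + 0.5) * spacing
        bp = bp[bp < c.bp].astype(np.int64) + 1
        chroms.extend([c.name] * len(bp))
        pos_bp.extend(bp.tolist())
        pos_cm.extend(((bp - 1) * (c.cm / c.bp)).tolist())
    return SnpMap(chroms, pos_bp, pos_cm, Karyotype(tuple(c.name for c in karyotype)))


def tracts_to_dosage(cohort: list[TractGenome], snp_map: SnpMap,
                     noise_sd: float = 0.0, seed: int = 0,
                     sample_prefix: str = "sim") -> DosageMatrix:
    """Red-wolf dosage per SNP: haplotype ancestries summed + clipped noise.

    The SNP map must carry cM positions within each simulated chromosome.
    With ``noise_sd=0`` the classification thresholds recover the true tract
    state at every SNP.
    """
    if snp_map.pos_cm is None:
        raise ValueError("SNP map needs cM positions for tract lookup")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    values = np.empty((n, len(snp_map)), dtype=float)
    for chrom in snp_map.chromosomes:
        sl = snp_map.chrom_slice(chrom)
        cm = snp_map.pos_cm[sl]
        for i, genome in enumerate(cohort):
            if chrom not in genome:
                raise ValueError(f"SNP map chromosome {chrom!r} not simulated")
            total = np.zeros(len(cm))
            for ends, anc in genome[chrom]:
                if cm[-1] > ends[-1]:
                    raise ValueError(f"SNP beyond simulated end of chromosome {chrom!r}")
                total += anc[np.searchsorted(ends, cm, side="left")]
            values[i, sl] = total
    if noise_sd > 0:
        values = np.clip(values + rng.normal(0.0, noise_sd, values.shape), 0.0, 2.0)
    samples = [f"{sample_prefix}{i:04d}" for i in range(n)]
    return DosageMatrix(samples, values, snp_map)


def true_ancestry_fraction(genome: TractGenome, karyotype: tuple[ChromosomeSpec, ...],
                           chroms: set[str] | None = None) -> float:
    """Tract-length-weighted red wolf fraction of a diploid genome (cM units)."""
    num = den = 0.0
    for c in karyotype:
        if chroms is not None and c.name not in chroms:
            continue
        for ends, anc in genome[c.name]:
            widths = np.diff(np.concatenate(([0.0], ends)))
            num += float((widths * anc).sum())
            den += c.cm
    if den == 0:
        raise ValueError("no chromosomes selected")
    return num / den


def true_switch_count(genome: TractGenome, chroms: set[str] | None = None) -> int:
    """True haplotype ancestry switches summed over both haplotypes."""
    b = 0
    for name, haps in genome.items():
        if chroms is not None and name not in chroms:
            continue
        for ends, anc in haps:
            b += int((np.diff(anc.astype(int)) != 0).sum())
    return b


def simulate_population_genotypes(
    pop_sizes: dict[str, int],
    n_shared_loci: int,
    private_plan: dict[str, tuple[int, float]],
    seed: int,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, PopulationSet, pd.DataFrame]:
    """Biallelic genotypes for several populations with planted private alleles.

    Shared loci draw one allele frequency ~ Uniform(0.1, 0.9) common to all
    populations. For each ``private_plan`` entry ``pop: (n_loci, freq)`` the
    alternate allele segregates at ``freq`` in that population only. Genotypes
    are Binomial(2, f) per individual. Returns the matrix, the population
    labels, and a per-locus truth table with the realized private status
    (a planted allele can fail to be sampled, in which case it is not
    realized and — being absent everywhere — not private either).
    """
    rng = np.random.default_rng(seed)
    pops = list(pop_sizes)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for pop, (_, f) in private_plan.items():
        if not 0 <= f <= 1:
            raise ValueError(f"private allele frequency {f} outside [0, 1]")
        if pop not in pop_sizes:
            raise ValueError(f"plan names unknown population {pop!r}")
    samples, labels = [], {}
    for pop, size in pop_sizes.items():
        for i in range(size):
            name = f"{pop}_{i:03d}"
            samples.append(name)
            labels[name] = pop
    sample_pop = np.array([labels[s] for s in samples])

    loci = [("shared", None, float(rng.uniform(0.1, 0.9)))
            for _ in range(n_shared_loci)]
    for pop, (n_priv, f) in private_plan.items():
        loci.extend(("private", pop, f) for _ in range(n_priv))

    n_total = len(loci)
    values = np.zeros((len(samples), n_total))
    truth_rows = []
    for j, (kind, pop, f) in enumerate(loci):
        if kind == "shared":
            values[:, j] = rng.binomial(2, f, size=len(samples))
        else:
            mask = sample_pop == pop
            values[mask, j] = rng.binomial(2, f, size=int(mask.sum()))
        if missing_rate > 0:
            miss = rng.random(len(samples)) < missing_rate
            values[miss, j] = np.nan
        realized = bool(kind == "private" and np.nansum(values[sample_pop == pop, j]) > 0)
        truth_rows.append({"locus": j, "kind": kind, "private_to": pop,
                           "freq": f, "realized_private": realized})
    snp_map = SnpMap(["1"] * n_total, np.arange(1, n_total + 1) * 1000)
    gm = GenotypeMatrix(samples, values, snp_map)
    return gm, PopulationSet(labels), pd.DataFrame(truth_rows)


def simulate_morphology(
    ancestry: pd.DataFrame,
    seed: int,
    beta_auto: float = 7.42,
    beta_sex_male: float = 2.1,
    beta_x: float = 0.0,
    intercept: float = 12.0,
    noise_sd: float = 2.0,
    region_effects: dict[str, float] | None = None,
    n_regions: int = 4,
    region_sd: float = 1.0,
) -> pd.DataFrame:
    """Sample metadata with weights from a known linear model.

    ``ancestry`` needs columns sample, z_auto (z_x optional). Weight (kg) is
    intercept + beta_auto * z_auto + beta_x * z_x + beta_sex_male * I(male)
    + region intercept + N(0, noise_sd). Default effect sizes are the point
    estimates the cohort analysis reports, so recovery tests run at the
    study's conditions; the default intercept and residual spread give
    realistic 10-20 kg coyotes. Regions are assigned round-robin; their
    intercepts are drawn N(0, region_sd) unless supplied.
    """
    rng = np.random.default_rng(seed)
    if region_effects is None:
        names = [f"region{i + 1}" for i in range(n_regions)]
        region_effects = {r: float(rng.normal(0.0, region_sd)) for r in names}
    regions = list(region_effects)
    n = len(ancestry)
    z_auto = ancestry["z_auto"].to_numpy(float)
    z_x = ancestry["z_x"].to_numpy(float) if "z_x" in ancestry else np.zeros(n)
    if np.nanmin(z_auto) < 0 or np.nanmax(z_auto) > 1:
        raise ValueError("ancestry values must lie in [0, 1]")
    region = [regions[i % len(regions)] for i in range(n)]
    sex = rng.choice(["F", "M"], size=n)
    age = rng.choice(["pup", "juvenile", "adult"], size=n, p=[0.1, 0.3, 0.6])
    weight = (intercept + beta_auto * z_auto + beta_x * z_x
              + beta_sex_male * (sex == "M")
              + np.array([region_effects[r] for r in region])
              + rng.normal(0.0, noise_sd, n))
    return pd.DataFrame({
        "sample": ancestry["sample"].tolist(),
        "region": region,
        "sex": sex,
        "age_class": age,
        "weight_kg": weight,
    })
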