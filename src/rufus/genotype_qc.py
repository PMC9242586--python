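"""SNP and sample quality-control filters for RADseq-style genotype matrices.

Implements the filtering chain used to build the study's two SNP sets:

1. drop singleton and private-doubleton alleles (minor-allele count 1, or 2
   with both copies in a single homozygote);
2. drop loci with more than 90% missing data, then individuals with more
   than 20% missing data (recomputed on the retained loci);
3. keep loci with minor allele frequency >= 3%;
4. for the "statistically neutral and unlinked" subset, additionally prune
   loci in 50-SNP sliding windows (step 5) whose squared genotype correlation
   exceeds 0.5, and drop loci deviating from Hardy-Weinberg equilibrium at
   an exact-test p < 0.001.

Tie-breaks, missing-data handling and test conventions are declared on each
function; external tools differ in these details and bit-for-bit agreement
with them is not a goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .formats_io import GenotypeMatrix, SnpMap

__all__ = [
    "QcConfig",
    "QcReport",
    "filter_missingness",
    "filter_rare",
    "hwe_exact_test",
    "ld_prune",
    "run_qc",
]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds of the filtering chain; defaults are the study's settings."""

    max_locus_missing: float = 0.90
    max_individual_missing: float = 0.20
    min_maf: float = 0.03
    ld_window: int = 50
    ld_step: int = 5
    ld_r2: float = 0.5
    hwe_alpha: float = 0.001
    drop_singletons_doubletons: bool = True

    def __post_init__(self):
        for name in ("max_locus_missing", "max_individual_missing", "min_maf"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if not self.ld_window >= self.ld_step >= 1:
            raise ValueError("require ld_window >= ld_step >= 1")


@dataclass
class QcReport:
    """Per-filter removal lists; locus entries are indices into the input matrix."""

    removed_loci: dict[str, list[int]] = field(default_factory=dict)
    removed_samples: dict[str, list[str]] = field(default_factory=dict)

    def add_loci(self, reason: str, indices) -> None:
        self.removed_loci.setdefault(reason, []).extend(int(i) for i in indices)

    def add_samples(self, reason: str, names) -> None:
        self.removed_samples.setdefault(reason, []).extend(names)


def _subset(gm: GenotypeMatrix, sample_idx, locus_idx) -> GenotypeMatrix:
    snp_map = gm.snp_map
    if snp_map is not None:
        locus_idx = np.asarray(locus_idx)
        cm = None if snp_map.pos_cm is None else snp_map.pos_cm[locus_idx]
        snp_map = SnpMap(snp_map.chrom[locus_idx], snp_map.pos_bp[locus_idx],
                         cm, snp_map.karyotype)
    return GenotypeMatrix(
        [gm.samples[i] for i in np.atleast_1d(sample_idx)],
        gm.values[np.ix_(np.atleast_1d(sample_idx), np.atleast_1d(locus_idx))],
        snp_map,
    )


def filter_missingness(gm: GenotypeMatrix, cfg: QcConfig = QcConfig(),
                       report: QcReport | None = None) -> GenotypeMatrix:
    """Drop loci with missingness strictly above the locus threshold, then
    individuals strictly above the individual threshold (on retained loci).

    A locus missing in exactly 90% of samples is retained ("more than 90%").
    Raises if every locus or every sample would be removed.
    """
    if gm.values.size == 0:
        raise ValueError("empty genotype matrix")
    report = report if report is not None else QcReport()
    locus_missing = np.isnan(gm.values).mean(axis=0)
    keep_loci = np.flatnonzero(locus_missing <= cfg.max_locus_missing)
    if keep_loci.size == 0:
        raise ValueError("all loci exceed the missingness threshold")
    report.add_loci("locus_missingness", np.flatnonzero(locus_missing > cfg.max_locus_missing))

    sample_missing = np.isnan(gm.values[:, keep_loci]).mean(axis=1)
    keep_samples = np.flatnonzero(sample_missing <= cfg.max_individual_missing)
    if keep_samples.size == 0:
        raise ValueError("all individuals exceed the missingness threshold")
    report.add_samples(
        "individual_missingness",
        [gm.samples[i] for i in np.flatnonzero(sample_missing > cfg.max_individual_missing)],
    )
    return _subset(gm, keep_samples, keep_loci)


def _allele_counts(values: np.ndarray):
    """Per-locus (minor allele count, total called copies, minor-is-alt flag)."""
    called = ~np.isnan(values)
    n_copies = 2 * called.sum(axis=0)
    alt = np.nansum(values, axis=0)
    ref = n_copies - alt
    minor = np.minimum(alt, ref)
    return minor, n_copies, alt <= ref


def filter_rare(gm: GenotypeMatrix, cfg: QcConfig = QcConfig(),
                report: QcReport | None = None, *,
                apply_maf: bool = True) -> GenotypeMatrix:
    """Drop singleton/private-doubleton loci, then apply the MAF floor.

    A singleton is minor-allele count 1; a private doubleton is count 2 with
    both copies in one individual (a single homozygote for the minor allele).
    Two heterozygous carriers in different samples are not a private
    doubleton. The MAF threshold is inclusive: MAF exactly at ``min_maf``
    is retained. ``apply_maf=False`` runs only the singleton/doubleton rule
    (the chain applies MAF after the missingness filters, as the source
    tooling order did).
    """
    report = report if report is not None else QcReport()
    values = gm.values
    minor, n_copies, minor_is_alt = _allele_counts(values)

    keep = np.ones(gm.n_loci, dtype=bool)
    if cfg.drop_singletons_doubletons:
        singleton = minor == 1
        # doubleton carried by a single homozygote: one sample holds both copies
        hom_minor_count = np.where(
            minor_is_alt, (values == 2).sum(axis=0), (values == 0).sum(axis=0)
        )
        het_count = (values == 1).sum(axis=0)
        private_doubleton = (minor == 2) & (hom_minor_count == 1) & (het_count == 0)
        keep &= ~(singleton | private_doubleton)
        report.add_loci("singleton", np.flatnonzero(singleton))
        report.add_loci("private_doubleton", np.flatnonzero(private_doubleton))

    if apply_maf:
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.where(n_copies > 0, minor / n_copies, 0.0)
        below = (maf < cfg.min_maf) & keep
        report.add_loci("maf", np.flatnonzero(below))
        keep &= ~below
    return _subset(gm, np.arange(gm.n_samples), np.flatnonzero(keep))


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of the same parity, the hypergeometric-weighted probabilities of
    configurations no more probable than the observed one. A monomorphic
    locus returns 1.0 by convention.
    """
    for x in (n_aa, n_ab, n_bb):
        if x < 0 or x != int(x):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | n, n_a) up to a common constant:
    #   P ∝ n! / (n_aa! n_ab! n_bb!) * 2^n_ab  with n_aa, n_bb fixed by h
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = hets * np.log(2) - (gammaln(n_rare_hom + 1) + gammaln(hets + 1)
                               + gammaln(n_common_hom + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[np.flatnonzero(hets == n_ab)[0]]
    # tie tolerance guards against FP noise when summing equal-probability tails
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def _corr2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two mean-imputed genotype vectors."""
    x = np.where(np.isnan(x), np.nanmean(x), x)
    y = np.where(np.isnan(y), np.nanmean(y), y)
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / np.sqrt(vx * vy)
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, cfg: QcConfig = QcConfig()) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns the retained locus indices.

    Windows of ``ld_window`` loci advance by ``ld_step``. Within a window,
    while any retained pair has squared genotype correlation above ``ld_r2``,
    one locus of the worst pair is dropped: the one with the lower MAF, or
    the later one on a tie. Genotype correlations use mean-imputed missing
    values. Loci are assumed ordered by map position.
    """
    n = gm.n_loci
    values = gm.values
    minor, n_copies, _ = _allele_counts(values)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_copies > 0, minor / n_copies, 0.0)
    keep = np.ones(n, dtype=bool)
    starts = range(0, max(n - 1, 1), cfg.ld_step)
    for start in starts:
        window = np.arange(start, min(start + cfg.ld_window, n))
        while True:
            active = window[keep[window]]
            if active.size < 2:
                break
            worst = None
            for a_pos in range(active.size - 1):
                for b_pos in range(a_pos + 1, active.size):
                    i, j = active[a_pos], active[b_pos]
                    r2 = _corr2(values[:, i], values[:, j])
                    if r2 > cfg.ld_r2 and (worst is None or r2 > worst[0]):
                        worst = (r2, i, j)
            if worst is None:
                break
            _, i, j = worst
            if maf[i] < maf[j]:
                keep[i] = False
            elif maf[j] < maf[i]:
                keep[j] = False
            else:
                keep[j] = False  # equal MAF: drop the later locus
        if start + cfg.ld_window >= n:
            break
    return np.flatnonzero(keep)


def run_qc(gm: GenotypeMatrix, cfg: QcConfig = QcConfig(), *,
           neutral_unlinked: bool = False) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full filtering chain; optionally add LD pruning + HWE filtering.

    With ``neutral_unlinked=False`` this produces the "full" SNP set
    (rare-allele, missingness and MAF filters); with ``True`` it additionally
    prunes linked loci and drops HWE-deviating loci, yielding a subset of the
    full set. The chain is idempotent: re-running it on its own output
    removes nothing.
    """
    report = QcReport()
    gm = filter_rare(gm, cfg, report, apply_maf=False)
    gm = filter_missingness(gm, cfg, report)
    gm = filter_rare(gm, cfg, report)  # sample removal can create new rare loci
    if neutral_unlinked:
        kept = ld_prune(gm, cfg)
        report.add_loci("ld_prune", np.setdiff1d(np.arange(gm.n_loci), kept))
        gm = _subset(gm, np.arange(gm.n_samples), kept)
        pvals = np.array([
            hwe_exact_test(
                int((gm.values[:, j] == 0).sum()),
                int((gm.values[:, j] == 1).sum()),
                int((gm.values[:, j] == 2).sum()),
            )
            for j in range(gm.n_loci)
        ])
        keep = np.flatnonzero(pvals >= cfg.hwe_alpha)
        report.add_loci("hwe", np.flatnonzero(pvals < cfg.hwe_alpha))
        gm = _subset(gm, np.arange(gm.n_samples), keep)
    return gm, report
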