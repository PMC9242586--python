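"""Private alleles across population sets, with ADZE-style rarefaction.

A private allele is an allele observed in exactly one population of a
defined set. Raw private-allele counts are sensitive to sample size, so a
combinatorial rarefaction standardises them to a common number of sampled
gene copies ``g``: at a locus where population ``j`` has ``N_j`` called
gene copies, ``N_ij`` of them carrying allele ``i``, the probability that a
subsample of ``g`` copies misses the allele is

    Q_ij(g) = C(N_j - N_ij, g) / C(N_j, g)

and the expected number of alleles private to ``j`` in subsamples of size
``g`` from every population is

    sum over loci, alleles of  (1 - Q_ij(g)) * prod_{j' != j} Q_ij'(g).

At ``g`` equal to every population's full copy count this reduces exactly
to the observed private-allele count. Binomials are evaluated in log space,
so copy counts up to ~1e4 are safe. Gene-copy counts are locus-specific
(missing genotypes excluded); loci where any population has fewer than
``g`` called copies are skipped at that ``g`` and the skip count reported.
The study standardised to ``G = 100`` gene copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .formats_io import GenotypeMatrix

__all__ = [
    "PopulationSet",
    "RarefactionResult",
    "private_allele_count",
    "rarefied_private_alleles",
    "rarefaction_curve",
    "DEFAULT_G",
]

DEFAULT_G = 100  # standardized sample size in gene copies


@dataclass(frozen=True)
class PopulationSet:
    """Sample -> population labels, with an optional focal population."""

    labels: dict[str, str]
    focal: str | None = None

    def __post_init__(self):
        if len(self.populations) < 2:
            raise ValueError("need at least two populations")
        if self.focal is not None and self.focal not in self.populations:
            raise ValueError(f"focal population {self.focal!r} not in labels")

    @property
    def populations(self) -> list[str]:
        seen = []
        for p in self.labels.values():
            if p not in seen:
                seen.append(p)
        return seen

    def member_indices(self, samples: list[str]) -> dict[str, np.ndarray]:
        unlabeled = [s for s in samples if s not in self.labels]
        if unlabeled:
            raise ValueError(f"samples without population label: {unlabeled[:5]}")
        return {
            pop: np.array([i for i, s in enumerate(samples) if self.labels[s] == pop])
            for pop in self.populations
        }


def _copy_counts(gm: GenotypeMatrix, pops: PopulationSet):
    """Per-population arrays of (called gene copies, alt copies) per locus."""
    idx = pops.member_indices(gm.samples)
    n_copies, alt_copies = {}, {}
    for pop, rows in idx.items():
        sub = gm.values[rows]
        called = ~np.isnan(sub)
        if called.sum() == 0:
            raise ValueError(f"population {pop!r} has no called genotypes")
        n_copies[pop] = 2 * called.sum(axis=0)
        alt_copies[pop] = np.nansum(sub, axis=0)
    return n_copies, alt_copies


def private_allele_count(gm: GenotypeMatrix, pops: PopulationSet) -> pd.Series:
    """Observed count of (locus, allele) pairs private to each population.

    An allele counts as private to a population when at least one copy is
    called there and no copies are called in any other population at that
    locus. Missing genotypes are simply excluded.
    """
    n_copies, alt_copies = _copy_counts(gm, pops)
    populations = pops.populations
    counts = {}
    for pop in populations:
        total = 0
        for allele in ("alt", "ref"):
            if allele == "alt":
                here = alt_copies[pop]
                elsewhere = sum(alt_copies[q] for q in populations if q != pop)
            else:
                here = n_copies[pop] - alt_copies[pop]
                elsewhere = sum(n_copies[q] - alt_copies[q]
                                for q in populations if q != pop)
            total += int(((here > 0) & (elsewhere == 0)).sum())
        counts[pop] = total
    return pd.Series(counts, name="private_alleles")


def _log_absent_prob(n: np.ndarray, k: np.ndarray, g: int) -> np.ndarray:
    """log Q = log[ C(n-k, g) / C(n, g) ], with Q = 0 where n - k < g."""
    n = np.asarray(n, float)
    k = np.asarray(k, float)
    with np.errstate(invalid="ignore"):
        logq = (gammaln(n - k + 1) - gammaln(n - k - g + 1)
                - gammaln(n + 1) + gammaln(n - g + 1))
    return np.where(n - k < g, -np.inf, logq)


@dataclass
class RarefactionResult:
    """Expected private alleles per population at one g, plus skipped-locus count."""

    g: int
    expected: pd.Series
    n_loci_used: int
    n_loci_skipped: int


def rarefied_private_alleles(gm: GenotypeMatrix, pops: PopulationSet,
                             g: int) -> RarefactionResult:
    """Expected private-allele count per population at ``g`` sampled gene copies.

    Loci where any population has fewer than ``g`` called copies are skipped
    at this ``g`` (their number is reported in the result). Raises if ``g``
    exceeds every locus's copy count for some population, or if g < 2.
    """
    if g < 2:
        raise ValueError("g must be at least 2 gene copies")
    n_copies, alt_copies = _copy_counts(gm, pops)
    populations = pops.populations
    usable = np.ones(gm.n_loci, dtype=bool)
    for pop in populations:
        if n_copies[pop].max() < g:
            raise ValueError(
                f"g={g} exceeds the maximum copy count of population {pop!r} "
                f"({int(n_copies[pop].max())}) at every locus"
            )
        usable &= n_copies[pop] >= g
    if not usable.any():
        raise ValueError(f"no locus has >= {g} called copies in every population")

    expected = {}
    for pop in populations:
        total = 0.0
        for allele in ("alt", "ref"):
            # log Q per population at the usable loci for this allele
            logq = {}
            for q in populations:
                k = alt_copies[q] if allele == "alt" else n_copies[q] - alt_copies[q]
                logq[q] = _log_absent_prob(n_copies[q][usable], k[usable], g)
            present = 1.0 - np.exp(logq[pop])
            absent_elsewhere = np.exp(
                sum(logq[q] for q in populations if q != pop)
            )
            total += float((present * absent_elsewhere).sum())
        expected[pop] = total
    return RarefactionResult(
        g=g,
        expected=pd.Series(expected, name=f"rarefied_g{g}"),
        n_loci_used=int(usable.sum()),
        n_loci_skipped=int((~usable).sum()),
    )


def rarefaction_curve(gm: GenotypeMatrix, pops: PopulationSet,
                      g_max: int = DEFAULT_G) -> pd.DataFrame:
    """Expected private alleles for each g in 2..g_max (rows: g; cols: pop).

    g values exceeding every population's locus-wise copy counts are omitted
    from the curve rather than raising.
    """
    rows = []
    for g in range(2, g_max + 1):
        try:
            res = rarefied_private_alleles(gm, pops, g)
        except ValueError:
            break
        row = res.expected.to_dict()
        row["g"] = g
        row["n_loci_used"] = res.n_loci_used
        rows.append(row)
    if not rows:
        raise ValueError("no g in range is attainable for every population")
    return pd.DataFrame(rows).set_index("g")
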