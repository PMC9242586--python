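"""Dating a single admixture pulse from diploid ancestry switch counts.

Under a one-pulse admixture model with admixture proportion ``z`` followed
by ``T`` generations of random mating, the expected number of diploid
ancestry switches across a genome of genetic length ``L`` centimorgans is

    B = 0.04 * T * L * z * (1 - z)

(two haplotypes, each accumulating crossovers at ``T * L / 100`` per genome,
each crossover changing ancestry with probability ``2 z (1 - z)``). The
estimator inverts this: ``T = B / (0.04 * L * z * (1 - z))``, applied
separately to autosomes (L = 2085 cM) and the X chromosome (L = 111 cM).
Generations convert to calendar years by averaging 2- and 4-year generation
times, i.e. ``years = 3 T``.

A genome with ``z`` of exactly 0 or 1 carries no admixture signal; its
timing is undefined and reported as a flagged null (the published table's
convention renders such entries as ``0.0``, available via
``undefined_as_zero=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLengths",
    "TimingEstimate",
    "UndefinedTimingError",
    "expected_switches",
    "estimate_generations",
    "generations_to_years",
    "timing_report",
]

SWITCH_CONSTANT = 0.04  # diploid: 2 haplotypes x crossover rate x 2z(1-z)
YEARS_PER_GENERATION = 3.0  # mean of the 2- and 4-year generation times


@dataclass(frozen=True)
class GenomeLengths:
    """Genetic map lengths in centimorgans; defaults are the canid values."""

    autosomal_cm: float = 2085.0
    x_cm: float = 111.0

    def __post_init__(self):
        if self.autosomal_cm <= 0 or self.x_cm <= 0:
            raise ValueError("map lengths must be positive")


class UndefinedTimingError(ValueError):
    """Raised when z is 0 or 1: an unadmixed compartment has no timing."""


@dataclass(frozen=True)
class TimingEstimate:
    """One compartment's dating: switch count, proportion, generations, years."""

    b: float
    z: float
    l_cm: float
    generations: float
    years: float


def expected_switches(t: float, l_cm: float, z: float) -> float:
    """Expected diploid switch count B = 0.04 * T * L * z * (1 - z)."""
    if t < 0:
        raise ValueError("generations must be non-negative")
    if l_cm <= 0:
        raise ValueError("map length must be positive")
    if not 0 <= z <= 1:
        raise ValueError("ancestry proportion must lie in [0, 1]")
    return SWITCH_CONSTANT * t * l_cm * z * (1 - z)


def estimate_generations(b: float, l_cm: float, z: float) -> float:
    """Generations since the pulse: T = B / (0.04 * L * z * (1 - z)).

    Raises :class:`UndefinedTimingError` for z in {0, 1}.
    """
    if b < 0:
        raise ValueError("switch count must be non-negative")
    if l_cm <= 0:
        raise ValueError("map length must be positive")
    if not 0 <= z <= 1:
        raise ValueError("ancestry proportion must lie in [0, 1]")
    if z == 0.0 or z == 1.0:
        raise UndefinedTimingError(
            f"timing undefined at z={z}: compartment carries a single ancestry"
        )
    return b / (SWITCH_CONSTANT * l_cm * z * (1 - z))


def generations_to_years(t: float) -> float:
    """Calendar years = 3 T (average of 2- and 4-year generation times)."""
    if t < 0:
        raise ValueError("generations must be non-negative")
    return YEARS_PER_GENERATION * t


def _estimate(b: float, z: float, l_cm: float) -> tuple[float, float, bool]:
    try:
        t = estimate_generations(b, l_cm, z)
        return t, generations_to_years(t), False
    except UndefinedTimingError:
        return np.nan, np.nan, True


def timing_report(summary: pd.DataFrame,
                  lengths: GenomeLengths = GenomeLengths(), *,
                  undefined_as_zero: bool = False) -> pd.DataFrame:
    """Per-sample autosomal and X timing from an ancestry summary frame.

    ``summary`` needs columns sample, z_auto, z_x, b_auto, b_x (as produced
    by :func:`rufus.ancestry_blocks.ancestry_summary`). Samples whose z is
    exactly 0 or 1 get NaN timing and a flag column rather than being
    dropped; ``undefined_as_zero=True`` renders those entries as 0.0 to
    match the published table's convention.
    """
    rows = []
    for rec in summary.itertuples(index=False):
        t_a, y_a, und_a = _estimate(rec.b_auto, rec.z_auto, lengths.autosomal_cm)
        if np.isnan(rec.z_x) if isinstance(rec.z_x, float) else False:
            t_x, y_x, und_x = np.nan, np.nan, True
        else:
            t_x, y_x, und_x = _estimate(rec.b_x, rec.z_x, lengths.x_cm)
        if undefined_as_zero:
            if und_a:
                t_a, y_a = 0.0, 0.0
            if und_x:
                t_x, y_x = 0.0, 0.0
        rows.append({
            "sample": rec.sample,
            "z_auto": rec.z_auto, "b_auto": rec.b_auto,
            "t_auto": t_a, "years_auto": y_a, "undefined_auto": und_a,
            "z_x": rec.z_x, "b_x": rec.b_x,
            "t_x": t_x, "years_x": y_x, "undefined_x": und_x,
        })
    return pd.DataFrame(rows)
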