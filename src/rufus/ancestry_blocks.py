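"""Local-ancestry tracks: dosage classification, block segmentation, summaries.

A diploid genome painted by a two-source local-ancestry method carries, at
each SNP, a red-wolf allele dosage in ``[0, 2]``. Dosages are discretised
into three ancestry states — homozygous coyote, heterozygous ("joint"), and
homozygous red wolf — using the published thresholds: dosage below 0.8 is
homozygous coyote, between 0.8 and 1.8 (inclusive on both ends) is
heterozygous, and above 1.8 is homozygous red wolf.

Maximal runs of identical state along a chromosome form ancestry blocks.
Block span is first-to-last SNP of the run (no extension toward flanking
SNPs), so a single-SNP block has length 0 — a conservative, map-independent
convention. Missing-dosage SNPs are transparent: a run continues across them.

Adjacent blocks of different state contribute ancestry *switches*: one for
coyote<->heterozygous or heterozygous<->red wolf, two for coyote<->red wolf
(both haplotypes must change). The diploid switch count ``B`` summed over
chromosomes feeds the admixture-timing equation, and equals the minimal
number of per-haplotype ancestry changes over all phasings consistent with
the unphased state sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .formats_io import DosageMatrix, SnpMap

__all__ = [
    "AncestryState",
    "Block",
    "AncestryTrackSet",
    "classify_dosages",
    "segment_blocks",
    "ancestry_proportion",
    "count_switches",
    "block_statistics",
    "ancestry_summary",
    "MISSING_STATE",
]

MISSING_STATE = -1

HET_LOW = 0.8
HET_HIGH = 1.8


class AncestryState(IntEnum):
    """Diploid ancestry state; the integer value is the red-wolf haplotype count."""

    COY_HOM = 0
    HET = 1
    RW_HOM = 2


@dataclass(frozen=True)
class Block:
    """One ancestry block: 1-based inclusive bp span of a run of equal state."""

    chrom: str
    start: int
    end: int
    state: AncestryState
    n_snps: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"block start {self.start} > end {self.end}")
        if self.n_snps < 1:
            raise ValueError("block must contain at least one SNP")

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6


class AncestryTrackSet:
    """Per-sample, per-chromosome ordered blocks partitioning the classified SNPs."""

    def __init__(self, tracks: dict[str, dict[str, list[Block]]]):
        self._tracks = tracks
        for sample, per_chrom in tracks.items():
            for chrom, blocks in per_chrom.items():
                for a, b in zip(blocks, blocks[1:]):
                    if b.start <= a.end:
                        raise ValueError(
                            f"unsorted/overlapping blocks for {sample} on {chrom}"
                        )
                    if b.state == a.state:
                        raise ValueError(
                            f"adjacent blocks share state for {sample} on {chrom}"
                        )

    @property
    def samples(self) -> list[str]:
        return list(self._tracks)

    def chromosomes(self, sample: str) -> list[str]:
        return list(self._tracks[sample])

    def blocks(self, sample: str, chrom: str) -> list[Block]:
        return self._tracks[sample].get(chrom, [])

    def iter_blocks(self) -> Iterator[tuple[str, str, Block]]:
        for sample, per_chrom in self._tracks.items():
            for chrom, blocks in per_chrom.items():
                for block in blocks:
                    yield sample, chrom, block

    def __eq__(self, other) -> bool:
        if not isinstance(other, AncestryTrackSet):
            return NotImplemented
        return self._tracks == other._tracks


def classify_dosages(dosages: DosageMatrix | np.ndarray) -> np.ndarray:
    """Map dosages to ancestry states (int matrix; -1 where dosage is missing).

    ``d < 0.8`` -> COY_HOM, ``0.8 <= d <= 1.8`` -> HET, ``d > 1.8`` -> RW_HOM.
    Both band boundaries classify as heterozygous.
    """
    values = dosages.values if isinstance(dosages, DosageMatrix) else np.asarray(dosages, float)
    states = np.full(values.shape, MISSING_STATE, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        states[values < HET_LOW] = AncestryState.COY_HOM
        states[(values >= HET_LOW) & (values <= HET_HIGH)] = AncestryState.HET
        states[values > HET_HIGH] = AncestryState.RW_HOM
    return states


def _run_lengths(states_1d: np.ndarray):
    """(start_idx, end_idx, value) for maximal runs of equal value."""
    n = len(states_1d)
    if n == 0:
        return []
    change = np.flatnonzero(states_1d[1:] != states_1d[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [n - 1]))
    return list(zip(starts, ends, states_1d[starts]))


def segment_blocks(states: np.ndarray, snp_map: SnpMap,
                   samples: list[str]) -> AncestryTrackSet:
    """Run-length segment state matrices into per-chromosome ancestry blocks.

    ``states`` is samples x SNPs with values in {0, 1, 2, -1 (missing)};
    missing SNPs are dropped before segmentation, so runs continue across
    them. A chromosome with no classified SNPs contributes no blocks.
    """
    states = np.asarray(states)
    if states.shape != (len(samples), len(snp_map)):
        raise ValueError("state matrix shape does not match samples x SNP map")
    tracks: dict[str, dict[str, list[Block]]] = {s: {} for s in samples}
    for chrom in snp_map.chromosomes:
        sl = snp_map.chrom_slice(chrom)
        pos = snp_map.pos_bp[sl]
        sub = states[:, sl]
        for i, sample in enumerate(samples):
            row = sub[i]
            called = row != MISSING_STATE
            if not called.any():
                continue
            cpos = pos[called]
            crow = row[called]
            blocks = [
                Block(chrom=chrom, start=int(cpos[a]), end=int(cpos[b]),
                      state=AncestryState(int(v)), n_snps=int(b - a + 1))
                for a, b, v in _run_lengths(crow)
            ]
            tracks[sample][chrom] = blocks
    return AncestryTrackSet(tracks)


def ancestry_proportion(dosages: DosageMatrix, chroms: Iterable[str]) -> np.ndarray:
    """Per-sample red wolf ancestry proportion z = mean(dosage)/2 on ``chroms``.

    Missing dosages are excluded from the mean. Raises if any sample has no
    called dosage on the requested chromosomes.
    """
    idx = dosages.snp_map.chrom_indices(chroms)
    if idx.size == 0:
        raise ValueError("no SNPs on the requested chromosomes")
    sub = dosages.values[:, idx]
    n_called = (~np.isnan(sub)).sum(axis=1)
    if (n_called == 0).any():
        bad = dosages.samples[int(np.flatnonzero(n_called == 0)[0])]
        raise ValueError(f"sample {bad!r} has no called dosages on the requested chromosomes")
    return np.nanmean(sub, axis=1) / 2.0


def count_switches(track_set: AncestryTrackSet, sample: str,
                   chroms: Iterable[str]) -> int:
    """Diploid ancestry switch count B for one sample over a chromosome set.

    Per chromosome, adjacent block pairs contribute the state distance
    |state_a - state_b| (1 for a one-haplotype change, 2 for coyote<->red
    wolf); chromosome ends contribute nothing.
    """
    b = 0
    for chrom in chroms:
        blocks = track_set.blocks(sample, chrom)
        for a, c in zip(blocks, blocks[1:]):
            b += abs(int(a.state) - int(c.state))
    return b


def block_statistics(track_set: AncestryTrackSet,
                     chroms: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-sample, per-state mean and longest block length in Mb.

    Restricted to ``chroms`` when given (the published block-size table is
    autosomes only). States with no blocks report 0 with ``present=False``.
    """
    chrom_set = None if chroms is None else set(chroms)
    rows = []
    for sample in track_set.samples:
        lengths: dict[AncestryState, list[float]] = {s: [] for s in AncestryState}
        for chrom in track_set.chromosomes(sample):
            if chrom_set is not None and chrom not in chrom_set:
                continue
            for block in track_set.blocks(sample, chrom):
                lengths[block.state].append(block.length_mb)
        for state, vals in lengths.items():
            rows.append({
                "sample": sample,
                "state": state.name,
                "n_blocks": len(vals),
                "mean_mb": float(np.mean(vals)) if vals else 0.0,
                "longest_mb": float(np.max(vals)) if vals else 0.0,
                "present": bool(vals),
            })
    return pd.DataFrame(rows)


def ancestry_summary(dosages: DosageMatrix,
                     x_chromosomes: Iterable[str] = ("X",)) -> pd.DataFrame:
    """Per-sample ancestry proportions and switch counts for both compartments.

    Returns a frame with columns sample, z_auto, z_x, b_auto, b_x (the X
    columns are NaN when the map carries no X SNPs). z is mean dosage / 2;
    B comes from classify -> segment -> count_switches.
    """
    snp_map = dosages.snp_map
    x_set = set(x_chromosomes)
    autosomes = [c for c in snp_map.chromosomes if c not in x_set]
    x_present = [c for c in snp_map.chromosomes if c in x_set]
    states = classify_dosages(dosages)
    tracks = segment_blocks(states, snp_map, dosages.samples)
    z_auto = ancestry_proportion(dosages, autosomes)
    z_x = ancestry_proportion(dosages, x_present) if x_present else np.full(len(dosages.samples), np.nan)
    rows = []
    for i, sample in enumerate(dosages.samples):
        rows.append({
            "sample": sample,
            "z_auto": float(z_auto[i]),
            "z_x": float(z_x[i]),
            "b_auto": count_switches(tracks, sample, autosomes),
            "b_x": count_switches(tracks, sample, x_present) if x_present else np.nan,
        })
    return pd.DataFrame(rows)
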