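"""Readers, writers and bundled fixtures for every on-disk format the pipeline touches.

The pipeline consumes four external representations:

* a tab/whitespace-delimited **dosage matrix** (local-ancestry HMM output style):
  one row per sample, leading sample id, one column per SNP with the red-wolf
  allele dosage in ``[0, 2]`` (``NA`` for missing);
* a tab-delimited **SNP map** with chromosome, 1-based physical position and an
  optional centimorgan position;
* biallelic **genotypes** as VCF or as a PLINK-style transposed text table
  (one row per SNP, alternate-allele counts per sample);
* CSV **sample metadata** (id, region, sex, age class, weight in kg).

It also ships three small fixtures transcribing the published cohort tables
(ancestry proportions and admixture timing; per-coyote ancestry block sizes;
the 1970s Texas canids), used by the summary stage and the acceptance checks.

Conventions pinned here and used everywhere: dosage counts copies of red wolf
ancestry (0 = homozygous coyote, 2 = homozygous red wolf); internal genomic
coordinates are 1-based inclusive; BED output is 0-based half-open.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Karyotype",
    "CANID_KARYOTYPE",
    "SnpMap",
    "DosageMatrix",
    "GenotypeMatrix",
    "FormatError",
    "read_snp_map",
    "write_snp_map",
    "read_dosage",
    "write_dosage",
    "average_dosage_runs",
    "read_genotypes",
    "write_genotypes_plink_text",
    "write_vcf",
    "read_metadata",
    "write_blocks_bed",
    "read_blocks_bed",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_cohort",
]

DOSAGE_TOL = 1e-6


class FormatError(ValueError):
    """Malformed or out-of-contract input file; message carries the location."""


# ---------------------------------------------------------------------------
# karyotype and SNP map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Karyotype:
    """An ordered set of chromosome names with the X-like names singled out.

    Canids carry 38 acrocentric autosomes plus X/Y; the default instance
    below models the 38 autosomes and X (the pipeline has no Y data).
    Arbitrary karyotypes are allowed for toys and simulations.
    """

    chromosomes: tuple[str, ...]
    x_chromosomes: frozenset[str] = frozenset({"X"})

    def __post_init__(self):
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names in karyotype")

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.chromosomes if c not in self.x_chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


CANID_KARYOTYPE = Karyotype(tuple(str(i) for i in range(1, 39)) + ("X",))


class SnpMap:
    """Ordered SNP coordinates: chromosome, 1-based bp, optional cM position.

    Positions must be strictly increasing within each chromosome, and each
    chromosome must form one contiguous run of records. If a karyotype is
    supplied, every chromosome id must belong to it.
    """

    def __init__(
        self,
        chrom: Sequence[str],
        pos_bp: Sequence[int],
        pos_cm: Sequence[float] | None = None,
        karyotype: Karyotype | None = None,
    ):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos_bp = np.asarray(pos_bp, dtype=np.int64)
        self.pos_cm = None if pos_cm is None else np.asarray(pos_cm, dtype=float)
        self.karyotype = karyotype
        if self.chrom.shape != self.pos_bp.shape:
            raise FormatError("chromosome and position columns differ in length")
        if self.pos_cm is not None and self.pos_cm.shape != self.pos_bp.shape:
            raise FormatError("cM column length does not match positions")
        self._index = {}
        seen_done = set()
        i = 0
        n = len(self.chrom)
        while i < n:
            c = self.chrom[i]
            if c in seen_done:
                raise FormatError(f"chromosome {c!r} appears in non-contiguous runs")
            j = i
            while j + 1 < n and self.chrom[j + 1] == c:
                if self.pos_bp[j + 1] <= self.pos_bp[j]:
                    raise FormatError(
                        f"positions not strictly increasing on chromosome {c!r} "
                        f"at record {j + 2}"
                    )
                j += 1
            self._index[c] = slice(i, j + 1)
            seen_done.add(c)
            i = j + 1
        if karyotype is not None:
            bad = [c for c in self._index if c not in karyotype]
            if bad:
                raise FormatError(f"chromosomes not in karyotype: {bad}")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def n_snps(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._index)

    def chrom_slice(self, chrom: str) -> slice:
        """Column slice of the SNPs on one chromosome."""
        return self._index[chrom]

    def chrom_indices(self, chroms: Iterable[str]) -> np.ndarray:
        """Concatenated column indices for a set of chromosomes (map order)."""
        parts = [np.arange(self._index[c].start, self._index[c].stop)
                 for c in self.chromosomes if c in set(chroms)]
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(parts)


def read_snp_map(path: str | os.PathLike, karyotype: Karyotype | None = None) -> SnpMap:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    for col in ("chrom", "pos_bp"):
        if col not in df.columns:
            raise FormatError(f"{path}: SNP map missing column {col!r}")
    cm = df["pos_cm"].to_numpy(float) if "pos_cm" in df.columns else None
    return SnpMap(df["chrom"].to_numpy(object), df["pos_bp"].to_numpy(np.int64),
                  cm, karyotype)


def write_snp_map(snp_map: SnpMap, path: str | os.PathLike) -> None:
    df = pd.DataFrame({"chrom": snp_map.chrom, "pos_bp": snp_map.pos_bp})
    if snp_map.pos_cm is not None:
        df["pos_cm"] = snp_map.pos_cm
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dosage matrices
# ---------------------------------------------------------------------------


@dataclass
class DosageMatrix:
    """Samples x SNPs red-wolf-allele dosage in [0, 2]; NaN marks missing.

    Rows align with ``samples``; columns align with ``snp_map``.
    """

    samples: list[str]
    values: np.ndarray
    snp_map: SnpMap

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.snp_map)):
            raise FormatError(
                f"dosage matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snp_map)} SNPs"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.values < -DOSAGE_TOL) | (self.values > 2 + DOSAGE_TOL)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"dosage {self.values[r, c]} outside [0, 2] at sample "
                f"{self.samples[r]!r} (row {r + 1}), SNP column {c + 1}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, sample: str) -> np.ndarray:
        return self.values[self.samples.index(sample)]


def read_dosage(path: str | os.PathLike, snp_map: SnpMap) -> DosageMatrix:
    """Read a delimited dosage matrix: one row per sample, leading sample id.

    Values must be in ``[0, 2]`` within 1e-6 or ``NA``/``nan`` for missing;
    out-of-range values are rejected with their location, never clamped.
    """
    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            samples.append(fields[0])
            try:
                row = np.array(
                    [np.nan if f.upper() in ("NA", "NAN", ".") else float(f)
                     for f in fields[1:]],
                    dtype=float,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric dosage ({exc})")
            if len(row) != len(snp_map):
                raise FormatError(
                    f"{path}:{lineno}: {len(row)} dosages but SNP map has "
                    f"{len(snp_map)} sites"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty dosage file")
    values = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        bad = (values < -DOSAGE_TOL) | (values > 2 + DOSAGE_TOL)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: dosage {values[r, c]} outside [0, 2] at row {r + 1} "
            f"(sample {samples[r]!r}), column {c + 2}"
        )
    return DosageMatrix(samples, values, snp_map)


def write_dosage(dm: DosageMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s, row in zip(dm.samples, dm.values):
            vals = "\t".join("NA" if np.isnan(v) else format(v, ".6g") for v in row)
            fh.write(f"{s}\t{vals}\n")


def average_dosage_runs(paths: Sequence[str | os.PathLike], snp_map: SnpMap) -> DosageMatrix:
    """Elementwise mean over replicate dosage runs (e.g. 12 independent HMM fits).

    All runs must share sample ids in the same order and the same SNP map; a
    cell missing in any run is missing in the mean (no partial averaging).
    """
    if not paths:
        raise FormatError("no dosage runs given")
    first = read_dosage(paths[0], snp_map)
    acc = first.values.copy()
    for p in paths[1:]:
        run = read_dosage(p, snp_map)
        if run.samples != first.samples:
            raise FormatError(f"{p}: sample ids/order differ from {paths[0]}")
        acc += run.values
    return DosageMatrix(first.samples, acc / len(paths), snp_map)


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alternate-allele counts {0,1,2}; NaN marks missing."""

    samples: list[str]
    values: np.ndarray
    snp_map: SnpMap | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.samples):
            raise FormatError("genotype matrix shape does not match sample list")
        with np.errstate(invalid="ignore"):
            ok = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0))
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise FormatError(
                f"genotype {self.values[r, c]} not in {{0,1,2,missing}} at "
                f"sample {self.samples[r]!r}, locus column {c + 1}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]


def read_genotypes(path: str | os.PathLike, fmt: str = "vcf") -> GenotypeMatrix:
    """Read biallelic genotypes from ``vcf`` or ``plink_text``.

    Multi-allelic VCF records are rejected (strict policy). The PLINK-style
    text format is a transposed table: header ``chrom pos id ref alt`` then
    sample ids, one row per SNP with per-sample alt-allele counts or ``NA``.
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "plink_text":
        return _read_plink_text(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if os.path.getsize(path) == 0:
        raise FormatError(f"{path}: empty VCF")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, pos, rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(
                f"{path}: non-biallelic record at {var.CHROM}:{var.POS}"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        row = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        chroms.append(var.CHROM)
        pos.append(var.POS)
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: VCF contains no variant records")
    snp_map = SnpMap(chroms, pos)
    return GenotypeMatrix(samples, np.vstack(rows).T, snp_map)


def _read_plink_text(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", comment="#", na_values=["NA", "."])
    fixed = ["chrom", "pos", "id", "ref", "alt"]
    if list(df.columns[:5]) != fixed:
        raise FormatError(f"{path}: expected leading columns {fixed}")
    if df.empty:
        raise FormatError(f"{path}: no variant rows")
    samples = list(df.columns[5:])
    if not samples:
        raise FormatError(f"{path}: no sample columns")
    values = df[samples].to_numpy(float).T
    snp_map = SnpMap(df["chrom"].astype(str).to_numpy(object),
                     df["pos"].to_numpy(np.int64))
    return GenotypeMatrix(samples, values, snp_map)


def write_genotypes_plink_text(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    if gm.snp_map is None:
        raise ValueError("genotype matrix has no SNP map to write coordinates from")
    df = pd.DataFrame({
        "chrom": gm.snp_map.chrom,
        "pos": gm.snp_map.pos_bp,
        "id": [f"snp{i + 1}" for i in range(gm.n_loci)],
        "ref": "A",
        "alt": "T",
    })
    for i, s in enumerate(gm.samples):
        col = gm.values[i]
        df[s] = [("NA" if np.isnan(v) else str(int(v))) for v in col]
    df.to_csv(path, sep="\t", index=False)


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal uncompressed VCF (GT only) for round-trip tests and toys."""
    if gm.snp_map is None:
        raise ValueError("genotype matrix has no SNP map to write coordinates from")
    gt_str = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in gm.snp_map.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_loci):
            gts = "\t".join(
                "./." if np.isnan(v) else gt_str[v] for v in gm.values[:, j]
            )
            fh.write(f"{gm.snp_map.chrom[j]}\t{gm.snp_map.pos_bp[j]}\tsnp{j + 1}"
                     f"\tA\tT\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

AGE_CLASSES = ("pup", "juvenile", "adult")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read sample metadata CSV: sample, region, sex, age_class, weight_kg.

    Weight may be missing; when present it must be positive. Age classes are
    restricted to pup/juvenile/adult.
    """
    df = pd.read_csv(path, comment="#")
    required = {"sample", "region", "sex", "age_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    bad_age = set(df["age_class"].dropna()) - set(AGE_CLASSES)
    if bad_age:
        raise FormatError(f"{path}: unknown age classes {sorted(bad_age)}")
    if "weight_kg" in df.columns:
        w = df["weight_kg"]
        if (w.dropna() <= 0).any():
            row = df.index[w <= 0][0]
            raise FormatError(f"{path}: non-positive weight at row {row + 2}")
    return df


# ---------------------------------------------------------------------------
# BED export/import of ancestry blocks
# ---------------------------------------------------------------------------


def write_blocks_bed(track_set, path: str | os.PathLike) -> None:
    """Write ancestry blocks as BED: 0-based half-open, sorted by (chrom, start).

    Extra columns: sample id, ancestry state name, SNP count. Internal block
    coordinates are 1-based inclusive, so start_bed = start - 1, end_bed = end.
    """
    records = []
    for sample, chrom, block in track_set.iter_blocks():
        records.append((chrom, block.start - 1, block.end, sample,
                        block.state.name, block.n_snps))
    records.sort(key=lambda r: (str(r[0]), r[1], r[3]))
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_blocks_bed(path: str | os.PathLike):
    """Read a blocks BED written by :func:`write_blocks_bed`."""
    from .ancestry_blocks import AncestryState, AncestryTrackSet, Block

    per_sample: dict[str, dict[str, list[Block]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            chrom, start, end, sample, state, n_snps = line.split("\t")
            block = Block(
                chrom=chrom,
                start=int(start) + 1,
                end=int(end),
                state=AncestryState[state],
                n_snps=int(n_snps),
            )
            per_sample.setdefault(sample, {}).setdefault(chrom, []).append(block)
    for chrom_map in per_sample.values():
        for blocks in chrom_map.values():
            blocks.sort(key=lambda b: b.start)
    return AncestryTrackSet(per_sample)


# ---------------------------------------------------------------------------
# bundled cohort-table fixtures
# ---------------------------------------------------------------------------


def _fixture(name: str) -> pd.DataFrame:
    text = resources.files("rufus.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", comment="#")


def load_table1() -> pd.DataFrame:
    """Published per-coyote ancestry proportions and admixture timing (31 rows).

    Columns: sample, parish, auto_ancestry, x_ancestry, auto_timing_years,
    x_timing_years, corrected. ``corrected`` flags the single transcription
    correction (one autosomal timing entry printed with a shifted decimal
    point; stored at the value consistent with the column scale).
    """
    df = _fixture("table1_ancestry_timing.tsv")
    assert len(df) == 31
    return df


def load_table2() -> pd.DataFrame:
    """Published per-coyote mean autosomal block sizes in Mb (31 rows).

    Columns: sample, parish, subregion (NW/NE/SW within Cameron, else NaN),
    coyote_mb, joint_mb, redwolf_mb.
    """
    df = _fixture("table2_block_sizes.tsv")
    assert len(df) == 31
    return df


def load_table3() -> pd.DataFrame:
    """Published 1970s Texas canid ancestry proportions (10 rows)."""
    df = _fixture("table3_texas_canids.tsv")
    assert len(df) == 10
    return df


def load_cohort() -> pd.DataFrame:
    """Join of the two cohort tables with a derived region label.

    The region label is ``"<parish>-<subregion>"`` for Cameron rows (the
    subregion comes from the block-size table, which is the only place it is
    printed) and the bare parish elsewhere.
    """
    t1 = load_table1()
    t2 = load_table2()
    merged = t1.merge(t2[["sample", "subregion", "coyote_mb", "joint_mb", "redwolf_mb"]],
                      on="sample", validate="one_to_one")
    region = [
        f"{p}-{s}" if isinstance(s, str) and s else p
        for p, s in zip(merged["parish"], merged["subregion"])
    ]
    merged["region"] = region
    return merged
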