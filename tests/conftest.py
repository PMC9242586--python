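import numpy as np
import pytest

from rufus.formats_io import DosageMatrix, GenotypeMatrix, SnpMap


@pytest.fixture
def toy_map():
    """Two chromosomes, three SNPs each, megabase-spaced."""
    return SnpMap(
        ["1", "1", "1", "2", "2", "2"],
        [1_000_000, 2_000_000, 3_000_000, 1_000_000, 2_000_000, 4_000_000],
    )


@pytest.fixture
def toy_dosage(toy_map):
    values = np.array([
        [0.0, 0.1, 1.0, 1.5, 2.0, 2.0],
        [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
    ])
    return DosageMatrix(["s1", "s2"], values, toy_map)


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)


def make_genotypes(values, samples=None, chrom="1"):
    values = np.asarray(values, float)
    samples = samples or [f"ind{i}" for i in range(values.shape[0])]
    snp_map = SnpMap([chrom] * values.shape[1],
                     (np.arange(values.shape[1]) + 1) * 1000)
    return GenotypeMatrix(list(samples), values, snp_map)
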