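import numpy as np
import pandas as pd
import pytest

from rufus.diversity import (
    PopulationSet,
    private_allele_count,
    rarefaction_curve,
    rarefied_private_alleles,
)
from rufus.diversity import _log_absent_prob

from conftest import make_genotypes


def pops_for(samples, assignment):
    return PopulationSet({s: assignment[i] for i, s in enumerate(samples)})


def brute_force_private(values, labels):
    """Per-locus, per-allele set-membership oracle for private-allele counts."""
    pops = sorted(set(labels))
    counts = dict.fromkeys(pops, 0)
    for j in range(values.shape[1]):
        present = {p: set() for p in pops}
        for i, lab in enumerate(labels):
            g = values[i, j]
            if np.isnan(g):
                continue
            if g > 0:
                present[lab].add("alt")
            if g < 2:
                present[lab].add("ref")
        for allele in ("ref", "alt"):
            holders = [p for p in pops if allele in present[p]]
            if len(holders) == 1:
                counts[holders[0]] += 1
    return counts


def mc_rarefaction_oracle(values, labels, focal, g, n_resamples, seed):
    """Monte-Carlo subsampling oracle: draw g gene copies per population per
    locus (hypergeometric) and count realized private alleles for ``focal``."""
    rng = np.random.default_rng(seed)
    pops = sorted(set(labels))
    labels = np.asarray(labels)
    total = np.zeros(n_resamples)
    for j in range(values.shape[1]):
        alt_sub = {}
        skip = False
        for p in pops:
            col = values[labels == p, j]
            col = col[~np.isnan(col)]
            n_copies = 2 * len(col)
            if n_copies < g:
                skip = True
                break
            alt = int(col.sum())
            alt_sub[p] = rng.hypergeometric(alt, n_copies - alt, g, size=n_resamples)
        if skip:
            continue
        for allele in ("alt", "ref"):
            if allele == "alt":
                here = alt_sub[focal]
                elsewhere = sum(alt_sub[p] for p in pops if p != focal)
            else:
                here = g - alt_sub[focal]
                elsewhere = sum(g - alt_sub[p] for p in pops if p != focal)
            total += (here > 0) & (elsewhere == 0)
    return total.mean(), total.std(ddof=1) / np.sqrt(n_resamples)


class TestPrivateAlleleCount:
    def test_focal_private_loci_counted(self):
        # alt allele only in pop A at 3 loci; shared elsewhere
        values = np.array([
            [1, 1, 2, 1],   # A
            [1, 2, 1, 1],   # A
            [0, 0, 0, 1],   # B
            [0, 0, 0, 2],   # B
        ], dtype=float)
        pops = pops_for(["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"])
        gm = make_genotypes(values, ["a1", "a2", "b1", "b2"])
        counts = private_allele_count(gm, pops)
        assert counts["A"] == 3
        assert counts["B"] == 0  # locus 4: both alleles shared

    def test_shared_allele_counts_for_neither(self):
        values = np.array([[1.0], [1.0]])
        gm = make_genotypes(values, ["a", "b"])
        counts = private_allele_count(gm, pops_for(["a", "b"], ["A", "B"]))
        assert counts["A"] == 0 and counts["B"] == 0

    def test_matches_brute_force_on_random_five_pop_toy(self, rng):
        n, m = 25, 40
        values = rng.binomial(2, rng.uniform(0.05, 0.95, size=m),
                              size=(n, m)).astype(float)
        values[rng.random((n, m)) < 0.1] = np.nan
        labels = [f"P{i % 5}" for i in range(n)]
        samples = [f"s{i}" for i in range(n)]
        gm = make_genotypes(values, samples)
        counts = private_allele_count(gm, pops_for(samples, labels))
        oracle = brute_force_private(values, labels)
        assert counts.to_dict() == oracle

    def test_population_with_no_calls_is_an_error(self):
        values = np.array([[1.0], [np.nan]])
        gm = make_genotypes(values, ["a", "b"])
        with pytest.raises(ValueError, match="no called genotypes"):
            private_allele_count(gm, pops_for(["a", "b"], ["A", "B"]))


class TestRarefiedPrivateAlleles:
    def test_absence_probability_by_enumeration(self):
        # N=4 copies, 2 carry the allele, g=2: 1 of the 6 pairs misses it
        logq = _log_absent_prob(np.array([4]), np.array([2]), 2)
        assert np.exp(logq[0]) == pytest.approx(1 / 6)

    def test_full_sample_size_equals_observed_count(self, rng):
        n_per = 6
        values = rng.binomial(2, 0.4, size=(3 * n_per, 20)).astype(float)
        samples = [f"s{i}" for i in range(3 * n_per)]
        labels = [f"P{i // n_per}" for i in range(3 * n_per)]
        gm = make_genotypes(values, samples)
        pops = pops_for(samples, labels)
        res = rarefied_private_alleles(gm, pops, g=2 * n_per)
        observed = private_allele_count(gm, pops)
        for p in observed.index:
            assert res.expected[p] == pytest.approx(observed[p], abs=1e-9)

    def test_monotone_in_g_for_truly_private_alleles(self, rng):
        # monotonicity holds when every segregating allele is private to one
        # population: larger subsamples can only reveal such an allele more
        # often. (With alleles shared across populations the expectation can
        # legitimately decrease in g: a shared allele is less likely to *look*
        # private in bigger samples of the other populations.)
        values = np.zeros((12, 10))
        values[0, :5] = 1.0   # P0 carries private alleles at loci 0-4
        values[4, 5:] = 1.0   # P1 carries private alleles at loci 5-9
        samples = [f"s{i}" for i in range(12)]
        labels = [f"P{i // 4}" for i in range(12)]
        gm = make_genotypes(values, samples)
        curve = rarefaction_curve(gm, pops_for(samples, labels), g_max=8)
        for p in ("P0", "P1"):
            assert (np.diff(curve[p]) >= -1e-9).all()

    def test_shared_alleles_can_reduce_apparent_privacy_with_g(self, rng):
        # documents the non-monotone case: a low-frequency allele present in
        # every population contributes less at larger g
        values = np.zeros((12, 1))
        values[[0, 4, 8], 0] = 1.0  # one carrier per population
        samples = [f"s{i}" for i in range(12)]
        labels = [f"P{i // 4}" for i in range(12)]
        gm = make_genotypes(values, samples)
        curve = rarefaction_curve(gm, pops_for(samples, labels), g_max=8)
        # apparent privacy vanishes at full sampling (the allele is shared)
        # after peaking at small g
        assert curve["P0"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert curve["P0"].max() > 0.1
        assert (np.diff(curve["P0"].iloc[2:]) <= 1e-9).all()

    def test_within_monte_carlo_ci_of_subsampling_oracle(self, rng):
        values = rng.binomial(2, rng.uniform(0.05, 0.95, 25),
                              size=(15, 25)).astype(float)
        # plant a private allele for P0
        values[:, 0] = 0.0
        values[0, 0] = 1.0
        samples = [f"s{i}" for i in range(15)]
        labels = [f"P{i // 5}" for i in range(15)]
        gm = make_genotypes(values, samples)
        pops = pops_for(samples, labels)
        res = rarefied_private_alleles(gm, pops, g=6)
        for focal in ("P0", "P1"):
            mc, se = mc_rarefaction_oracle(values, labels, focal, 6,
                                           n_resamples=20_000, seed=7)
            assert res.expected[focal] == pytest.approx(mc, abs=max(2.6 * se, 1e-9))

    def test_g_exceeding_population_names_it(self):
        values = np.array([[1, 1], [1, 0], [0, 1], [2, 0]], dtype=float)
        samples = ["a1", "a2", "b1", "b2"]
        gm = make_genotypes(values, samples)
        pops = pops_for(samples, ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="'A'|'B'"):
            rarefied_private_alleles(gm, pops, g=10)
        with pytest.raises(ValueError):
            rarefied_private_alleles(gm, pops, g=1)

    def test_locus_skipping_is_reported(self):
        values = np.array([
            [1, 1], [1, np.nan],
            [0, 1], [2, np.nan],
        ], dtype=float)
        samples = ["a1", "a2", "b1", "b2"]
        gm = make_genotypes(values, samples)
        res = rarefied_private_alleles(gm, pops_for(samples, ["A", "A", "B", "B"]), g=3)
        assert res.n_loci_used == 1 and res.n_loci_skipped == 1
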