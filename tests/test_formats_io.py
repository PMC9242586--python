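import hashlib
from importlib import resources

import numpy as np
import pandas as pd
import pytest

from rufus.ancestry_blocks import AncestryState, classify_dosages, segment_blocks
from rufus.formats_io import (
    CANID_KARYOTYPE,
    DosageMatrix,
    FormatError,
    SnpMap,
    average_dosage_runs,
    load_cohort,
    load_table1,
    load_table2,
    load_table3,
    read_blocks_bed,
    read_dosage,
    read_genotypes,
    read_metadata,
    write_blocks_bed,
    write_dosage,
    write_genotypes_plink_text,
    write_vcf,
)

from conftest import make_genotypes


class TestSnpMap:
    def test_positions_must_increase_within_chromosome(self):
        with pytest.raises(FormatError, match="strictly increasing"):
            SnpMap(["1", "1"], [200, 100])

    def test_chromosome_runs_must_be_contiguous(self):
        with pytest.raises(FormatError, match="non-contiguous"):
            SnpMap(["1", "2", "1"], [100, 100, 200])

    def test_karyotype_membership_enforced(self):
        with pytest.raises(FormatError, match="karyotype"):
            SnpMap(["chrZ"], [100], karyotype=CANID_KARYOTYPE)

    def test_chrom_indices_follow_map_order(self, toy_map):
        idx = toy_map.chrom_indices(["2", "1"])
        assert idx.tolist() == [0, 1, 2, 3, 4, 5]


class TestDosageIO:
    def test_identity_round_trip(self, toy_map, tmp_path):
        values = np.array([[0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
                           [2.0, 1.0, 0.0, np.nan, 0.5, 1.5]])
        dm = DosageMatrix(["a", "b"], values, toy_map)
        path = tmp_path / "d.tsv"
        write_dosage(dm, path)
        back = read_dosage(path, toy_map)
        assert back.samples == ["a", "b"]
        np.testing.assert_allclose(back.values, values)

    def test_out_of_range_rejected_with_location(self, toy_map, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("a\t0\t1\t2\t0\t1\t2.5\n")
        with pytest.raises(FormatError, match=r"2\.5.*row 1.*column 7"):
            read_dosage(path, toy_map)

    def test_dimension_mismatch_rejected(self, toy_map, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("a\t0\t1\t2\n")
        with pytest.raises(FormatError, match="3 dosages"):
            read_dosage(path, toy_map)

    def test_average_identical_runs_is_identity(self, toy_dosage, tmp_path):
        paths = []
        for i in range(12):
            p = tmp_path / f"run{i}.tsv"
            write_dosage(toy_dosage, p)
            paths.append(p)
        mean = average_dosage_runs(paths, toy_dosage.snp_map)
        np.testing.assert_allclose(mean.values, toy_dosage.values)

    def test_two_run_midpoint(self, toy_map, tmp_path):
        a = DosageMatrix(["s"], np.zeros((1, 6)), toy_map)
        b = DosageMatrix(["s"], np.full((1, 6), 2.0), toy_map)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_dosage(a, pa)
        write_dosage(b, pb)
        mean = average_dosage_runs([pa, pb], toy_map)
        np.testing.assert_allclose(mean.values, 1.0)

    def test_mean_matches_summation_oracle(self, toy_map, rng, tmp_path):
        runs = [rng.uniform(0, 2, size=(3, 6)) for _ in range(5)]
        paths = []
        for i, vals in enumerate(runs):
            p = tmp_path / f"r{i}.tsv"
            write_dosage(DosageMatrix(["a", "b", "c"], vals, toy_map), p)
            paths.append(p)
        mean = average_dosage_runs(paths, toy_map)
        oracle = sum(runs) / len(runs)
        np.testing.assert_allclose(mean.values, oracle, atol=1e-5)

    def test_missing_cell_propagates(self, toy_map, tmp_path):
        vals = np.ones((1, 6))
        a = DosageMatrix(["s"], vals, toy_map)
        with_nan = vals.copy()
        with_nan[0, 2] = np.nan
        b = DosageMatrix(["s"], with_nan, toy_map)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_dosage(a, pa)
        write_dosage(b, pb)
        mean = average_dosage_runs([pa, pb], toy_map)
        assert np.isnan(mean.values[0, 2])
        assert np.isfinite(mean.values[0, [0, 1, 3, 4, 5]]).all()


class TestGenotypeIO:
    def test_vcf_genotype_coding(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\n"
            "1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
        )
        gm = read_genotypes(path, "vcf")
        assert gm.samples == ["s1", "s2", "s3", "s4"]
        np.testing.assert_array_equal(gm.values[:3, 0], [0, 1, 2])
        assert np.isnan(gm.values[3, 0])

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\t.\tA\tT,G\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(FormatError, match="non-biallelic"):
            read_genotypes(path, "vcf")

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text("")
        with pytest.raises(FormatError):
            read_genotypes(path, "vcf")

    def test_cross_format_equality(self, tmp_path):
        gm = make_genotypes([[0, 1, 2, np.nan], [2, 2, 0, 1]])
        vcf_path, txt_path = tmp_path / "g.vcf", tmp_path / "g.tsv"
        write_vcf(gm, vcf_path)
        write_genotypes_plink_text(gm, txt_path)
        from_vcf = read_genotypes(vcf_path, "vcf")
        from_txt = read_genotypes(txt_path, "plink_text")
        assert from_vcf.samples == from_txt.samples == gm.samples
        np.testing.assert_array_equal(from_vcf.values, from_txt.values)
        np.testing.assert_array_equal(from_vcf.snp_map.pos_bp, from_txt.snp_map.pos_bp)


class TestMetadata:
    def test_reads_and_validates(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample,region,sex,age_class,weight_kg\n"
                     "a,Cameron-NW,F,adult,14.2\nb,Cameron-NE,M,pup,\n")
        df = read_metadata(p)
        assert len(df) == 2 and df["weight_kg"].isna().sum() == 1

    def test_rejects_bad_age_and_weight(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample,region,sex,age_class,weight_kg\na,R,F,elder,10\n")
        with pytest.raises(FormatError, match="age class"):
            read_metadata(p)
        p.write_text("sample,region,sex,age_class,weight_kg\na,R,F,adult,-3\n")
        with pytest.raises(FormatError, match="weight"):
            read_metadata(p)


class TestBlocksBed:
    def _tracks(self, states, snp_map, samples=("s1",)):
        return segment_blocks(np.asarray(states), snp_map, list(samples))

    def test_bed_is_zero_based_half_open(self, tmp_path):
        snp_map = SnpMap(["1", "1"], [100, 500])
        tracks = self._tracks([[2, 2]], snp_map)
        path = tmp_path / "b.bed"
        write_blocks_bed(tracks, path)
        chrom, start, end, sample, state, n = path.read_text().split()
        assert (chrom, start, end, sample, state, n) == ("1", "99", "500", "s1", "RW_HOM", "2")

    def test_round_trip(self, toy_map, toy_dosage, tmp_path):
        tracks = segment_blocks(classify_dosages(toy_dosage), toy_map, toy_dosage.samples)
        path = tmp_path / "b.bed"
        write_blocks_bed(tracks, path)
        assert read_blocks_bed(path) == tracks

    def test_output_sorted_by_chrom_then_start(self, tmp_path):
        snp_map = SnpMap(["2", "2", "1", "1"], [100, 900, 50, 700])
        tracks = self._tracks([[0, 2, 1, 0]], snp_map)
        path = tmp_path / "b.bed"
        write_blocks_bed(tracks, path)
        recs = [line.split("\t")[:2] for line in path.read_text().splitlines()]
        assert recs == sorted(recs, key=lambda r: (r[0], int(r[1])))


FIXTURE_SHA256 = {
    "table1_ancestry_timing.tsv":
        "652e415341bba2791795cd5df4d6ab33cece00f2df06a9a51e1ec6339d57dba9",
    "table2_block_sizes.tsv":
        "ef3a59ec6950bd8519400523c1deeead2b6fe695dd20e2cd4cc457bb152f006d",
    "table3_texas_canids.tsv":
        "e6da5f85fa0e49b3effed2cbca7734574f275343f4a35da8b5f2aee4a932bab2",
}


class TestFixtures:
    @pytest.mark.parametrize("name,digest", sorted(FIXTURE_SHA256.items()))
    def test_fixture_checksums_pinned(self, name, digest):
        data = resources.files("rufus.data").joinpath(name).read_bytes()
        assert hashlib.sha256(data).hexdigest() == digest

    def test_table_shapes_and_spot_values(self):
        t1, t2, t3 = load_table1(), load_table2(), load_table3()
        assert len(t1) == 31 and len(t2) == 31 and len(t3) == 10
        row = t1.set_index("sample").loc["CL12927"]
        assert row["auto_ancestry"] == 0.573 and row["x_ancestry"] == 1.000
        assert t2.set_index("sample").loc["CL12923", "redwolf_mb"] == 122.6
        assert t3.set_index("sample").loc["70-TX-04", "rw_ancestry"] == 0.52

    def test_single_documented_correction(self):
        t1 = load_table1()
        corrected = t1[t1["corrected"] == 1]
        assert list(corrected["sample"]) == ["CL12980"]
        assert corrected["auto_timing_years"].iloc[0] == 20.9

    def test_cohort_join_regions(self):
        cohort = load_cohort()
        assert len(cohort) == 31
        counts = cohort["region"].value_counts()
        assert counts["Cameron-NW"] == 8
        assert counts["Cameron-NE"] == 4
        assert counts["Cameron-SW"] == 10
        assert counts["Jefferson Davis"] == 5
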