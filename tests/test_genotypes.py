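import numpy as np
import pandas as pd
import pytest

from domscan import (
    MISSING,
    allele_partition,
    at_composition,
    filter_sites,
    ibs_matrix,
    load_vcf,
    site_summaries,
    snp_density,
)
from domscan.genotypes import read_subpop_map

from conftest import make_gm

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2\n"
)


def write_vcf_text(tmp_path, records):
    p = tmp_path / "t.vcf"
    p.write_text(VCF_HEADER + "".join(records))
    return p


class TestLoadVcf:
    def test_dosage_encoding(self, tmp_path):
        p = write_vcf_text(
            tmp_path, ["chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"]
        )
        gm = load_vcf(p)
        assert gm.calls.tolist() == [[0], [1], [2]]

    def test_indel_and_multiallelic_dropped(self, tmp_path):
        p = write_vcf_text(
            tmp_path,
            [
                "chr1\t100\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
                "chr1\t200\t.\tA\tC,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
                "chr1\t300\t.\tG\tT\t.\tPASS\t.\tGT\t0/0\t./.\t1/1\n",
            ],
        )
        gm = load_vcf(p)
        assert gm.n_sites == 1
        assert gm.sites["pos"].tolist() == [300]
        assert gm.calls.tolist() == [[0], [MISSING], [2]]

    def test_subpop_map_unknown_sample_raises(self, tmp_path):
        p = write_vcf_text(
            tmp_path, ["chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"]
        )
        m = tmp_path / "pops.tsv"
        m.write_text("sample\tsubpop\nghost\tpopA\n")
        with pytest.raises(ValueError, match="ghost"):
            load_vcf(p, m)

    def test_unmapped_samples_get_unassigned(self, tmp_path):
        p = write_vcf_text(
            tmp_path, ["chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"]
        )
        m = tmp_path / "pops.tsv"
        m.write_text("sample\tsubpop\ns0\thyb\n")
        gm = load_vcf(p, m)
        assert gm.samples["subpop"].tolist() == ["hyb", "unassigned", "unassigned"]

    def test_no_snps_raises(self, tmp_path):
        p = write_vcf_text(
            tmp_path, ["chr1\t100\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"]
        )
        with pytest.raises(ValueError, match="no biallelic"):
            load_vcf(p)

    def test_duplicate_map_sample_raises(self, tmp_path):
        m = tmp_path / "pops.tsv"
        m.write_text("s0\thyb\ns0\tland\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_subpop_map(m)


class TestFilterSites:
    def test_missingness_and_maf_rules(self):
        # site 0: 2/10 missing (0.2 > 0.1) -> removed
        # site 1: single het of 10 samples, maf 0.05 -> retained at min_maf 0.05
        # site 2: monomorphic -> removed at any positive min_maf
        calls = np.zeros((10, 3), dtype=np.int8)
        calls[:2, 0] = MISSING
        calls[0, 1] = 1
        gm = make_gm(calls)
        out = filter_sites(gm, max_missing=0.10, min_maf=0.05)
        assert out.sites["pos"].tolist() == [200]

    def test_idempotent(self, neutral_cohort):
        _, gm = neutral_cohort
        once = filter_sites(gm)
        twice = filter_sites(once)
        assert np.array_equal(once.calls, twice.calls)
        assert once.sites.equals(twice.sites)

    def test_all_removed_raises_with_thresholds(self):
        gm = make_gm(np.zeros((4, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="min_maf=0.05"):
            filter_sites(gm)


class TestSiteSummaries:
    @pytest.mark.parametrize(
        "calls, miss, het, maf",
        [
            ([0, 0, 1, 2], 0.0, 0.25, 0.375),
            ([1, 1, 1, 1], 0.0, 1.0, 0.5),
            ([0, 0, MISSING, MISSING], 0.5, 0.0, 0.0),
        ],
    )
    def test_examples(self, calls, miss, het, maf):
        s = site_summaries(make_gm(calls)).iloc[0]
        assert s["missingness"] == pytest.approx(miss)
        assert s["heterozygosity"] == pytest.approx(het)
        assert s["maf"] == pytest.approx(maf)

    def test_all_missing_site_flagged_undefined(self):
        s = site_summaries(make_gm([MISSING, MISSING, MISSING])).iloc[0]
        assert s["missingness"] == 1.0
        assert np.isnan(s["maf"]) and np.isnan(s["heterozygosity"])


class TestIBS:
    def brute_force(self, a, b):
        scores = []
        for x, y in zip(a, b):
            if x == MISSING or y == MISSING:
                continue
            scores.append((2 - abs(x - y)) / 2.0)
        return np.mean(scores) if scores else np.nan

    def test_anchor_scores(self):
        ib = ibs_matrix(make_gm([[0], [0]]))
        assert ib.values[0, 1] == 1.0
        ib = ibs_matrix(make_gm([[0], [2]]))
        assert ib.values[0, 1] == 0.0
        ib = ibs_matrix(make_gm([[0], [1]]))
        assert ib.values[0, 1] == 0.5

    def test_identical_samples_score_one(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 50)
        ib = ibs_matrix(make_gm([g, g]))
        assert ib.values[0, 1] == 1.0

    def test_matches_per_locus_brute_force(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([0, 1, 2, MISSING], size=(6, 100), p=[0.4, 0.2, 0.3, 0.1])
        ib = ibs_matrix(make_gm(calls))
        for i in range(6):
            for j in range(6):
                expect = self.brute_force(calls[i], calls[j])
                assert ib.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_symmetric_unit_diagonal_and_permutation(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([0, 1, 2, MISSING], size=(8, 60))
        ib = ibs_matrix(make_gm(calls))
        assert np.allclose(ib.values, ib.values.T, equal_nan=True)
        assert np.allclose(np.diag(ib.values), 1.0)
        perm = rng.permutation(8)
        ib_p = ibs_matrix(make_gm(calls[perm]))
        assert np.allclose(ib_p.values, ib.values[np.ix_(perm, perm)], equal_nan=True)

    def test_pair_without_shared_loci_is_nan(self):
        calls = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        ib = ibs_matrix(make_gm(calls))
        assert np.isnan(ib.values[0, 1])


class TestAllelePartition:
    def test_set_arithmetic_and_inclusion_exclusion(self):
        # popA polymorphic at sites 0,1,2; popB at 1,2,3,4
        calls = np.zeros((8, 5), dtype=np.int8)
        calls[0:2, 0] = 1  # A-only polymorphism
        calls[[0, 4], 1] = 1
        calls[[1, 5], 2] = 1
        calls[4:6, 3] = 1  # B-only
        calls[4:6, 4] = 1  # B-only
        gm = make_gm(calls, subpops=["A"] * 4 + ["B"] * 4)
        part = allele_partition(gm, per_subpop_min_maf=0.05)
        row = part.pairwise.iloc[0]
        assert row["union"] == 5
        assert row["intersection"] == 2
        assert row["b_minus_a"] == 2
        assert row["union"] == len(part.sets["A"]) + len(part.sets["B"]) - row["intersection"]
        assert part.shared_all == 2

    def test_fixed_site_excluded(self):
        calls = np.full((4, 1), 2, dtype=np.int8)
        part = allele_partition(make_gm(calls, subpops=["A"] * 4))
        assert len(part.sets["A"]) == 0

    def test_identical_subpops_have_empty_differences(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 3, size=(4, 20), dtype=np.int8)
        gm = make_gm(np.vstack([block, block]), subpops=["A"] * 4 + ["B"] * 4)
        part = allele_partition(gm)
        assert part.pairwise.iloc[0]["a_minus_b"] == 0
        assert part.pairwise.iloc[0]["b_minus_a"] == 0

    def test_unique_per_accession_scaling(self):
        calls = np.zeros((6, 2), dtype=np.int8)
        calls[0:2, 0] = 1  # private to A (4 accessions)
        gm = make_gm(calls, subpops=["A"] * 4 + ["B"] * 2)
        part = allele_partition(gm)
        assert part.unique_per_accession["A"] == pytest.approx(1 / 4)


class TestATComposition:
    def test_ct_site_with_half_frequency(self):
        gm = make_gm([0, 1, 1, 2], ref="C", alt="T")
        assert at_composition(gm, by_subpop=False)["all"] == pytest.approx(0.5)

    def test_pure_at_and_pure_cg_sites(self):
        gm = make_gm([[0, 1], [1, 0], [2, 1]], ref=["A", "A"], alt=["T", "T"])
        assert at_composition(gm, by_subpop=False)["all"] == 1.0
        gm = make_gm([[0, 1], [1, 0], [2, 1]], ref=["C", "G"], alt=["G", "C"])
        assert at_composition(gm, by_subpop=False)["all"] == 0.0

    def test_unweighted_mode_ignores_frequency(self):
        gm = make_gm([0, 0, 0, 1], ref="C", alt="T")  # T at freq 1/8
        assert at_composition(gm, by_subpop=False, weighted=False)["all"] == 0.5
        assert at_composition(gm, by_subpop=False)["all"] == pytest.approx(1 / 8)


class TestSnpDensity:
    def test_single_bin(self):
        gm = make_gm(np.ones((2, 10), dtype=np.int8), positions=np.arange(1, 11))
        t = snp_density(gm)
        assert len(t.df) == 1
        assert t.df.iloc[0]["value"] == 10

    def test_half_open_bin_edges(self):
        gm = make_gm(np.ones((2, 2), dtype=np.int8), positions=[999_999, 1_000_001])
        t = snp_density(gm)
        assert t.df["value"].tolist() == [1.0, 1.0]
        assert t.df["start"].tolist() == [0, 1_000_000]

    def test_multi_chromosome(self):
        gm = make_gm(
            np.ones((2, 4), dtype=np.int8),
            positions=[5, 10, 5, 10],
            chrom=["chr1", "chr1", "chr2", "chr2"],
        )
        t = snp_density(gm)
        assert set(t.df["chrom"]) == {"chr1", "chr2"}
        assert t.df["value"].tolist() == [2.0, 2.0]
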