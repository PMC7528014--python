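import numpy as np
import pandas as pd
import pytest

from domscan import (
    Region,
    WindowTrack,
    collocate,
    intersect_annotation,
    merge_regions,
    top_percentile_regions,
)
from domscan.regions import read_annotation, regions_from_bed, regions_to_bed


def make_track(values, window_bp=10_000, chrom="chr1"):
    n = len(values)
    return WindowTrack(
        df=pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(n) * window_bp,
                "end": (np.arange(n) + 1) * window_bp,
                "n_sites": 1,
                "value": values,
            }
        ),
        statistic="test",
    )


class TestTopPercentile:
    def test_counts_upper_tail(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(1000).astype(float)
        regions = top_percentile_regions(make_track(vals), 99.0, "upper", "FST")
        n_windows = sum((r.end - r.start) // 10_000 for r in regions)
        assert n_windows == 10

    def test_lower_tail_selects_near_zero_window(self):
        vals = np.ones(200)
        vals[37] = 0.001
        regions = top_percentile_regions(make_track(vals), 99.0, "lower", "ROD")
        assert len(regions) == 1
        assert regions[0].start == 37 * 10_000

    def test_flat_track_selects_nothing(self):
        assert top_percentile_regions(make_track(np.ones(500)), 99.0, "upper") == []

    def test_nan_windows_excluded(self):
        vals = np.ones(300)
        vals[10:20] = np.nan
        vals[50] = 5.0
        regions = top_percentile_regions(make_track(vals), 99.0, "upper", "FST")
        assert len(regions) == 1 and regions[0].start == 50 * 10_000


class TestMergeRegions:
    def test_gap_below_threshold_merges(self):
        rs = [
            Region("chr1", 2_000_000, 2_500_000, "FST", 1.0),
            Region("chr1", 2_900_000, 3_100_000, "FST", 2.0),
        ]
        out = merge_regions(rs)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (2_000_000, 3_100_000)
        assert out[0].score == 2.0

    def test_gap_at_or_above_threshold_does_not_merge(self):
        rs = [
            Region("chr1", 0, 500_000, "FST"),
            Region("chr1", 1_700_000, 2_000_000, "FST"),  # gap 1.2 Mbp
        ]
        assert len(merge_regions(rs)) == 2
        rs = [
            Region("chr1", 0, 500_000, "FST"),
            Region("chr1", 1_500_000, 2_000_000, "FST"),  # gap exactly 1 Mbp
        ]
        assert len(merge_regions(rs)) == 2

    def test_single_region_unchanged(self):
        r = Region("chr1", 10, 20, "ROD", 0.5)
        assert merge_regions([r]) == [r]

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(4)
        rs = [
            Region("chr1", int(s), int(s) + 200_000, "SWEEP", float(i))
            for i, s in enumerate(rng.integers(0, 20_000_000, 30))
        ]
        once = merge_regions(rs)
        assert merge_regions(once) == once
        shuffled = [rs[i] for i in rng.permutation(30)]
        assert merge_regions(shuffled) == once

    def test_labels_never_merge_across_types(self):
        rs = [
            Region("chr1", 0, 500_000, "FST"),
            Region("chr1", 600_000, 900_000, "ROD"),
        ]
        out = merge_regions(rs)
        assert len(out) == 2


class TestAnnotation:
    def test_gene_inside_and_abutting(self):
        regions = [Region("chr1", 1000, 2000, "FST")]
        anno = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [1200, 2000],  # second gene abuts the half-open end
                "end": [1300, 2100],
                "gene": ["inside", "abutting"],
            }
        )
        hits = intersect_annotation(regions, anno)
        assert hits["gene"].tolist() == ["inside"]

    def test_chromosome_name_mismatch_raises(self):
        regions = [Region("chr1", 0, 100, "FST")]
        anno = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [50], "gene": ["g"]})
        with pytest.raises(ValueError, match="chromosome"):
            intersect_annotation(regions, anno)

    def test_even_gene_spacing_proportional_overlap(self):
        # 100 genes of 5 kbp every 100 kbp over 10 Mbp; a region covering 10%
        # of the span overlaps 10 +/- 1 of them
        anno = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(100) * 100_000,
                "end": np.arange(100) * 100_000 + 5_000,
                "gene": [f"g{i}" for i in range(100)],
            }
        )
        hits = intersect_annotation([Region("chr1", 3_000_000, 4_000_000, "FST")], anno)
        assert abs(len(hits) - 10) <= 1

    def test_gff3_reader_gene_features(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=geneA\n"
            "chr1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=geneA.1;Parent=geneA\n"
        )
        df = read_annotation(gff)
        assert df["gene"].tolist() == ["geneA"]
        assert df.iloc[0]["start"] == 1000 and df.iloc[0]["end"] == 2000


class TestCollocation:
    def test_exact_overlap_collocates(self):
        report = collocate(
            {
                "FST": [Region("chr1", 100, 200, "FST")],
                "SWEEP": [Region("chr1", 100, 200, "SWEEP")],
            },
            min_labels=2,
        )
        assert len(report) == 1
        assert report.iloc[0]["labels"] == "FST,SWEEP"

    def test_disjoint_labels_no_collocation(self):
        report = collocate(
            {
                "FST": [Region("chr1", 100, 200, "FST")],
                "SWEEP": [Region("chr1", 5_000_000, 5_000_100, "SWEEP")],
            },
            min_labels=2,
            max_gap_bp=1,
        )
        assert len(report) == 0

    def test_snp_list_as_point_features(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [150]})
        report = collocate(
            {
                "FST": [Region("chr1", 100, 200, "FST")],
                "SWEEP": [Region("chr1", 120, 180, "SWEEP")],
            },
            snp_lists=snps,
            min_labels=3,
            max_gap_bp=1,
        )
        assert len(report) == 1
        assert "SNPLIST" in report.iloc[0]["labels"]


class TestBedRoundTrip:
    def test_zero_based_half_open_round_trip(self, tmp_path):
        rs = [
            Region("chr1", 0, 1000, "FST", 1.5),
            Region("chr2", 500, 2500, "ROD", 0.1),
        ]
        p = tmp_path / "r.bed"
        regions_to_bed(rs, p)
        back = regions_from_bed(p)
        assert [(r.chrom, r.start, r.end, r.label) for r in back] == [
            (r.chrom, r.start, r.end, r.label) for r in rs
        ]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            Region("chr1", 0, 10, "WEIRD")

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Region("chr1", 10, 10, "FST")
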