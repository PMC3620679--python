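"""Interval algebra, map/gene readers, spot classification and coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import per_base_intersection, per_base_occupancy_merge
from recspot import genome_intervals as gi


def make_windows(srrs, width=10_000, chrom="chr1"):
    return [
        gi.RecombinationWindow(gi.GenomicInterval(chrom, i * width, (i + 1) * width), s)
        for i, s in enumerate(srrs)
    ]


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            gi.GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            gi.GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            gi.GenomicInterval("", 0, 10)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 100, 200), ("chr1", 150, 250), 50),
            (("chr1", 100, 200), ("chr1", 200, 300), 0),  # half-open abutment
            (("chr1", 100, 200), ("chr2", 100, 200), 0),
            (("chr1", 0, 10), ("chr1", 2, 5), 3),
        ],
    )
    def test_overlap_len(self, a, b, expected):
        ia, ib = gi.GenomicInterval(*a), gi.GenomicInterval(*b)
        assert ia.overlap_len(ib) == expected
        assert ib.overlap_len(ia) == expected  # pairwise symmetry


class TestReadRecombMap:
    def test_single_row(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("chr1\t0\t10000\t12.5\n")
        (w,) = gi.read_recomb_map(p)
        assert w.interval == gi.GenomicInterval("chr1", 0, 10000)
        assert w.srr == 12.5

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("#chrom\tstart\tend\tsrr\n")
        assert gi.read_recomb_map(p) == []

    def test_missing_column_names_line(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("chr1\t0\t10000\t1.0\nchr1\t10000\t20000\n")
        with pytest.raises(gi.MapParseError, match="line 2"):
            gi.read_recomb_map(p)

    def test_negative_srr_rejected(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("chr1\t0\t10000\t-1\n")
        with pytest.raises(gi.MapParseError, match="negative SRR"):
            gi.read_recomb_map(p)

    def test_thousand_row_round_trip(self, tmp_path, rng):
        windows = []
        for c in ("chr1", "chr2"):
            windows += make_windows(rng.lognormal(0, 2, size=500), chrom=c)
        p = tmp_path / "map.tsv"
        gi.write_recomb_map(windows, p)
        back = gi.read_recomb_map(p)
        assert back == sorted(windows, key=lambda w: (w.interval.chrom, w.interval.start))


class TestClassifySpots:
    def test_thresholds_are_strict(self):
        # srr exactly 10 is not hot; exactly 0.1 or 1 is not middle
        sets = gi.classify_spots(make_windows([10.0, 10.0001, 0.1, 1.0, 0.5, 0.0]))
        assert len(sets["hot"]) == 1
        assert len(sets["middle"]) == 1
        assert len(sets["cold"]) == 1

    def test_partition_is_disjoint(self, rng):
        windows = make_windows(rng.lognormal(0, 2, size=500))
        sets = gi.classify_spots(windows)
        hot, mid, cold = (set(sets[k].spots) for k in ("hot", "middle", "cold"))
        assert not (hot & mid) and not (hot & cold) and not (mid & cold)

    def test_matches_brute_force_filter(self, rng):
        srrs = np.round(rng.lognormal(0, 2, size=1000), 3)
        srrs[rng.random(1000) < 0.3] = 0.0
        windows = make_windows(srrs)
        sets = gi.classify_spots(windows)
        assert len(sets["hot"]) == sum(1 for s in srrs if s > 10)
        assert len(sets["middle"]) == sum(1 for s in srrs if 0.1 < s < 1)
        assert len(sets["cold"]) == sum(1 for s in srrs if s == 0)

    def test_empty_input(self):
        sets = gi.classify_spots([])
        assert all(len(sets[k]) == 0 for k in sets)

    def test_bad_threshold_order(self):
        with pytest.raises(ValueError):
            gi.classify_spots([], hot_min=1, mid_lo=2, mid_hi=3)


class TestSampleSpots:
    def setup_method(self):
        self.spotset = gi.SpotSet(
            "hot", [gi.GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(10)]
        )

    def test_full_sample_is_identity(self):
        for seed in (0, 1, 99):
            assert gi.sample_spots(self.spotset, 10, seed).spots == self.spotset.spots

    def test_deterministic_per_seed(self):
        a = gi.sample_spots(self.spotset, 4, seed=7)
        b = gi.sample_spots(self.spotset, 4, seed=7)
        assert a.spots == b.spots

    def test_oversample_reports_counts(self):
        with pytest.raises(ValueError, match="11.*10|10.*11"):
            gi.sample_spots(self.spotset, 11, seed=0)

    def test_uniformity(self):
        counts = {s: 0 for s in self.spotset.spots}
        for seed in range(10_000):
            (chosen,) = gi.sample_spots(self.spotset, 1, seed=seed).spots
            counts[chosen] += 1
        freqs = np.array(list(counts.values())) / 10_000
        assert np.all(np.abs(freqs - 0.1) <= 0.01)


def tx(i, chrom, start, end, symbol=None):
    return gi.TranscriptModel(f"T{i}", symbol or f"G{i}", gi.GenomicInterval(chrom, start, end))


class TestMergeTranscripts:
    def test_overlap_merges_abutment_does_not(self):
        regions = gi.merge_transcripts(
            [tx(1, "chr1", 0, 10), tx(2, "chr1", 5, 15), tx(3, "chr1", 20, 30)]
        )
        assert [(r.interval.start, r.interval.end) for r in regions] == [(0, 15), (20, 30)]
        assert regions[0].member_transcripts == ("T1", "T2")

        two = gi.merge_transcripts([tx(1, "chr1", 0, 10), tx(2, "chr1", 10, 20)])
        assert len(two) == 2

    def test_idempotent(self, rng):
        txs = [
            tx(i, f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 500)))
            for i, s in enumerate(rng.integers(0, 10_000, size=100))
        ]
        regions = gi.merge_transcripts(txs)
        as_tx = [
            gi.TranscriptModel(f"R{i}", f"R{i}", r.interval) for i, r in enumerate(regions)
        ]
        again = gi.merge_transcripts(as_tx)
        assert [r.interval for r in again] == [r.interval for r in regions]

    def test_matches_per_base_occupancy(self, rng):
        txs = []
        for i in range(200):
            chrom = f"chr{int(rng.integers(1, 4))}"
            start = int(rng.integers(0, 90_000))
            txs.append(tx(i, chrom, start, start + int(rng.integers(1, 2_000))))
        regions = gi.merge_transcripts(txs)
        expected = per_base_occupancy_merge(
            [(t.interval.chrom, t.interval.start, t.interval.end) for t in txs]
        )
        got = [(r.interval.chrom, r.interval.start, r.interval.end) for r in regions]
        assert sorted(got) == sorted(expected)


class TestIntersect:
    def spots(self, ivs):
        return gi.SpotSet("hot", [gi.GenomicInterval(*v) for v in ivs])

    def test_basic_overlap(self):
        recs = gi.intersect([tx(1, "chr1", 100, 200)], self.spots([("chr1", 150, 250)]))
        assert recs == [gi.IntersectionRecord("T1", 1, 50, False)]

    def test_half_open_abutment_is_no_overlap(self):
        assert gi.intersect([tx(1, "chr1", 100, 200)], self.spots([("chr1", 200, 300)])) == []

    def test_min_overlap_threshold(self):
        region = [tx(1, "chr1", 100, 200)]
        spots = self.spots([("chr1", 195, 300)])
        assert gi.intersect(region, spots, min_overlap=5) != []
        assert gi.intersect(region, spots, min_overlap=6) == []

    def test_contains_full_spot(self):
        recs = gi.intersect([tx(1, "chr1", 0, 1000)], self.spots([("chr1", 100, 200)]))
        assert recs[0].contains_full_spot and recs[0].covered_bases == 100

    def test_covered_bases_union_not_sum(self):
        # two spots overlapping each other within the region
        recs = gi.intersect(
            [tx(1, "chr1", 0, 100)], self.spots([("chr1", 10, 50), ("chr1", 40, 80)])
        )
        assert recs[0].covered_bases == 70 and recs[0].n_spots_overlapped == 2

    def test_matches_per_base_brute_force(self, rng):
        regions, spot_ivs = [], []
        for i in range(50):
            c = f"chr{int(rng.integers(1, 3))}"
            s = int(rng.integers(0, 95_000))
            regions.append(tx(i, c, s, s + int(rng.integers(1, 5_000))))
            c2 = f"chr{int(rng.integers(1, 3))}"
            s2 = int(rng.integers(0, 95_000))
            spot_ivs.append((c2, s2, s2 + int(rng.integers(1, 5_000))))
        spots = self.spots(spot_ivs)
        recs = {r.region_or_transcript_id: r for r in gi.intersect(regions, spots)}
        for t in regions:
            n, cov, full = per_base_intersection(
                (t.interval.chrom, t.interval.start, t.interval.end), spot_ivs
            )
            if n == 0:
                assert t.transcript_id not in recs
            else:
                r = recs[t.transcript_id]
                assert (r.n_spots_overlapped, r.covered_bases, r.contains_full_spot) == (
                    n, cov, full,
                )

    def test_spot_order_invariance(self, rng):
        regions = [tx(0, "chr1", 0, 50_000)]
        ivs = [("chr1", int(s), int(s) + 500) for s in rng.integers(0, 60_000, size=30)]
        a = gi.intersect(regions, self.spots(ivs))
        b = gi.intersect(regions, self.spots(list(reversed(ivs))))
        assert a == b

    @given(st.integers(0, 500), st.integers(1, 500), st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_covered_never_exceeds_region_length(self, rs, rl, ss, sl):
        region = [tx(1, "chr1", rs, rs + rl)]
        recs = gi.intersect(region, self.spots([("chr1", ss, ss + sl)]))
        for r in recs:
            assert 1 <= r.covered_bases <= rl


class TestCoverageSummary:
    def test_all_full_containment(self):
        regions = [tx(i, "chr1", i * 1000, i * 1000 + 500) for i in range(4)]
        recs = [gi.IntersectionRecord(f"T{i}", 1, 100, True) for i in range(4)]
        s = gi.coverage_summary(recs, regions)
        assert s.fraction_full_spot == 1.0

    def test_single_record_median(self):
        s = gi.coverage_summary(
            [gi.IntersectionRecord("T1", 1, 10_000, False)], [tx(1, "chr1", 0, 20_000)]
        )
        assert s.median_covered == 10_000
        assert s.fraction_covered_ge_threshold == 1.0

    def test_planted_containment_fraction(self):
        # 7 of 10 regions fully contain a spot: fraction recovered exactly
        recs = [gi.IntersectionRecord(f"T{i}", 1, 50, i < 7) for i in range(10)]
        regions = [tx(i, "chr1", i * 1000, i * 1000 + 500) for i in range(10)]
        assert gi.coverage_summary(recs, regions).fraction_full_spot == 0.7

    def test_empty_records_give_nulls(self):
        s = gi.coverage_summary([], [tx(1, "chr1", 0, 10)])
        assert s.median_covered is None and s.n_intersected == 0


class TestReadTranscripts:
    def test_combined_six_column_form(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t200\tT1\t0\tGENE1\nchr1\t150\t300\tT2\t0\tGENE1\n")
        txs = gi.read_transcripts(p)
        assert [t.gene_symbol for t in txs] == ["GENE1", "GENE1"]

    def test_bed_plus_symbol_map(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tT1\t0\t+\n")
        m = tmp_path / "map.tsv"
        m.write_text("T1\tGENE1\n")
        (t,) = gi.read_transcripts(bed, m)
        assert t.gene_symbol == "GENE1"

    def test_duplicate_transcript_id_rejected(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t1\t2\tT1\t0\tG1\nchr1\t5\t9\tT1\t0\tG2\n")
        with pytest.raises(gi.MapParseError, match="duplicate"):
            gi.read_transcripts(p)
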