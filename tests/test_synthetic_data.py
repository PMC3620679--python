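"""Determinism, planted-effect structure, and round-trips of the generators."""

import json
import math

import numpy as np
import pytest

from recspot import enrichment_stats as es
from recspot import evolution_compare as ec
from recspot import genome_intervals as gi
from recspot import sequence_features as sf
from recspot import synthetic_data as sd


def tiny_config(**kw):
    defaults = dict(
        n_chromosomes=2, chromosome_length=2_000_000, n_genes=100,
        set_sizes={"S1": 20, "S2": 30}, seed=3,
    )
    defaults.update(kw)
    return sd.GeneratorConfig(**defaults)


class TestGenRecombMap:
    def test_deterministic_file_bytes(self, tmp_path):
        cfg = tiny_config()
        for name in ("a.tsv", "b.tsv"):
            windows, _ = sd.gen_recomb_map(cfg, 0.05)
            gi.write_recomb_map(windows, tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_zero_hotspot_fraction(self):
        windows, _ = sd.gen_recomb_map(tiny_config(), 0.0)
        assert len(gi.classify_spots(windows)["hot"]) == 0

    def test_hot_count_binomial(self):
        cfg = sd.GeneratorConfig(
            n_chromosomes=1, chromosome_length=100_000_000, n_genes=10, seed=5,
            set_sizes={},
        )
        windows, truth = sd.gen_recomb_map(cfg, 0.05)
        assert len(windows) == 10_000
        n_hot = len(gi.classify_spots(windows)["hot"])
        assert abs(n_hot - 500) <= 50
        assert truth.extras["n_hot_windows"] == n_hot

    def test_tiles_without_gaps(self):
        windows, _ = sd.gen_recomb_map(tiny_config(), 0.1)
        by_chrom = {}
        for w in windows:
            by_chrom.setdefault(w.interval.chrom, []).append(w.interval)
        for ivs in by_chrom.values():
            for a, b in zip(ivs, ivs[1:]):
                assert a.end == b.start

    def test_round_trips_through_reader(self, tmp_path):
        windows, _ = sd.gen_recomb_map(tiny_config(), 0.05)
        p = tmp_path / "map.tsv"
        gi.write_recomb_map(windows, p)
        assert gi.read_recomb_map(p) == windows


class TestGenGeneAnnotation:
    def test_zero_bias_means_zero_hot_overlap(self):
        cfg = tiny_config(n_genes=60)
        windows, _ = sd.gen_recomb_map(cfg, 0.10)
        txs = sd.gen_gene_annotation(cfg, windows, hotspot_bias=0.0)
        hot = gi.classify_spots(windows)["hot"]
        assert gi.intersect(txs, hot) == []

    def test_unbiased_hot_overlap_matches_geometry(self):
        cfg = sd.GeneratorConfig(
            n_chromosomes=2, chromosome_length=20_000_000, n_genes=1000,
            set_sizes={}, seed=9,
        )
        windows, _ = sd.gen_recomb_map(cfg, 0.05)
        txs = sd.gen_gene_annotation(cfg, windows, hotspot_bias=1.0)
        hot = gi.classify_spots(windows)["hot"]
        hit_tx = {r.region_or_transcript_id for r in gi.intersect(txs, hot)}
        genes = {}
        for t in txs:
            genes.setdefault(t.gene_symbol, []).append(t.transcript_id)
        frac = sum(any(t in hit_tx for t in v) for v in genes.values()) / len(genes)
        # a gene of length L intersects a hot window iff its span touches one:
        # expected fraction ~ n_hot * (L_mean + window) / genome
        n_hot = len(hot)
        mean_len = np.mean([t.interval.end - t.interval.start
                            for t in txs if t.transcript_id.endswith(".1")])
        expect = n_hot * (mean_len + cfg.window_size) / (2 * 20_000_000)
        se = math.sqrt(expect * (1 - expect) / len(genes))
        assert abs(frac - expect) <= max(3 * se, 0.02)

    def test_transcripts_of_one_gene_merge_to_one_region(self):
        cfg = tiny_config()
        windows, _ = sd.gen_recomb_map(cfg, 0.05)
        txs = sd.gen_gene_annotation(cfg, windows)
        regions = gi.merge_transcripts(txs)
        genes = {t.gene_symbol for t in txs}
        assert len(regions) == len(genes)  # genes never overlap each other

    def test_deterministic(self):
        cfg = tiny_config()
        windows, _ = sd.gen_recomb_map(cfg, 0.05)
        assert sd.gen_gene_annotation(cfg, windows) == sd.gen_gene_annotation(cfg, windows)


class TestGenGeneSets:
    def make_annotation(self, n=2000):
        return [
            gi.TranscriptModel(f"G{i:05d}.1", f"G{i:05d}",
                               gi.GenomicInterval("chr1", 100 * i, 100 * i + 50))
            for i in range(n)
        ]

    def test_neutral_fe_within_binomial_band(self):
        ann = self.make_annotation()
        hi = es.GeneSet("HI", [f"G{i:05d}" for i in range(200)])
        inside = 0
        for seed in range(100):
            sets, truth = sd.gen_gene_sets(ann, hi, {"S": 1.0}, {"S": 300}, seed)
            overlap = truth.extras["realized_overlap"]["S"]
            m = len(sets[0])
            p_hi = m / 2000  # under independence
            mean, sdv = 200 * p_hi, math.sqrt(200 * p_hi * (1 - p_hi))
            if abs(overlap - mean) <= 1.96 * sdv:
                inside += 1
        assert inside >= 90

    def test_saturation_at_large_fe(self):
        ann = self.make_annotation(500)
        hi = es.GeneSet("HI", [f"G{i:05d}" for i in range(250)])
        sets, _ = sd.gen_gene_sets(ann, hi, {"S": 200.0}, {"S": 20}, seed=1)
        assert sets[0].symbols <= hi.symbols

    def test_infeasible_combination_names_set(self):
        ann = self.make_annotation(100)
        hi = es.GeneSet("HI", [f"G{i:05d}" for i in range(50)])
        with pytest.raises(ValueError, match="BIG"):
            sd.gen_gene_sets(ann, hi, {"BIG": 10.0}, {"BIG": 90}, seed=1)

    def test_planted_fe_recovered_at_study_scale(self):
        # headline-scale scenario: ~400-gene disease set, ~1,150 HI genes,
        # 18,000-gene background, planted fe 2.9
        ann = self.make_annotation(18_000)
        hi = es.GeneSet("HI", [f"G{i:05d}" for i in range(1150)])
        bg = es.GeneSet("bg", [t.gene_symbol for t in ann])
        ok = 0
        for seed in range(100):
            sets, _ = sd.gen_gene_sets(ann, hi, {"dbCRID": 2.9}, {"dbCRID": 400}, seed)
            fe = es.enrich(hi, sets[0], bg).fe
            if 2.0 <= fe <= 4.0:
                ok += 1
        assert ok >= 90


class TestGenRateTable:
    def test_zero_ds_leaves_ratio_undefined(self):
        gs = es.GeneSet("A", [f"G{i}" for i in range(500)])
        recs = sd.gen_rate_table([gs], sd.RateLaw(ds_zero_prob=0.2), {}, seed=1)
        zero_ds = [r for r in recs if r.ds == 0.0]
        assert zero_ds and all(r.dnds is None for r in zero_ds)
        assert all(r.dnds is not None for r in recs if r.ds > 0)

    def test_null_shifts_give_uniform_pvalues(self):
        gs_a = es.GeneSet("A", [f"A{i}" for i in range(150)])
        gs_b = es.GeneSet("B", [f"B{i}" for i in range(150)])
        pvals = []
        for seed in range(120):
            recs = sd.gen_rate_table([gs_a, gs_b], sd.RateLaw(), {}, seed=seed)
            comps = {c.metric: c for c in ec.compare_rates(gs_a, gs_b, recs, "none")}
            pvals.append(comps["dnds"].p)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_negative_shift_recovers_sign(self):
        gs_hi = es.GeneSet("HI", [f"A{i}" for i in range(200)])
        gs_hk = es.GeneSet("HK", [f"B{i}" for i in range(200)])
        hits = 0
        for seed in range(100):
            recs = sd.gen_rate_table([gs_hi, gs_hk], sd.RateLaw(), {"HK": -0.05}, seed=seed)
            comps = {c.metric: c for c in ec.compare_rates(gs_hi, gs_hk, recs, "none")}
            if comps["dn"].direction == -1 and comps["dn"].p < 0.05:
                hits += 1
        assert hits >= 95

    def test_priority_first_match_wins(self):
        both = [f"G{i}" for i in range(300)]
        a = es.GeneSet("A", both)
        b = es.GeneSet("B", both)  # same genes in both sets
        up = sd.gen_rate_table([a, b], sd.RateLaw(), {"A": 0.3, "B": -0.1}, seed=2)
        down = sd.gen_rate_table([a, b], sd.RateLaw(), {"B": -0.1, "A": 0.3}, seed=2)
        med = lambda recs: np.median([r.dnds for r in recs if r.dnds is not None])
        assert med(up) > med(down)


class TestGenSequencesAndRepeats:
    def regions(self, n, start_id=0, length=400):
        return [
            gi.GeneRegion(gi.GenomicInterval("chr1", 10_000 * (start_id + i),
                                             10_000 * (start_id + i) + length), (f"T{i}",))
            for i in range(n)
        ]

    def test_extreme_rates_are_exact(self):
        motif = sf.MotifSpec("CCCCACCCC")
        seqs, _, _ = sd.gen_sequences_and_repeats(
            {"a": self.regions(10), "b": self.regions(10, start_id=50)},
            {("a", motif.name): 1.0, ("b", motif.name): 0.0},
            {}, seed=8, motifs=[motif], seq_len_cap=300,
        )
        assert all(sf.count_motif(s, motif) >= 1 for s in seqs["a"])
        assert all(sf.count_motif(s, motif) == 0 for s in seqs["b"])

    def test_motif_longer_than_region_skipped(self):
        motif = sf.MotifSpec("CCCCACCCC")
        regions = [gi.GeneRegion(gi.GenomicInterval("chr1", 0, 6), ("T1",))]
        seqs, _, truth = sd.gen_sequences_and_repeats(
            {"a": regions}, {("a", motif.name): 1.0}, {}, seed=1, motifs=[motif],
        )
        assert truth.extras["motifs_skipped_too_long"] == 1
        assert len(seqs["a"][0].sequence) == 6

    def test_planted_repeat_ratio_flagged(self):
        hot = {"chr1": [(i * 100_000, i * 100_000 + 10_000) for i in range(10)]}
        extent = {"chr1": 1_000_000}
        hits = 0
        for seed in range(100):
            _, reps, _ = sd.gen_sequences_and_repeats(
                {}, {}, {"THE1B": 5.0, "L1": 1.0, "MIR": 1.0}, seed=seed,
                hot_space=hot, genome_extent=extent, base_repeat_per_mb=60.0,
            )
            hot_ivs = [gi.GenomicInterval("chr1", s, e) for s, e in hot["chr1"]]
            rest = [gi.GenomicInterval("chr1", e, e + 90_000) for _, e in hot["chr1"]]
            out = {r.name: r for r in sf.repeat_enrichment(reps, hot_ivs, rest)}
            if "THE1B" in out and out["THE1B"].q < 0.05 and out["THE1B"].fe > 1:
                hits += 1
        assert hits >= 95

    def test_deterministic(self):
        kw = dict(
            regions_by_class={"a": self.regions(5)},
            motif_rates={("a", "CCTCCCT"): 0.5},
            repeat_density_ratio={"X": 2.0, "Y": 1.0},
            seed=4,
            hot_space={"chr1": [(0, 50_000)]},
            genome_extent={"chr1": 500_000},
        )
        s1, r1, _ = sd.gen_sequences_and_repeats(**kw)
        s2, r2, _ = sd.gen_sequences_and_repeats(**kw)
        assert s1 == s2 and r1 == r2


class TestBundle:
    def test_all_files_written_and_readable(self, small_bundle):
        names = {"map.tsv", "genes.bed", "sets.tsv", "rates.tsv", "branches.tsv",
                 "regions.fa", "rmsk.tsv", "fragile.bed", "truth.json"}
        assert names <= {p.name for p in small_bundle.iterdir()}
        windows = gi.read_recomb_map(small_bundle / "map.tsv")
        txs = gi.read_transcripts(small_bundle / "genes.bed")
        sets = es.read_gene_sets(small_bundle / "sets.tsv")
        rates = ec.read_rate_table(small_bundle / "rates.tsv")
        seqs = sf.read_fasta(small_bundle / "regions.fa")
        reps = sf.read_repeat_table(small_bundle / "rmsk.tsv")
        sites = gi.read_bed(small_bundle / "fragile.bed")
        assert windows and txs and sets and rates and seqs and reps and sites
        truth = json.loads((small_bundle / "truth.json").read_text())
        assert truth["schema_version"] == 1
        assert set(truth["planted_fe"]) == set(sd.DEFAULT_PLANTED_FE)

    def test_fragile_hit_fraction_planted(self, small_bundle, small_config):
        sites = gi.read_bed(small_bundle / "fragile.bed")
        # the default 11-site census plants round(11 * 0.78) = 9 hit sites
        assert len(sites) == 11

    def test_bundle_deterministic(self, small_config, tmp_path):
        d1, d2 = tmp_path / "b1", tmp_path / "b2"
        sd.simulate_bundle(small_config, d1)
        sd.simulate_bundle(small_config, d2)
        for name in ("map.tsv", "genes.bed", "sets.tsv", "rates.tsv", "regions.fa",
                     "rmsk.tsv", "fragile.bed", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_null_bundle_neutralizes_truth(self, small_config, tmp_path):
        sd.simulate_bundle(small_config, tmp_path / "n", null=True)
        truth = json.loads((tmp_path / "n" / "truth.json").read_text())
        assert all(v == 1.0 for v in truth["planted_fe"].values())
        assert truth["rate_shifts"] == {}
        assert all(v == 1.0 for v in truth["repeat_density_ratio"].values())
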