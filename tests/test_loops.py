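"""Loop merging, strength, GSEA, enrichment permutations and classification."""

import numpy as np
import pandas as pd
import pytest

import loopshift as ls
from loopshift.contacts import ContactMatrix
from loopshift.loops import (
    LoopSet,
    anchor_element_enrichment,
    classify_responsive_loops,
    gene_category_enrichment,
    length_rank_gsea,
    loop_strength,
    merge_multires_loops,
    read_loops,
    write_loops,
)


def _loopset(genome, recs, resolution=None):
    return LoopSet(pd.DataFrame(recs), genome, resolution)


class TestMergeMultires:
    def test_loops_in_same_base_bin_collapse(self, genome):
        fine = _loopset(genome, [{"chrom": "chr1", "start1": 100_000, "end1": 105_000,
                                  "start2": 500_000, "end2": 505_000}], 5_000)
        mid = _loopset(genome, [{"chrom": "chr1", "start1": 110_000, "end1": 120_000,
                                 "start2": 510_000, "end2": 520_000}], 10_000)
        merged = merge_multires_loops([fine, mid], 25_000)
        assert len(merged) == 1
        assert merged.df.loc[0, "source_resolution"] == 5_000

    def test_distinct_bin_pairs_preserved(self, genome):
        a = _loopset(genome, [
            {"chrom": "chr1", "start1": 100_000, "end1": 105_000,
             "start2": 500_000, "end2": 505_000},
            {"chrom": "chr1", "start1": 200_000, "end1": 205_000,
             "start2": 700_000, "end2": 705_000},
        ], 5_000)
        assert len(merge_multires_loops([a], 25_000)) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_binpair_set_oracle(self, genome, seed):
        rng = np.random.default_rng(seed)
        sets = []
        expect = set()
        for res in (5_000, 10_000, 25_000):
            n = 30
            s1 = rng.integers(0, 8_000_000, n)
            gap = rng.integers(100_000, 1_000_000, n)
            chroms = np.where(rng.random(n) < 0.5, "chr1", "chr2")
            df = pd.DataFrame({"chrom": chroms, "start1": s1, "end1": s1 + res,
                               "start2": s1 + gap, "end2": s1 + gap + res})
            sets.append(LoopSet(df, genome, res))
            for c, a, b in zip(chroms, s1, s1 + gap):
                expect.add((c, (a + res // 2) // 25_000, (b + res // 2) // 25_000))
        merged = merge_multires_loops(sets, 25_000)
        got = {
            (r.chrom, r.start1 // 25_000, r.start2 // 25_000)
            for r in merged.df.itertuples()
        }
        assert got == expect

    def test_idempotent(self, genome):
        rng = np.random.default_rng(9)
        s1 = rng.integers(0, 8_000_000, 40)
        df = pd.DataFrame({"chrom": "chr1", "start1": s1, "end1": s1 + 5_000,
                           "start2": s1 + 400_000, "end2": s1 + 405_000})
        once = merge_multires_loops([LoopSet(df, genome, 5_000)], 25_000)
        twice = merge_multires_loops([once], 25_000)
        pd.testing.assert_frame_equal(
            once.df[["chrom", "start1", "start2"]], twice.df[["chrom", "start1", "start2"]]
        )

    def test_bedpe_roundtrip(self, tmp_path, genome):
        df = pd.DataFrame({"chrom": ["chr1", "chr2"], "start1": [100_000, 200_000],
                           "end1": [125_000, 225_000], "start2": [600_000, 800_000],
                           "end2": [625_000, 825_000]})
        loops = LoopSet(df, genome, 25_000)
        p = tmp_path / "l.bedpe"
        write_loops(loops, p)
        back = read_loops(p, genome, 25_000)
        pd.testing.assert_frame_equal(loops.df, back.df)


class TestLoopStrength:
    def test_all_ones_oe(self, genome):
        n = 100
        iu, ju = np.triu_indices(n)
        m = ContactMatrix("chr1", 25_000, n, iu, ju, np.ones(len(iu)),
                          state="oe", weights=np.ones(n))
        row = {"chrom": "chr1", "start1": 20 * 25_000, "end1": 21 * 25_000,
               "start2": 60 * 25_000, "end2": 61 * 25_000}
        assert loop_strength({"chr1": m}, row) == pytest.approx(1.0)

    def test_planted_bump_recovered(self, sim_map):
        truth = sim_map["truth"]
        vals = []
        for r in truth.loops.itertuples():
            row = {"chrom": r.chrom, "start1": r.bin1 * 25_000, "end1": (r.bin1 + 1) * 25_000,
                   "start2": r.bin2 * 25_000, "end2": (r.bin2 + 1) * 25_000}
            try:
                vals.append(loop_strength(sim_map["bal"], row, sim_map["exp"]))
            except ValueError:
                pass
        assert np.nanmean(vals) == pytest.approx(2.0, rel=0.15)

    def test_identical_conditions_zero_log2fc(self, sim_map):
        truth = sim_map["truth"]
        genome = sim_map["cfg"].genome()
        loops = LoopSet.from_bins(genome, truth.loops["chrom"][:5], truth.loops["bin1"][:5],
                                  truth.loops["bin2"][:5], 25_000)
        out = ls.loop_strength_log2fc(sim_map["bal"], sim_map["bal"], loops,
                                      sim_map["exp"], sim_map["exp"])
        fin = np.isfinite(out["log2fc"])
        assert np.allclose(out["log2fc"][fin], 0.0)


class TestLengthRankGsea:
    def _loops(self, genome, lengths):
        n = len(lengths)
        return LoopSet(pd.DataFrame({
            "chrom": "chr1", "start1": np.zeros(n, int), "end1": np.full(n, 1000),
            "start2": lengths, "end2": np.asarray(lengths) + 1000}), genome)

    def test_hits_at_top_give_maximal_es(self, genome):
        lengths = np.arange(100, 0, -1) * 10_000
        hits = np.zeros(100, bool)
        hits[:10] = True  # the 10 longest loops
        res, curve = length_rank_gsea(self._loops(genome, lengths), hits, n_perm=50, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value <= 1 / 51 + 1e-12

    def test_uniformly_interleaved_hits_score_near_zero(self, genome):
        lengths = np.arange(100, 0, -1) * 10_000
        hits = np.zeros(100, bool)
        hits[::10] = True  # perfectly spread along the ranking
        res, _ = length_rank_gsea(self._loops(genome, lengths), hits, n_perm=200, seed=0)
        assert abs(res.observed) < 0.15
        # the signed-max statistic of an interleaved pattern sits in the bulk
        # of the null, not its lower tail
        assert res.p_value > 0.3

    def test_empty_or_full_hit_set_rejected(self, genome):
        loops = self._loops(genome, np.arange(1, 11) * 10_000)
        with pytest.raises(ValueError):
            length_rank_gsea(loops, np.zeros(10, bool), 10, 0)
        with pytest.raises(ValueError):
            length_rank_gsea(loops, np.ones(10, bool), 10, 0)

    def test_bit_reproducible_under_seed(self, genome):
        rng = np.random.default_rng(1)
        lengths = rng.integers(50_000, 2_000_000, 80)
        hits = rng.random(80) < 0.2
        a, _ = length_rank_gsea(self._loops(genome, lengths), hits, n_perm=100, seed=42)
        b, _ = length_rank_gsea(self._loops(genome, lengths), hits, n_perm=100, seed=42)
        assert (a.observed, a.p_value, a.null_mean, a.null_sd) == \
               (b.observed, b.p_value, b.null_mean, b.null_sd)


class TestAnchorElementEnrichment:
    def test_saturating_elements_give_unit_enrichment(self, genome):
        loops = LoopSet.from_bins(genome, ["chr1"] * 4, [20, 80, 150, 250],
                                  [60, 120, 200, 300], 25_000)
        # 5 kb tiling: any 25 kb anchor holds exactly 5 peak midpoints, so
        # the count is placement-invariant and enrichment is exactly 1
        tile = np.arange(0, 10_000_000, 5_000)
        elements = ls.PeakSet(pd.DataFrame(
            {"chrom": "chr1", "start": tile, "end": tile + 5_000}), genome)
        enr, res = anchor_element_enrichment(loops, elements, genome, n_perm=50, seed=0)
        assert enr == pytest.approx(1.0, abs=0.05)

    def test_no_overlaps_anywhere_flagged_undefined(self, genome):
        loops = LoopSet.from_bins(genome, ["chr1"], [20], [60], 25_000)
        elements = ls.PeakSet(
            pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100]}), genome)
        with pytest.warns(RuntimeWarning, match="undefined"):
            enr, _ = anchor_element_enrichment(loops, elements, genome, n_perm=20, seed=0)
        assert np.isnan(enr)

    def test_planted_anchor_elements_enriched(self, genome):
        rng = np.random.default_rng(2)
        b1 = rng.integers(10, 200, 20)
        loops = LoopSet.from_bins(genome, ["chr1"] * 20, b1, b1 + 40, 25_000)
        els = pd.DataFrame({
            "chrom": "chr1",
            "start": loops.df["start1"] + 5_000,
            "end": loops.df["start1"] + 6_000,
        })
        enr, res = anchor_element_enrichment(
            loops, ls.PeakSet(els, genome), genome, n_perm=200, seed=1)
        assert enr > 3
        assert res.p_value == pytest.approx(1 / 201)


def _brute_force_classify(loops, tf, down, atac, track, lfc, min_length, top_n):
    """Per-loop predicate + sort oracle, all in plain python."""
    recs = []
    for i, row in enumerate(loops.df.itertuples()):
        length = ((row.start2 + row.end2) // 2) - ((row.start1 + row.end1) // 2)
        if length <= min_length:
            continue
        s, e = row.start1, row.end2
        score = 0.0
        for k in range(len(atac)):
            mid = (atac.starts[k] + atac.ends[k]) // 2
            if atac.chroms[k] == row.chrom and s <= mid <= e:
                score += track.region_mean(atac.chroms[k], atac.starts[k], atac.ends[k])
                score += abs(lfc[k])
        has_tf = any(
            tf.chroms[k] == row.chrom and s <= (tf.starts[k] + tf.ends[k]) // 2 <= e
            for k in range(len(tf)))
        has_down = any(
            down.chroms[k] == row.chrom and s <= (down.starts[k] + down.ends[k]) // 2 <= e
            for k in range(len(down)))
        recs.append((i, score, has_tf, has_down, row.chrom, row.start1))
    order = loops.genome.chrom_index
    resp = sorted([r for r in recs if r[2] and r[3]],
                  key=lambda r: (-r[1], order(r[4]), r[5]))[:top_n]
    less = sorted([r for r in recs if not r[2] and not r[3]],
                  key=lambda r: (r[1], order(r[4]), r[5]))[:top_n]
    return [r[0] for r in resp], [r[0] for r in less]


class TestClassifyResponsive:
    def _random_instance(self, genome, rng, n_loops=50):
        b1 = rng.integers(5, 300, n_loops)
        span = rng.integers(4, 80, n_loops)
        chroms = np.where(rng.random(n_loops) < 0.5, "chr1", "chr2")
        loops = LoopSet.from_bins(genome, chroms, b1, b1 + span, 25_000)

        def peaks(n):
            c = np.where(rng.random(n) < 0.5, "chr1", "chr2")
            s = rng.integers(0, 9_900_000, n)
            return ls.PeakSet(pd.DataFrame({"chrom": c, "start": s, "end": s + 500}), genome)

        track = ls.SignalTrack(
            10_000, {c: rng.random(1000) for c in genome.chrom_names})
        atac = peaks(40)
        return loops, peaks(25), peaks(25), atac, track, rng.normal(size=40)

    def test_loop_without_atac_scores_zero(self, genome):
        loops = LoopSet.from_bins(genome, ["chr1"], [10], [40], 25_000)
        empty = ls.PeakSet(pd.DataFrame(columns=["chrom", "start", "end"]), genome)
        atac = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr2"], "start": [100], "end": [600]}), genome)
        track = ls.SignalTrack(10_000, {c: np.ones(1000) for c in genome.chrom_names})
        with pytest.warns(RuntimeWarning):
            out = classify_responsive_loops(loops, empty, empty, atac, track,
                                            np.zeros(1), top_n=5)
        assert out.scores[0] == 0.0

    def test_forced_two_loop_partition(self, genome):
        loops = LoopSet.from_bins(genome, ["chr1", "chr1"], [10, 200], [40, 230], 25_000)
        tf = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [500_000], "end": [500_400]}), genome)
        down = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [600_000], "end": [600_400]}), genome)
        atac = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [500_000, 5_100_000],
             "end": [500_400, 5_100_400]}), genome)
        track = ls.SignalTrack(10_000, {c: np.ones(1000) for c in genome.chrom_names})
        out = classify_responsive_loops(loops, tf, down, atac, track,
                                        np.array([2.0, 0.0]), top_n=1)
        assert list(out.responsive) == [0]
        assert list(out.less_responsive) == [1]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, genome, seed):
        rng = np.random.default_rng(seed)
        loops, tf, down, atac, track, lfc = self._random_instance(genome, rng)
        got = classify_responsive_loops(loops, tf, down, atac, track, lfc,
                                        min_length=500_000, top_n=5)
        resp, less = _brute_force_classify(loops, tf, down, atac, track, lfc,
                                           500_000, 5)
        assert list(got.responsive) == resp
        assert list(got.less_responsive) == less


class TestGeneCategoryEnrichment:
    def test_saturating_loop_set_gives_unit_ratio(self, genome):
        loops = LoopSet(pd.DataFrame({
            "chrom": ["chr1", "chr2"], "start1": [0, 0], "end1": [1000, 1000],
            "start2": [9_990_000, 9_990_000], "end2": [10_000_000, 10_000_000]}), genome)
        rng = np.random.default_rng(0)
        n = 200
        tss = rng.integers(0, 9_000_000, n)
        chrom = np.where(rng.random(n) < 0.5, "chr1", "chr2")
        cat = rng.choice(["down", "unchanged", "up"], n)
        out = gene_category_enrichment(loops, tss, chrom, cat, genome, n_perm=20, seed=0)
        for c, (ratio, _) in out.items():
            assert ratio == pytest.approx(1.0)

    def test_uncategorized_gene_rejected(self, genome):
        loops = LoopSet.from_bins(genome, ["chr1"], [10], [40], 25_000)
        with pytest.raises(ValueError, match="uncategorized"):
            gene_category_enrichment(loops, [100], ["chr1"], ["weird"], genome, 10, 0)

    def test_planted_up_enrichment_recovered(self, genome):
        # 'up' genes planted at twice the background rate inside a sparse loop
        # set; observed/expected ratio ~ 2 / (1 + in-loop gene fraction)
        rng = np.random.default_rng(3)
        nl = 10
        starts = np.concatenate([rng.choice(np.arange(100, 9_000_000, 70_000), nl // 2,
                                            replace=False) for _ in range(2)])
        chroms = np.array(["chr1"] * (nl // 2) + ["chr2"] * (nl // 2))
        loops = LoopSet(pd.DataFrame({
            "chrom": chroms, "start1": starts, "end1": starts + 1000,
            "start2": starts + 59_000, "end2": starts + 60_000}), genome)
        ng = 40_000
        tss = rng.integers(0, 10_000_000, ng)
        gchrom = np.where(rng.random(ng) < 0.5, "chr1", "chr2")
        inloop = np.zeros(ng, bool)
        ch, s, e = loops.spans()
        for c0, s0, e0 in zip(ch, s, e):
            inloop |= (gchrom == c0) & (tss >= s0) & (tss < e0)
        p_up = np.where(inloop, 0.30, 0.15)
        u = rng.random(ng)
        cat = np.where(u < p_up, "up", np.where(u < p_up + 0.15, "down", "unchanged"))
        out = gene_category_enrichment(loops, tss, gchrom, cat, genome,
                                       n_perm=2000, seed=4)
        ratio, res = out["up"]
        assert ratio == pytest.approx(2.0, rel=0.15)
        assert res.p_value <= 0.01
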