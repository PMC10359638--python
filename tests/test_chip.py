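"""Track quantification, scalings, annotation, clustering and small formulas."""

import numpy as np
import pandas as pd
import pytest

import loopshift as ls
from loopshift.chip import (
    annotate_peaks,
    bound_unbound_genes,
    build_regulatory_elements,
    cluster_diff_signal,
    cooccupancy_categories,
    feature_matrix,
    percent_input,
    resource_annotations,
    rpgc_scale,
    spike_in_scale,
    zscore_rows,
)


class TestScalings:
    @pytest.mark.parametrize("cov,size,expect", [(1e9, 1e9, 1.0), (2e9, 1e9, 0.5)])
    def test_rpgc_examples(self, cov, size, expect):
        assert rpgc_scale(cov, size) == expect

    def test_rpgc_makes_mean_coverage_one(self):
        rng = np.random.default_rng(0)
        track = ls.SignalTrack(100, {"chr1": rng.random(10_000) * 7})
        total_cov = sum(v.sum() * 100 for v in track.data.values())
        f = rpgc_scale(total_cov, 1_000_000)
        scaled = track.scale(f)
        assert np.mean(scaled.data["chr1"]) == pytest.approx(1.0, abs=1e-12)

    def test_rpgc_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            rpgc_scale(0, 1e9)

    @pytest.mark.parametrize("spike,ref,expect", [(1000, 1000, 1.0), (2000, 1000, 0.5)])
    def test_spike_in_examples(self, spike, ref, expect):
        assert spike_in_scale(10_000, spike, ref) == expect

    def test_spike_in_removes_planted_depth_difference(self):
        # equal truth, 2x depth difference: scaled tracks agree within 5%
        rng = np.random.default_rng(1)
        truth = rng.random(5000) * 4 + 1
        a = np.random.default_rng(2).poisson(truth * 20) / 1.0
        b = np.random.default_rng(3).poisson(truth * 40) / 1.0
        fa = spike_in_scale(0, 1000, 1000)
        fb = spike_in_scale(0, 2000, 1000)
        ratio = (a * fa).sum() / (b * fb).sum()
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestFeatureMatrix:
    def test_constant_track_constant_cells(self, genome):
        track = ls.SignalTrack(100, {c: np.full(100_000, 2.5) for c in genome.chrom_names})
        peaks = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [1_000_000], "end": [1_001_000]}), genome)
        fm = feature_matrix(track, peaks, flank=2000, bin=100)
        assert np.allclose(fm.values, 2.5)

    def test_minus_strand_row_is_reversed_mirror(self, genome):
        rng = np.random.default_rng(4)
        track = ls.SignalTrack(100, {"chr1": rng.random(100_000)})
        plus = [ls.Gene("gp", "chr1", "+", 1_000_000, 1_020_000)]
        minus = [ls.Gene("gm", "chr1", "-", 1_000_000, 980_000)]
        fp = feature_matrix(track, plus, flank=1000, bin=100, mode="tss")
        fm = feature_matrix(track, minus, flank=1000, bin=100, mode="tss")
        np.testing.assert_allclose(fm.values[0], fp.values[0][::-1])

    def test_matches_gather_oracle(self, genome):
        rng = np.random.default_rng(5)
        vals = rng.random(100_000)
        track = ls.SignalTrack(100, {"chr1": vals})
        centers = [500_000, 2_000_000]
        peaks = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [c - 50 for c in centers],
             "end": [c + 50 for c in centers]}), genome)
        fm = feature_matrix(track, peaks, flank=500, bin=100)
        for r, c in enumerate(centers):
            expect = [vals[(c + off) // 100] for off in range(-500, 500, 100)]
            np.testing.assert_allclose(fm.values[r], expect)

    def test_off_chromosome_cells_masked(self, genome):
        track = ls.SignalTrack(100, {"chr1": np.ones(100_000)})
        peaks = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100]}), genome)
        fm = feature_matrix(track, peaks, flank=1000, bin=100)
        assert np.isnan(fm.values[0][:9]).all()
        profile = fm.meta_profile()
        assert np.isfinite(profile[-1])


class TestAnnotation:
    def _elements(self, genome):
        genes = [ls.Gene("g1", "chr1", "+", 100_000, 120_000)]
        active = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [99_500, 400_000],
             "end": [100_500, 401_000]}), genome)
        ctcf = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [400_500, 700_000],
             "end": [401_500, 701_000]}), genome)
        return build_regulatory_elements(genes, active, ctcf, genome)

    def test_builder_applies_exclusions(self, genome):
        promoters, enhancers, ctcf_sites, bodies = self._elements(genome)
        assert len(promoters) == 1
        # active peak inside the promoter is not an enhancer
        assert len(enhancers) == 1 and enhancers.starts[0] == 400_000
        # ctcf peak overlapping that enhancer is dropped
        assert len(ctcf_sites) == 1 and ctcf_sites.starts[0] == 700_000

    def test_priority_promoter_beats_enhancer(self, genome):
        promoters, enhancers, ctcf_sites, bodies = self._elements(genome)
        peaks = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [99_800], "end": [100_200]}), genome)
        cats, props = annotate_peaks(peaks, promoters, enhancers, ctcf_sites, bodies)
        assert cats[0] == "promoter"

    def test_orphan_peak_is_other(self, genome):
        promoters, enhancers, ctcf_sites, bodies = self._elements(genome)
        peaks = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr2"], "start": [1000], "end": [2000]}), genome)
        cats, props = annotate_peaks(peaks, promoters, enhancers, ctcf_sites, bodies)
        assert cats[0] == "other"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sequential_predicate_oracle(self, genome, seed):
        from conftest import random_peakset
        rng = np.random.default_rng(seed)
        peaks = random_peakset(genome, rng, 60, max_len=5000)
        element_sets = [random_peakset(genome, rng, 20, max_len=5000) for _ in range(4)]
        cats, props = annotate_peaks(peaks, *element_sets)
        names = ["promoter", "enhancer", "ctcf", "gene_body"]
        for i in range(len(peaks)):
            expect = "other"
            for name, es in zip(names, element_sets):
                if any(es.chroms[j] == peaks.chroms[i]
                       and es.starts[j] < peaks.ends[i] and peaks.starts[i] < es.ends[j]
                       for j in range(len(es))):
                    expect = name
                    break
            assert cats[i] == expect
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)


class TestBoundUnbound:
    def _setup(self, genome, rng, n_genes=30, n_peaks=10):
        genes = [ls.Gene(f"g{i:02d}", "chr1", "+", int(p), int(p) + 10_000)
                 for i, p in enumerate(sorted(rng.choice(
                     np.arange(50_000, 9_000_000, 20_000), n_genes, replace=False)))]
        peak_genes = rng.choice(n_genes, n_peaks, replace=False)
        tf = ls.PeakSet(pd.DataFrame({
            "chrom": "chr1",
            "start": [genes[i].tss - 200 for i in peak_genes],
            "end": [genes[i].tss + 200 for i in peak_genes]}), genome)
        track = ls.SignalTrack(1000, {"chr1": rng.random(10_000) * 5})
        return genes, tf, track

    def test_gene_without_promoter_peak_never_bound(self, genome):
        rng = np.random.default_rng(6)
        genes, tf, track = self._setup(genome, rng)
        with pytest.warns(RuntimeWarning):
            bound, unbound = bound_unbound_genes(genes, tf, track, genome, top_n=1000)
        hit, _ = ls.intersect(
            ls.PeakSet(pd.DataFrame({
                "chrom": [g.chrom for g in bound],
                "start": [g.tss - 1000 for g in bound],
                "end": [g.tss + 1000 for g in bound]}), genome), tf)
        assert hit.all()

    def test_forced_selection_top3(self, genome):
        rng = np.random.default_rng(7)
        genes, tf, track = self._setup(genome, rng, n_genes=10, n_peaks=5)
        bound, unbound = bound_unbound_genes(genes, tf, track, genome, top_n=3)
        assert len(bound) == 3 and len(unbound) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_filter_then_sort_oracle(self, genome, seed):
        rng = np.random.default_rng(seed)
        genes, tf, track = self._setup(genome, rng)
        top_n = 5
        bound, unbound = bound_unbound_genes(genes, tf, track, genome, top_n=top_n)

        def signal(g):
            return track.region_mean(g.chrom, g.tss - 1000, g.tss + 1000)

        def has_peak(g):
            return any(tf.chroms[j] == g.chrom
                       and tf.starts[j] < g.tss + 1000 and g.tss - 1000 < tf.ends[j]
                       for j in range(len(tf)))

        expect_bound = sorted([g for g in genes if has_peak(g)],
                              key=lambda g: (-signal(g), g.id))[:top_n]
        expect_unbound = sorted([g for g in genes if not has_peak(g)],
                                key=lambda g: (signal(g), g.id))[:top_n]
        assert [g.id for g in bound] == [g.id for g in expect_bound]
        assert [g.id for g in unbound] == [g.id for g in expect_unbound]


class TestZscore:
    def test_simple_row(self):
        z, flagged = zscore_rows([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(z[0], [-1, 0, 1])
        assert len(flagged) == 0

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(8)
        z1, _ = zscore_rows(rng.random((5, 10)))
        z2, _ = zscore_rows(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_constant_row_flagged_zero(self):
        z, flagged = zscore_rows([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        assert list(flagged) == [0]
        assert (z[0] == 0).all()

    def test_random_matrix_moments(self):
        rng = np.random.default_rng(9)
        z, _ = zscore_rows(rng.random((20, 30)))
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-12


class TestClusterDiffSignal:
    def _planted(self, rng, centers, rows_per=20, dim=6, noise=0.05):
        rows = np.concatenate([
            c + rng.normal(0, noise, (rows_per, dim)) for c in centers
        ])
        labels = np.repeat(np.arange(len(centers)), rows_per)
        return rows, labels

    def test_three_planted_groups_found(self):
        rng = np.random.default_rng(10)
        centers = [np.zeros(6), np.full(6, 3.0), np.array([3, 3, 3, -3, -3, -3.0])]
        rows, truth = self._planted(rng, centers)
        labels, k, curve, degenerate = cluster_diff_signal(rows, range(2, 7))
        assert k == 3 and not degenerate
        # partition identity up to label names
        for t in np.unique(truth):
            assert len(np.unique(labels[truth == t])) == 1

    def test_two_planted_groups_found(self):
        rng = np.random.default_rng(11)
        rows, truth = self._planted(rng, [np.zeros(6), np.full(6, 4.0)])
        labels, k, curve, degenerate = cluster_diff_signal(rows, range(2, 7))
        assert k == 2

    def test_identical_rows_degenerate(self):
        rows = np.ones((10, 4))
        labels, k, curve, degenerate = cluster_diff_signal(rows, range(2, 5))
        assert degenerate and k == 2

    def test_small_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_diff_signal(np.ones((2, 3)), [2])


class TestCooccupancy:
    def test_two_identical_sets_label_two(self, genome):
        ps = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [1000], "end": [2000]}), genome)
        df, counts = cooccupancy_categories({"a": ps, "b": ps})
        assert len(df) == 1 and df.loc[0, "category"] == "2"

    def test_disjoint_sets_label_one(self, genome):
        sets = {
            f"f{i}": ls.PeakSet(pd.DataFrame(
                {"chrom": ["chr1"], "start": [i * 10_000], "end": [i * 10_000 + 500]}),
                genome)
            for i in range(5)
        }
        df, counts = cooccupancy_categories(sets)
        assert len(df) == 5 and (df["category"] == "1").all()

    def test_five_shared_sites_label_4plus(self, genome):
        ps = ls.PeakSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [1000], "end": [2000]}), genome)
        df, counts = cooccupancy_categories({f"f{i}": ps for i in range(5)})
        assert df.loc[0, "category"] == "4+"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_membership_oracle(self, genome, seed):
        from conftest import random_peakset
        rng = np.random.default_rng(seed)
        sets = {f"f{i}": random_peakset(genome, rng, 15, max_len=20_000) for i in range(4)}
        df, counts = cooccupancy_categories(sets)
        # oracle: per merged region, count factors with an overlapping peak
        for row in df.itertuples():
            n = sum(
                any(ps.chroms[j] == row.chrom
                    and ps.starts[j] < row.end and row.start < ps.ends[j]
                    for j in range(len(ps)))
                for ps in sets.values()
            )
            assert n == row.n_factors
        # regions tile the union without overlap
        for chrom in df["chrom"].unique():
            sub = df[df["chrom"] == chrom]
            assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()


class TestPercentInput:
    def test_equal_ct_gives_input_fraction(self):
        assert percent_input(24.0, 24.0) == pytest.approx(5.0)

    def test_one_cycle_halves(self):
        assert percent_input(24.0, 25.0) == pytest.approx(2.5)

    def test_two_cycles_quadruple(self):
        assert percent_input(24.0, 22.0) == pytest.approx(20.0)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            percent_input(np.nan, 24.0)


class TestResourceAnnotations:
    def test_threshold_is_strict_and_essentiality_table(self):
        tpm = pd.DataFrame(
            {"t1": [50.0, 10.0, 5.0], "t2": [20.0, 12.0, 5.0]},
            index=["gA", "gB", "gC"])
        crispr = pd.DataFrame(
            {"score": [-0.5, -0.5, 0.3], "p": [0.01, 0.2, 0.01]},
            index=["gA", "gB", "gC"])
        out = resource_annotations(tpm, crispr)
        assert out.loc["gA", "expression_pct"] == 100.0
        assert out.loc["gB", "expression_pct"] == 50.0  # TPM exactly 10 not counted
        assert out.loc["gC", "expression_pct"] == 0.0
        assert bool(out.loc["gA", "essential"]) is True
        assert bool(out.loc["gB", "essential"]) is False
        assert bool(out.loc["gC", "essential"]) is False
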