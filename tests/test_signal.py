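"""Repeat read summation, cpm normalization, and binned signal matrices."""

import numpy as np
import pandas as pd
import pytest

import retrochip as rc
from retrochip.annotation import FragmentSet, RepeatAnnotation
from retrochip.intervals import IntervalSet
from retrochip.signal import CountMatrix

from oracles import brute_per_query_label_membership

SIZES = {"chr1": 100_000}


def _frags(df, sample="s1", lib=None, spike=0):
    ivs = IntervalSet.from_dataframe(df, chrom_sizes=SIZES)
    return FragmentSet(sample, ivs, library_size=lib or len(ivs), spikein_size=spike)


def _repeats(rows):
    return RepeatAnnotation(
        pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "repeat_name",
                     "repeat_family", "repeat_class"],
        ),
        chrom_sizes=SIZES,
    )


class TestSumReadsPerRepeat:
    def test_single_fragment_in_single_instance(self):
        reps = _repeats([("chr1", 1000, 3000, "IAPEz-int", "ERVK", "LTR")])
        frags = _frags(pd.DataFrame({"chrom": ["chr1"], "start": [1500], "end": [1700]}))
        cm = rc.sum_reads_per_repeat(frags, reps, "repeat_name")
        assert cm.counts.loc["IAPEz-int", "s1"] == 1

    def test_fragment_bridging_two_same_name_instances_counts_once(self):
        reps = _repeats(
            [
                ("chr1", 1000, 2000, "IAPEz-int", "ERVK", "LTR"),
                ("chr1", 2100, 3000, "IAPEz-int", "ERVK", "LTR"),
            ]
        )
        frags = _frags(pd.DataFrame({"chrom": ["chr1"], "start": [1900], "end": [2200]}))
        cm = rc.sum_reads_per_repeat(frags, reps, "repeat_name")
        assert cm.counts.loc["IAPEz-int", "s1"] == 1

    def test_fragment_spanning_two_groups_counts_for_both(self):
        reps = _repeats(
            [
                ("chr1", 1000, 2000, "IAPEz-int", "ERVK", "LTR"),
                ("chr1", 2100, 3000, "L1Md_A", "L1", "LINE"),
            ]
        )
        frags = _frags(pd.DataFrame({"chrom": ["chr1"], "start": [1900], "end": [2200]}))
        cm = rc.sum_reads_per_repeat(frags, reps, "repeat_name")
        assert cm.counts.loc["IAPEz-int", "s1"] == 1
        assert cm.counts.loc["L1Md_A", "s1"] == 1

    def test_matches_bruteforce_on_simulated_fragments(self, toy_genome, toy_chip):
        frags = toy_chip.chip[0]
        sub = frags.fragments.subset(np.arange(0, len(frags.fragments), 2))
        fs = FragmentSet("sub", sub, library_size=len(sub))
        cm = rc.sum_reads_per_repeat(fs, toy_genome.repeats, "repeat_name")
        brute = brute_per_query_label_membership(
            sub.to_dataframe(), toy_genome.repeats.to_dataframe(), "repeat_name"
        )
        for name in cm.counts.index:
            assert cm.counts.loc[name, "sub"] == int(brute[name].sum()), name

    def test_empty_annotation_rejected(self):
        reps = _repeats([("chr1", 0, 10, "x", "y", "z")])
        reps.instances = reps.instances.subset(np.array([], dtype=int))
        frags = _frags(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}))
        empty = RepeatAnnotation.__new__(RepeatAnnotation)
        empty.instances = reps.instances
        empty.labels = reps.labels.iloc[:0]
        empty._merged_cache = {}
        with pytest.raises(ValueError, match="empty"):
            rc.sum_reads_per_repeat(frags, empty, "repeat_name")


class TestNormalizeCounts:
    def _matrix(self, counts, libs, spikes=None):
        df = pd.DataFrame(counts)
        return CountMatrix(
            counts=df,
            library_size=pd.Series(libs),
            spikein_size=pd.Series(spikes or {c: 0 for c in df.columns}),
        )

    def test_cpm_definition_prior_zero(self):
        m = self._matrix({"a": [10]}, {"a": 2_000_000})
        # single sample: the scaled prior is prior * 1, here zero
        out = rc.normalize_counts(m, prior_count=0)
        assert out.loc[0, "a"] == pytest.approx(5.0)

    def test_joint_scale_invariance(self):
        m1 = self._matrix({"a": [10, 3], "b": [7, 9]}, {"a": 1_000_000, "b": 2_000_000})
        m2 = self._matrix({"a": [20, 6], "b": [14, 18]}, {"a": 2_000_000, "b": 4_000_000})
        pd.testing.assert_frame_equal(
            rc.normalize_counts(m1, prior_count=0), rc.normalize_counts(m2, prior_count=0)
        )

    def test_equal_counts_at_equal_depth_give_equal_values(self):
        m = self._matrix({"a": [10], "b": [10]}, {"a": 500_000, "b": 500_000})
        out = rc.normalize_counts(m, prior_count=3)
        assert out.loc[0, "a"] == out.loc[0, "b"]

    def test_spikein_mode_uses_spikein_denominator(self):
        m = self._matrix(
            {"a": [10], "b": [10]},
            {"a": 1_000_000, "b": 1_000_000},
            {"a": 1000, "b": 2000},
        )
        out = rc.normalize_counts(m, mode="spikein", prior_count=0)
        assert out.loc[0, "a"] == pytest.approx(2 * out.loc[0, "b"])

    def test_spikein_zero_rejected_with_sample_name(self):
        m = self._matrix({"a": [10], "b": [10]}, {"a": 1, "b": 1}, {"a": 100, "b": 0})
        with pytest.raises(ValueError, match="b"):
            rc.normalize_counts(m, mode="spikein")

    def test_monotone_in_counts(self):
        m1 = self._matrix({"a": [10, 20]}, {"a": 1_000_000})
        m2 = self._matrix({"a": [11, 20]}, {"a": 1_000_000})
        assert (
            rc.normalize_counts(m2)["a"].iloc[0] > rc.normalize_counts(m1)["a"].iloc[0]
        )

    def test_global_efficiency_loss_separates_modes(self, toy_genome):
        """Halving all genome fragments with spike-ins fixed is invisible to
        library-size normalization but shows as 0.5x under spike-in mode."""
        cfg = rc.ChipSimConfig(
            seed=40, n_replicates=2, fragments_per_replicate=100_000,
            enrichment={"ERVK": 4.0}, spikein_fraction=0.05,
            group_key="repeat_family",
        )
        wt = rc.simulate_chip_fragments(toy_genome, cfg)
        spike_total = wt.chip[0].spikein_size

        def halved(fs, name):
            sub = fs.fragments.subset(np.arange(len(fs.fragments)) % 2 == 0)
            return FragmentSet(name, sub, library_size=len(sub),
                               spikein_size=spike_total)

        full = FragmentSet("wt", wt.chip[0].fragments,
                           library_size=len(wt.chip[0].fragments),
                           spikein_size=spike_total)
        half = halved(wt.chip[1], "mut")
        cm = rc.sum_reads_per_repeat([full, half], toy_genome.repeats, "repeat_family")
        lib = rc.normalize_counts(cm, mode="library_size", prior_count=0)
        spk = rc.normalize_counts(cm, mode="spikein", prior_count=0)
        lib_ratio = (lib["mut"] / lib["wt"]).loc["ERVK"]
        spk_ratio = (spk["mut"] / spk["wt"]).loc["ERVK"]
        assert abs(lib_ratio - 1.0) < 0.10
        assert abs(spk_ratio - 0.5) < 0.05


class TestSignalMatrix:
    def test_single_fragment_hits_only_central_bin(self):
        # fragment exactly covering the bin just right of the summit
        frags = _frags(
            pd.DataFrame({"chrom": ["chr1"], "start": [5025], "end": [5075]}),
            lib=1_000_000,
        )
        anchors = IntervalSet(["chr1"], [5025], [5026])
        bs = rc.signal_matrix(frags, anchors, flank=500, bin_width=50)
        nonzero = np.flatnonzero(np.nan_to_num(bs.matrix[0]) > 0)
        assert list(nonzero) == [10]

    def test_flank_not_multiple_of_bin_rejected(self):
        frags = _frags(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}))
        anchors = IntervalSet(["chr1"], [500], [501])
        with pytest.raises(ValueError, match="multiple"):
            rc.signal_matrix(frags, anchors, flank=100, bin_width=33)

    def test_window_beyond_chromosome_gives_nan_not_zero(self):
        frags = _frags(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}))
        anchors = IntervalSet(["chr1"], [100], [101], chrom_sizes=SIZES)
        bs = rc.signal_matrix(frags, anchors, flank=500, bin_width=50,
                              chrom_sizes=SIZES)
        assert np.isnan(bs.matrix[0, :7]).all()  # bins left of position 0
        assert not np.isnan(bs.matrix[0, 8:]).any()

    def test_uniform_field_is_flat_within_poisson(self):
        rng = np.random.default_rng(50)
        n = 40_000
        starts = rng.integers(0, 99_000, size=n)
        frags = _frags(
            pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 100}),
            lib=n,
        )
        anchor_pos = rng.integers(5000, 95_000, size=200)
        anchors = IntervalSet(["chr1"] * 200, anchor_pos, anchor_pos + 1)
        bs = rc.signal_matrix(frags, anchors, flank=1000, bin_width=100)
        col_total = np.nansum(bs.matrix, axis=0) * n / 1e6  # raw counts per column
        expected = col_total.mean()
        assert np.all(np.abs(col_total - expected) < 4 * np.sqrt(expected))

    def test_planted_enrichment_ratio_recovered(self):
        rng = np.random.default_rng(51)
        hot = np.arange(10_000, 50_000, 4000)  # 10 hot anchors
        cold = np.arange(60_000, 92_000, 3200)  # 10 cold anchors
        bg_starts = rng.integers(0, 99_800, size=20_000)
        hot_starts = np.concatenate(
            [rng.integers(h - 100, h + 1, size=200) for h in hot]
        )
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.concatenate([bg_starts, hot_starts]),
            }
        )
        df["end"] = df["start"] + 100
        frags = _frags(df)
        anchors = IntervalSet(
            ["chr1"] * 20, np.concatenate([hot, cold]),
            np.concatenate([hot, cold]) + 1,
        )
        bs = rc.signal_matrix(frags, anchors, flank=500, bin_width=100)
        # rows are waterfall-ordered; hot anchors must sort first
        center = bs.matrix[:, 4:6].mean(axis=1)
        hot_mean = center[:10].mean()
        cold_mean = center[10:].mean()
        planted = 1 + 200 / (20_000 * 200 / 100_000)  # hot rate over background
        assert hot_mean / cold_mean == pytest.approx(planted, rel=0.2)

    def test_waterfall_rows_sorted_by_descending_mean(self, toy_chip):
        fs = toy_chip.chip[0]
        pos = np.arange(10_000, 90_000, 8000)
        anchors = IntervalSet(["chr1"] * len(pos), pos, pos + 1)
        bs = rc.signal_matrix(fs, anchors, flank=1000, bin_width=100)
        means = np.nanmean(bs.matrix, axis=1)
        assert np.all(np.diff(means) <= 1e-12)


class TestGenomeBinnedSignal:
    def test_bin_count_and_truncation(self):
        frags = _frags(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}))
        out = rc.genome_binned_signal(frags, {"chr1": 10_500}, bin_width=1000)
        assert len(out) == 11
        assert out["end"].iloc[-1] == 10_500

    def test_fragment_counts_in_every_bin_it_overlaps(self):
        frags = _frags(
            pd.DataFrame({"chrom": ["chr1"], "start": [950], "end": [2050]}), lib=1
        )
        out = rc.genome_binned_signal(frags, {"chr1": 10_000}, bin_width=1000)
        hits = out[out["s1"] > 0]
        assert hits["start"].tolist() == [0, 1000, 2000]

    def test_bin_sum_vs_fragment_count(self):
        rng = np.random.default_rng(60)
        starts = rng.integers(0, 99_000, size=5000)
        frags = _frags(
            pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 100}),
        )
        out = rc.genome_binned_signal(frags, SIZES, bin_width=1000)
        raw = out["s1"].sum() / 1e6 * frags.library_size
        assert raw >= 5000
        # exact when no fragment spans a bin boundary
        aligned_starts = (starts // 1000) * 1000
        frags2 = _frags(
            pd.DataFrame(
                {"chrom": "chr1", "start": aligned_starts, "end": aligned_starts + 100}
            )
        )
        out2 = rc.genome_binned_signal(frags2, SIZES, bin_width=1000)
        assert out2["s1"].sum() / 1e6 * frags2.library_size == pytest.approx(5000)

    def test_shared_loci_correlate_more_than_independent(self, toy_genome):
        """Two ChIP replicates (shared enrichment) out-correlate a ChIP vs
        an input replicate across genomic bins, over many seeds."""
        wins = 0
        for seed in range(20):
            cfg = rc.ChipSimConfig(
                seed=100 + seed, n_replicates=2, fragments_per_replicate=10_000,
                enrichment={"ERVK": 6.0}, group_key="repeat_family",
            )
            res = rc.simulate_chip_fragments(toy_genome, cfg)
            out = rc.genome_binned_signal(
                res.chip + res.input, toy_genome.chrom_sizes, bin_width=1000
            )
            r_shared = out["chip_rep1"].corr(out["chip_rep2"])
            r_indep = out["chip_rep1"].corr(out["input_rep2"])
            wins += int(r_shared > r_indep)
        assert wins >= 19
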