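"""Peak filtering, category assignment, and the bootstrap enrichment null."""

import numpy as np
import pandas as pd
import pytest

import retrochip as rc
from retrochip.intervals import IntervalSet
from retrochip.peaks import (
    PeakTable,
    category_combinations,
    random_matched_regions,
    replicate_fold_ratios,
    tally_label_presence,
    _merged_label_arrays,
)

from conftest import random_interval_frame
from oracles import brute_per_query_label_membership, random_region_hit_probability


def _table_from_ratios(ratios_per_peak, libsize=1_000_000):
    """Build a PeakTable whose pseudocounted, depth-normalized ratios are
    exactly the requested values (input count 999, chip = ratio*1000 - 1)."""
    n = len(ratios_per_peak)
    reps = len(ratios_per_peak[0])
    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 300,
            "summit": np.arange(n) * 1000 + 150,
        }
    )
    chip = pd.DataFrame(
        {
            f"chip{r}": [int(round(ratios_per_peak[i][r] * 1000)) - 1 for i in range(n)]
            for r in range(reps)
        }
    )
    inp = pd.DataFrame({f"input{r}": [999] * n for r in range(reps)})
    return PeakTable(
        peaks=peaks,
        chip_counts=chip,
        input_counts=inp,
        chip_libsizes=pd.Series({f"chip{r}": libsize for r in range(reps)}),
        input_libsizes=pd.Series({f"input{r}": libsize for r in range(reps)}),
    )


class TestFilterEnrichedPeaks:
    def test_threshold_rule_keeps_three_of_four(self):
        table = _table_from_ratios([[1.5, 1.3, 1.25, 1.1]])
        kept = rc.filter_enriched_peaks(table, min_fold=1.2, min_reps=3)
        assert len(kept) == 1

    def test_boundary_ratio_is_discarded_strict_inequality(self):
        table = _table_from_ratios([[1.2, 1.2, 1.2, 1.2]])
        kept = rc.filter_enriched_peaks(table, min_fold=1.2, min_reps=3)
        assert len(kept) == 0

    def test_ten_peak_toy_table_matches_hand_enumeration(self):
        ratios = [
            [1.5, 1.4, 1.3],   # keep: 3 pass
            [1.5, 1.4, 1.1],   # drop: 2 pass
            [1.2, 1.2, 1.2],   # drop: boundary, strict
            [1.21, 1.21, 1.21],  # keep
            [0.5, 0.6, 0.7],   # drop
            [2.0, 2.0, 0.9],   # drop: 2 pass
            [1.3, 1.3, 1.3],   # keep
            [1.0, 1.0, 1.0],   # drop
            [5.0, 5.0, 5.0],   # keep
            [1.19, 1.3, 1.3],  # drop: 2 pass
        ]
        table = _table_from_ratios(ratios)
        kept = rc.filter_enriched_peaks(table, min_fold=1.2, min_reps=3)
        assert sorted(kept.peaks["start"] // 1000) == [0, 3, 6, 8]

    def test_computed_ratios_are_depth_normalized_with_pseudocount(self):
        table = _table_from_ratios([[1.5, 1.5, 1.5]])
        ratios = replicate_fold_ratios(table)
        assert np.allclose(ratios.to_numpy(), 1.5)

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(0)
        ratios = rng.uniform(0.5, 3.0, size=(50, 4)).tolist()
        table = _table_from_ratios(ratios)
        base = len(rc.filter_enriched_peaks(table, min_fold=1.2, min_reps=2))
        assert len(rc.filter_enriched_peaks(table, min_fold=1.5, min_reps=2)) <= base
        assert len(rc.filter_enriched_peaks(table, min_fold=1.2, min_reps=3)) <= base

    def test_too_few_replicates_rejected(self):
        table = _table_from_ratios([[1.5, 1.5]])
        with pytest.raises(ValueError, match="replicate"):
            rc.filter_enriched_peaks(table, min_reps=3)


class TestCategorizePeaks:
    def test_plus_strand_promoter_window(self, toy_genes):
        win = toy_genes.tss_windows(upstream=300).to_dataframe()
        t1 = win.iloc[0]  # + strand TSS at 10_000
        assert (t1["start"], t1["end"]) == (9_700, 10_000)

    def test_minus_strand_promoter_window_reflected(self, toy_genes):
        win = toy_genes.tss_windows(upstream=300).to_dataframe()
        t2 = win[win["strand"] == "-"].iloc[0]  # - strand TSS at 58_000
        assert (t2["start"], t2["end"]) == (58_000, 58_300)

    def test_missing_strand_rejected(self):
        tx = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100], "strand": ["."],
             "transcript_id": ["t"], "gene_id": ["g"]}
        )
        with pytest.raises(ValueError, match="strand"):
            rc.GeneAnnotation(tx, tx.assign(transcript_id="t"))

    def test_peak_in_repeat_only(self, toy_genome, toy_genes):
        inst = toy_genome.repeats.to_dataframe().iloc[0]
        peaks = IntervalSet(
            [inst["chrom"]], [inst["start"] + 10], [inst["start"] + 60]
        )
        cats = rc.categorize_peaks(peaks, toy_genes, toy_genome.repeats)
        assert bool(cats.loc[0, "repeat"])
        assert not cats.loc[0, ["TSS", "exon", "intron"]].any()
        assert not cats.loc[0, "intergenic"]

    def test_intron_exclusion_drops_exactly_intronic_instances(
        self, toy_genome, toy_genes
    ):
        filtered = rc.exclude_intronic_instances(toy_genome.repeats, toy_genes)
        introns = toy_genes.intron_intervals().merge()
        assert not introns.overlaps_any(filtered.instances).any()
        dropped = len(toy_genome.repeats) - len(filtered)
        assert dropped == int(
            introns.overlaps_any(toy_genome.repeats.instances).sum()
        )

    def test_combination_counts_match_bruteforce(self, toy_genome, toy_genes):
        rng = np.random.default_rng(21)
        peaks_df = random_interval_frame(rng, 500, toy_genome.chrom_sizes, max_len=300)
        peaks = IntervalSet.from_dataframe(peaks_df, chrom_sizes=toy_genome.chrom_sizes)
        cats = rc.categorize_peaks(peaks, toy_genes, toy_genome.repeats)

        feature_df = []
        for name, ivs in [
            ("TSS", toy_genes.tss_windows()),
            ("exon", toy_genes.exon_intervals()),
            ("intron", toy_genes.intron_intervals()),
            ("repeat", toy_genome.repeats.instances),
        ]:
            d = ivs.to_dataframe()
            d["label"] = name
            feature_df.append(d)
        feature_df = pd.concat(feature_df, ignore_index=True)
        brute = brute_per_query_label_membership(
            peaks.to_dataframe(), feature_df, "label"
        )
        for cat in ["TSS", "exon", "intron", "repeat"]:
            np.testing.assert_array_equal(
                cats[cat].to_numpy(), brute[cat].to_numpy(), err_msg=cat
            )
        combos = category_combinations(cats)
        assert combos.sum() == len(peaks)


class TestBootstrapEnrichment:
    def test_bootstrap_sets_match_count_and_length_multiset(self, toy_genome):
        rng = np.random.default_rng(0)
        lengths = rng.integers(100, 1000, size=200)
        chroms, starts, ends = random_matched_regions(
            lengths, toy_genome.chrom_sizes, rng, n_sets=5
        )
        assert len(starts) == 5 * 200
        for b in range(5):
            sl = slice(b * 200, (b + 1) * 200)
            assert sorted(ends[sl] - starts[sl]) == sorted(lengths)

    def test_regions_fit_their_chromosome(self, toy_genome):
        rng = np.random.default_rng(1)
        lengths = np.full(500, 150_000)  # fits chr1 only
        chroms, starts, ends = random_matched_regions(
            lengths, toy_genome.chrom_sizes, rng
        )
        assert set(chroms.astype(str)) == {"chr1"}
        assert (starts >= 0).all()
        assert (ends <= toy_genome.chrom_sizes["chr1"]).all()

    def test_region_longer_than_every_chromosome_rejected(self, toy_genome):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="exceeds"):
            random_matched_regions(
                np.array([10**7]), toy_genome.chrom_sizes, rng
            )

    def test_null_mean_matches_analytic_hit_probability(self):
        """Single family on a single chromosome: bootstrap hit rate equals
        the exact random-placement probability."""
        cfg = rc.GenomeConfig(
            seed=31,
            chrom_lengths=[1_000_000],
            repeat_catalog=[
                rc.RepeatSpec("fam", "FAM", "CLS", 2000, target_fraction=0.10)
            ],
        )
        g = rc.simulate_genome(cfg)
        rng = np.random.default_rng(5)
        n_peaks, peak_len, n_boot = 200, 300, 1000
        starts = rng.integers(0, 1_000_000 - peak_len, size=n_peaks)
        peaks = IntervalSet(
            ["chr1"] * n_peaks, starts, starts + peak_len,
            chrom_sizes=g.chrom_sizes,
        )
        res = rc.bootstrap_repeat_enrichment(
            peaks, g.repeats, g.chrom_sizes, n_boot=n_boot, seed=6,
            group_key="repeat_family",
        )
        merged = g.repeats.merged_group("repeat_family", "FAM")
        p_hit = random_region_hit_probability(
            list(zip(merged.start, merged.end)), peak_len, 1_000_000
        )
        null_rate = res.loc["FAM", "null_mean"] / n_peaks
        mc_se = res.loc["FAM", "null_sd"] / n_peaks / np.sqrt(n_boot)
        assert abs(null_rate - p_hit) <= 3 * mc_se

    def test_planted_peaks_recovered(self, toy_genome):
        df = toy_genome.repeats.to_dataframe()
        inst = df[df["repeat_family"] == "ERVK"]
        rng = np.random.default_rng(9)
        rows = inst.sample(n=200, replace=True, random_state=1)
        starts = rows["start"].to_numpy() + rng.integers(0, 1500, size=200)
        peaks = IntervalSet(
            rows["chrom"].to_numpy(), starts, starts + 300,
            chrom_sizes=toy_genome.chrom_sizes,
        )
        res = rc.bootstrap_repeat_enrichment(
            peaks, toy_genome.repeats, toy_genome.chrom_sizes,
            n_boot=100, seed=10, group_key="repeat_family",
        )
        assert (
            res.loc["ERVK", "observed"]
            >= res.loc["ERVK", "null_mean"] + 3 * res.loc["ERVK", "null_sd"]
        )
        assert res.loc["ERVK", "z"] > 3

    def test_bootstrap_fed_back_as_observed_is_unremarkable(self, toy_genome):
        """Exchangeability: a random matched set scored against the null has
        |z| < 4 nearly always."""
        rng = np.random.default_rng(13)
        lengths = np.full(200, 300)
        label_arrays = _merged_label_arrays(toy_genome.repeats, "repeat_family")
        n_trials, n_boot = 1000, 500
        chroms, starts, ends = random_matched_regions(
            lengths, toy_genome.chrom_sizes, rng, n_sets=n_boot + n_trials
        )
        tallies = np.array(
            [
                tally_label_presence(
                    chroms[b * 200: (b + 1) * 200],
                    starts[b * 200: (b + 1) * 200],
                    ends[b * 200: (b + 1) * 200],
                    label_arrays,
                ).to_numpy()
                for b in range(n_boot + n_trials)
            ]
        )
        null = tallies[:n_boot]
        trials = tallies[n_boot:]
        z = (trials - null.mean(axis=0)) / null.std(axis=0, ddof=0)
        frac_ok = (np.abs(z) < 4).all(axis=1).mean()
        assert frac_ok >= 0.99

    def test_reproducible_under_seed(self, toy_genome):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 190_000, size=50)
        peaks = IntervalSet(["chr1"] * 50, starts, starts + 300)
        a = rc.bootstrap_repeat_enrichment(
            peaks, toy_genome.repeats, toy_genome.chrom_sizes, n_boot=50, seed=3
        )
        b = rc.bootstrap_repeat_enrichment(
            peaks, toy_genome.repeats, toy_genome.chrom_sizes, n_boot=50, seed=3
        )
        pd.testing.assert_frame_equal(a, b)
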