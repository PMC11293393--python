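"""Peak post-processing: enrichment filtering, feature-category assignment,
and the randomized-region bootstrap repeat-enrichment statistic.

The enrichment filter keeps a peak only when the depth-normalized
ChIP/input ratio exceeds a fold threshold in at least a given number of
replicates (defaults: > 1.2-fold in >= 3 replicates), with a pseudocount of
one fragment on both counts.

The bootstrap null draws sets of regions matching the observed peaks in
number and in their exact multiset of lengths, placed uniformly on the
genome (chromosome chosen with probability proportional to its length among
those the region fits, start uniform so the region fits). Overlaps per
repeat label use presence counting — one peak hitting several instances of
a label contributes one — so observed and null live on the same scale. The
reported spread is the SD across bootstrap sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import FragmentSet, GeneAnnotation, RepeatAnnotation
from .intervals import IntervalSet, count_overlaps_starts_ends


@dataclass
class PeakTable:
    """Peaks with summits and per-replicate ChIP/input fragment counts."""

    peaks: pd.DataFrame  # chrom, start, end, summit (absolute, 0-based)
    chip_counts: pd.DataFrame  # peaks x replicates
    input_counts: pd.DataFrame
    chip_libsizes: pd.Series
    input_libsizes: pd.Series

    def __post_init__(self) -> None:
        bad = (self.peaks["summit"] < self.peaks["start"]) | (
            self.peaks["summit"] >= self.peaks["end"]
        )
        if bad.any():
            raise ValueError(f"summit outside peak at row(s) {list(bad[bad].index)}")
        for df in (self.chip_counts, self.input_counts):
            if (df.to_numpy() < 0).any():
                raise ValueError("negative fragment count")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def n_replicates(self) -> int:
        return self.chip_counts.shape[1]

    def interval_set(self, chrom_sizes: dict[str, int] | None = None) -> IntervalSet:
        return IntervalSet.from_dataframe(self.peaks, chrom_sizes=chrom_sizes)

    def subset(self, mask) -> "PeakTable":
        mask = np.asarray(mask)
        return PeakTable(
            peaks=self.peaks.loc[mask].reset_index(drop=True),
            chip_counts=self.chip_counts.loc[mask].reset_index(drop=True),
            input_counts=self.input_counts.loc[mask].reset_index(drop=True),
            chip_libsizes=self.chip_libsizes,
            input_libsizes=self.input_libsizes,
        )


def build_peak_table(
    peaks: pd.DataFrame,
    chip: list[FragmentSet],
    input_: list[FragmentSet],
    chrom_sizes: dict[str, int] | None = None,
) -> PeakTable:
    """Count each replicate's fragments over every peak."""
    if len(chip) != len(input_):
        raise ValueError("need one input replicate per ChIP replicate")
    ivs = IntervalSet.from_dataframe(peaks, chrom_sizes=chrom_sizes)
    # counts come back in the set's sorted order; realign to the input rows
    inverse = np.argsort(ivs._order)

    def count_all(sets: list[FragmentSet]) -> tuple[pd.DataFrame, pd.Series]:
        cols, libs = {}, {}
        for fs in sets:
            cols[fs.sample_id] = fs.fragments.count_overlaps(ivs)[inverse]
            libs[fs.sample_id] = fs.library_size
        return pd.DataFrame(cols), pd.Series(libs)

    chip_counts, chip_libs = count_all(chip)
    input_counts, input_libs = count_all(input_)
    return PeakTable(
        peaks=peaks.reset_index(drop=True),
        chip_counts=chip_counts,
        input_counts=input_counts,
        chip_libsizes=chip_libs,
        input_libsizes=input_libs,
    )


def replicate_fold_ratios(table: PeakTable) -> pd.DataFrame:
    """Depth-normalized ChIP/input ratio per peak per replicate pair.

    Replicates are paired positionally; a pseudocount of 1 fragment is
    added to both the ChIP and the input count before depth normalization.
    """
    if (table.chip_libsizes <= 0).any() or (table.input_libsizes <= 0).any():
        raise ValueError("zero library size")
    chip = table.chip_counts.to_numpy(dtype=float) + 1.0
    inp = table.input_counts.to_numpy(dtype=float) + 1.0
    chip_rate = chip / table.chip_libsizes.to_numpy()
    inp_rate = inp / table.input_libsizes.to_numpy()
    return pd.DataFrame(
        chip_rate / inp_rate,
        columns=[f"rep{i + 1}" for i in range(table.n_replicates)],
    )


def filter_enriched_peaks(
    table: PeakTable, min_fold: float = 1.2, min_reps: int = 3
) -> PeakTable:
    """Keep peaks enriched strictly > min_fold over input in >= min_reps
    replicates."""
    if table.n_replicates < min_reps:
        raise ValueError(
            f"{table.n_replicates} replicate(s) present, {min_reps} required"
        )
    ratios = replicate_fold_ratios(table)
    n_pass = (ratios.to_numpy() > min_fold).sum(axis=1)
    return table.subset(n_pass >= min_reps)


# ---------------------------------------------------------------- categories

CATEGORIES = ("TSS", "exon", "intron", "repeat")


def categorize_peaks(
    peaks: IntervalSet,
    genes: GeneAnnotation,
    repeats: RepeatAnnotation,
    tss_upstream: int = 300,
) -> pd.DataFrame:
    """Boolean membership of each peak in TSS/exon/intron/repeat classes.

    The TSS window covers the ``tss_upstream`` bases 5' of each TSS,
    strand-aware. Membership is non-exclusive (Upset semantics); a peak in
    no class is intergenic. Rows follow the peak set's sorted order.
    """
    feature_sets = {
        "TSS": genes.tss_windows(upstream=tss_upstream),
        "exon": genes.exon_intervals(),
        "intron": genes.intron_intervals(),
        "repeat": repeats.instances,
    }
    out = {}
    for name, ivs in feature_sets.items():
        out[name] = (
            ivs.merge().overlaps_any(peaks) if len(ivs) else np.zeros(len(peaks), bool)
        )
    df = pd.DataFrame(out)
    df["intergenic"] = ~df[list(CATEGORIES)].any(axis=1)
    return df


def category_combinations(matrix: pd.DataFrame) -> pd.Series:
    """Upset-style counts of each observed category combination."""
    cols = [c for c in matrix.columns if c != "intergenic"]
    keys = matrix[cols].apply(
        lambda row: "+".join([c for c in cols if row[c]]) or "intergenic", axis=1
    )
    return keys.value_counts()


# ----------------------------------------------------------------- bootstrap

def _merged_label_arrays(
    repeats: RepeatAnnotation, group_key: str
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """label -> chrom -> (sorted starts, sorted ends) of merged intervals."""
    out = {}
    for g in repeats.groups(group_key):
        merged = repeats.merged_group(group_key, g)
        per_chrom = {}
        for c, sl in merged.by_chrom().items():
            per_chrom[c] = (merged.start[sl], merged.end[sl])
        out[g] = per_chrom
    return out


def tally_label_presence(
    chroms: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    label_arrays: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]],
) -> pd.Series:
    """Per label: number of regions overlapping >= 1 merged interval."""
    tallies = {}
    order = np.argsort(chroms.astype(str), kind="stable")
    chroms_s = chroms[order].astype(str)
    starts_s = starts[order]
    ends_s = ends[order]
    boundaries = np.flatnonzero(chroms_s[1:] != chroms_s[:-1]) + 1
    slices = list(zip(np.r_[0, boundaries], np.r_[boundaries, len(chroms_s)]))
    for lab, per_chrom in label_arrays.items():
        hit = 0
        for lo, hi in slices:
            arrs = per_chrom.get(chroms_s[lo])
            if arrs is None:
                continue
            counts = count_overlaps_starts_ends(
                arrs[0], arrs[1], starts_s[lo:hi], ends_s[lo:hi]
            )
            hit += int((counts > 0).sum())
        tallies[lab] = hit
    return pd.Series(tallies, dtype=np.int64)


def random_matched_regions(
    lengths: np.ndarray,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
    n_sets: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniformly placed regions matching a length multiset, ``n_sets`` times.

    Returns flat (chrom, start, end) arrays of length ``n_sets * len(lengths)``
    laid out set-by-set. Chromosome is chosen with probability proportional
    to length among chromosomes the region fits; start uniform in
    ``[0, chrom_len - L]``.
    """
    names = np.array(list(chrom_sizes), dtype=object)
    clens = np.array([chrom_sizes[c] for c in names], dtype=np.int64)
    if lengths.max() > clens.max():
        raise ValueError(
            f"region length {int(lengths.max())} exceeds every chromosome"
        )
    total = n_sets * len(lengths)
    all_lengths = np.tile(lengths, n_sets)
    chrom_idx = np.empty(total, dtype=np.int64)
    if lengths.max() <= clens.min():
        p = clens / clens.sum()
        chrom_idx[:] = rng.choice(len(names), size=total, p=p)
    else:
        for L in np.unique(all_lengths):
            fit = clens >= L
            p = np.where(fit, clens, 0).astype(float)
            p /= p.sum()
            idx = np.flatnonzero(all_lengths == L)
            chrom_idx[idx] = rng.choice(len(names), size=len(idx), p=p)
    max_start = clens[chrom_idx] - all_lengths
    starts = (rng.random(total) * (max_start + 1)).astype(np.int64)
    return names[chrom_idx], starts, starts + all_lengths


def bootstrap_repeat_enrichment(
    peaks: IntervalSet,
    repeats: RepeatAnnotation,
    chrom_sizes: dict[str, int],
    n_boot: int = 100,
    seed: int = 0,
    group_key: str = "repeat_name",
) -> pd.DataFrame:
    """Observed vs randomized-region repeat overlap per label.

    Returns one row per repeat label: observed (peaks hitting the label),
    null_mean and null_sd (across ``n_boot`` matched random sets), empirical
    z = (observed - null_mean) / null_sd, fold = observed / null_mean (NaN
    when the null mean is zero, flagged in ``fold_defined``).
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    label_arrays = _merged_label_arrays(repeats, group_key)
    observed = tally_label_presence(peaks.chrom, peaks.start, peaks.end, label_arrays)

    rng = np.random.default_rng(seed)
    lengths = peaks.lengths()
    n = len(peaks)
    chroms, starts, ends = random_matched_regions(
        lengths, chrom_sizes, rng, n_sets=n_boot
    )
    null = np.zeros((n_boot, len(observed)), dtype=np.int64)
    for b in range(n_boot):
        sl = slice(b * n, (b + 1) * n)
        null[b] = tally_label_presence(
            chroms[sl], starts[sl], ends[sl], label_arrays
        ).reindex(observed.index).to_numpy()
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed.to_numpy() - null_mean) / null_sd
        fold = observed.to_numpy() / null_mean
    return pd.DataFrame(
        {
            "label": observed.index,
            "observed": observed.to_numpy(),
            "null_mean": null_mean,
            "null_sd": null_sd,
            "n_boot": n_boot,
            "z": z,
            "fold": np.where(null_mean > 0, fold, np.nan),
            "fold_defined": null_mean > 0,
        }
    ).set_index("label")
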