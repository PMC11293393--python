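"""Per-repeat read summation, cpm normalization, and binned signal.

Counting is fragment-level: a paired-end fragment overlapping a feature by
at least one base counts once. A fragment spanning two instances of the
same repeat group still counts once for that group (dedup per group per
fragment); a fragment bridging instances of two different groups counts for
both.

Normalization follows the cpm-with-prior convention: the pseudocount is
shared across samples on the depth scale, so equal counts at equal depth
give equal normalized values regardless of the prior. The denominator is
either the sample's genome library size or its exogenous spike-in total —
the latter is what makes global binding changes measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import FragmentSet, RepeatAnnotation
from .intervals import IntervalSet


@dataclass
class CountMatrix:
    """Feature x sample integer counts with per-sample denominators."""

    counts: pd.DataFrame  # features x samples
    library_size: pd.Series  # per sample
    spikein_size: pd.Series  # per sample
    group_key: str = "feature"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        for s in (self.library_size, self.spikein_size):
            missing = [c for c in self.counts.columns if c not in s.index]
            if missing:
                raise ValueError(f"missing denominators for samples {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def denominators(self, mode: str) -> pd.Series:
        if mode == "library_size":
            return self.library_size[self.counts.columns].astype(float)
        if mode == "spikein":
            s = self.spikein_size[self.counts.columns].astype(float)
            zero = s[s <= 0]
            if len(zero):
                raise ValueError(
                    f"spikein mode with spikein_size = 0 for sample(s) "
                    f"{list(zero.index)}"
                )
            return s
        raise ValueError("mode must be 'library_size' or 'spikein'")


def sum_reads_per_repeat(
    fragment_sets: list[FragmentSet] | FragmentSet,
    repeats: RepeatAnnotation,
    group_key: str = "repeat_name",
) -> CountMatrix:
    """Fragment counts per repeat group per sample.

    A fragment increments a group once if it overlaps >= 1 merged base of
    that group; overlapping instances of the same group never double-count.
    """
    if isinstance(fragment_sets, FragmentSet):
        fragment_sets = [fragment_sets]
    if len(repeats) == 0:
        raise ValueError("empty repeat annotation")
    groups = repeats.groups(group_key)
    data = {}
    lib, spike = {}, {}
    for fs in fragment_sets:
        col = np.zeros(len(groups), dtype=np.int64)
        for gi, g in enumerate(groups):
            merged = repeats.merged_group(group_key, g)
            col[gi] = int(merged.overlaps_any(fs.fragments).sum())
        data[fs.sample_id] = col
        lib[fs.sample_id] = fs.library_size
        spike[fs.sample_id] = fs.spikein_size
    counts = pd.DataFrame(data, index=groups)
    return CountMatrix(
        counts=counts,
        library_size=pd.Series(lib),
        spikein_size=pd.Series(spike),
        group_key=group_key,
    )


def normalize_counts(
    matrix: CountMatrix, mode: str = "library_size", prior_count: float = 3.0
) -> pd.DataFrame:
    """Counts-per-million with a depth-scaled prior.

    value_ij = (count_ij + prior * s_j / mean(s)) / s_j * 1e6, where s_j is
    the chosen denominator. Scaling the prior by relative depth makes equal
    counts at equal depth map to equal values and keeps zeros finite.
    """
    s = matrix.denominators(mode)
    prior_per_sample = prior_count * s / s.mean()
    return (matrix.counts + prior_per_sample) / s * 1e6


@dataclass
class BinnedSignal:
    """Anchor x bin normalized signal around summits.

    ``matrix`` rows follow ``row_order`` (descending row mean — waterfall
    layout); bins outside the chromosome are NaN (absent, not zero).
    """

    matrix: np.ndarray  # anchors x bins, cpm
    bin_width: int
    flank: int
    row_order: np.ndarray  # anchor indices, waterfall order
    anchor_index: np.ndarray  # original anchor index per row

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def metaplot(self) -> pd.DataFrame:
        """Column mean and SD across anchors (NaN-aware)."""
        center = (np.arange(self.n_bins) + 0.5) * self.bin_width - self.flank
        return pd.DataFrame(
            {
                "bin_center": center,
                "mean": np.nanmean(self.matrix, axis=0),
                "sd": np.nanstd(self.matrix, axis=0, ddof=0),
            }
        )


def _per_chrom_sorted(fragments: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for c, sl in fragments.by_chrom().items():
        out[c] = (np.sort(fragments.start[sl]), np.sort(fragments.end[sl]))
    return out


def signal_matrix(
    fragments: FragmentSet,
    anchors: IntervalSet,
    flank: int = 3000,
    bin_width: int = 50,
    chrom_sizes: dict[str, int] | None = None,
) -> BinnedSignal:
    """Fragment counts in fixed bins around anchor midpoints, cpm-scaled.

    Each anchor contributes one row covering [midpoint - flank, midpoint +
    flank) split into 2*flank/bin_width bins; a fragment counts in every bin
    it overlaps. Rows are ordered by descending mean for waterfall display.
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin_width")
    n_bins = 2 * flank // bin_width
    sizes = chrom_sizes or fragments.fragments.chrom_sizes or {}
    frags = _per_chrom_sorted(fragments.fragments)
    mat = np.full((len(anchors), n_bins), np.nan)
    mids = (anchors.start + anchors.end) // 2
    scale = 1e6 / fragments.library_size
    offsets = np.arange(n_bins + 1) * bin_width
    for i in range(len(anchors)):
        c = str(anchors.chrom[i])
        win_start = int(mids[i]) - flank
        edges = win_start + offsets
        clen = sizes.get(c, np.inf)
        valid = (edges[:-1] >= 0) & (edges[1:] <= clen)
        if c not in frags:
            mat[i, valid] = 0.0
            continue
        starts_sorted, ends_sorted = frags[c]
        n_start_lt = np.searchsorted(starts_sorted, edges[1:], side="left")
        n_end_le = np.searchsorted(ends_sorted, edges[:-1], side="right")
        row = (n_start_lt - n_end_le).astype(float) * scale
        row[~valid] = np.nan
        mat[i] = row
    row_means = np.where(
        np.all(np.isnan(mat), axis=1), -np.inf, np.nanmean(mat, axis=1)
    )
    order = np.argsort(-row_means, kind="stable")
    return BinnedSignal(
        matrix=mat[order],
        bin_width=bin_width,
        flank=flank,
        row_order=order,
        anchor_index=order,
    )


def genome_binned_signal(
    fragment_sets: list[FragmentSet] | FragmentSet,
    chrom_sizes: dict[str, int],
    bin_width: int = 1000,
) -> pd.DataFrame:
    """cpm per fixed genomic bin per sample (bedGraph-style long table).

    The genome is tiled with non-overlapping bins (last bin truncated); a
    fragment is assigned to every bin it overlaps.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(fragment_sets, FragmentSet):
        fragment_sets = [fragment_sets]
    bins = []
    for c, length in chrom_sizes.items():
        edges = np.arange(0, length, bin_width)
        bins.append(
            pd.DataFrame(
                {"chrom": c, "start": edges, "end": np.minimum(edges + bin_width, length)}
            )
        )
    out = pd.concat(bins, ignore_index=True)
    offsets = {}
    pos = 0
    for c, length in chrom_sizes.items():
        offsets[c] = pos
        pos += int(np.ceil(length / bin_width))
    total_bins = pos
    for fs in fragment_sets:
        counts = np.zeros(total_bins, dtype=np.int64)
        f = fs.fragments
        chroms = f.chrom.astype(str)
        first = f.start // bin_width
        last = (f.end - 1) // bin_width
        base = np.array([offsets[c] for c in chroms], dtype=np.int64)
        lo = base + first
        hi = base + last
        # most fragments span one or two bins; sweep the remaining spans
        cur = lo.copy()
        active = cur <= hi
        while active.any():
            np.add.at(counts, cur[active], 1)
            cur = cur + 1
            active = cur <= hi
        out[fs.sample_id] = counts / fs.library_size * 1e6
    return out
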