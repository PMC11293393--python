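"""Genomic interval containers and the overlap engine.

All coordinates are 0-based half-open ``[start, end)`` on a named sequence.
Conversions from 1-based inclusive formats (GTF, RepeatMasker .out) happen
only at the I/O boundary (:mod:`retrochip.io`).

Overlap queries are answered with sorted numpy arrays and ``searchsorted``:
for a query ``[s, e)`` the number of subject intervals sharing at least one
base equals ``(# subjects with start < e) - (# subjects with end <= s)``,
because ``end <= s`` implies ``start < e``. Presence against a label is a
membership test against the merged (disjoint) intervals of that label.
Both paths are verified exactly against an exhaustive pairwise oracle in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of intervals with vectorized overlap queries.

    Intervals are stored as parallel numpy arrays sorted by
    ``(chrom, start, end)``. An optional ``chrom_sizes`` table is enforced
    on construction: every chromosome must be known and every interval must
    fit inside its chromosome.
    """

    def __init__(
        self,
        chrom,
        start,
        end,
        strand=None,
        chrom_sizes: dict[str, int] | None = None,
    ) -> None:
        chrom = np.asarray(chrom, dtype=object)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if not (len(chrom) == len(start) == len(end)):
            raise ValueError("chrom, start, end must have equal length")
        if strand is None:
            strand = np.full(len(chrom), ".", dtype=object)
        else:
            strand = np.asarray(strand, dtype=object)
        if np.any(start < 0) or np.any(start >= end):
            bad = np.flatnonzero((start < 0) | (start >= end))[0]
            raise ValueError(
                f"invalid interval [{start[bad]}, {end[bad]}) on {chrom[bad]}"
            )
        order = np.lexsort((end, start, _chrom_rank(chrom)))
        self.chrom = chrom[order]
        self.start = start[order]
        self.end = end[order]
        self.strand = strand[order]
        self._order = order  # original index -> sorted position mapping
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes is not None else None
        if self.chrom_sizes is not None:
            self._validate_against_sizes()
        self._by_chrom: dict[str, slice] | None = None

    def _validate_against_sizes(self) -> None:
        sizes = self.chrom_sizes
        for c in np.unique(self.chrom.astype(str)):
            if c not in sizes:
                raise KeyError(f"unknown chromosome {c!r} (not in chrom.sizes)")
        if len(self) > 0:
            lens = np.array([sizes[c] for c in self.chrom], dtype=np.int64)
            if np.any(self.end > lens):
                bad = np.flatnonzero(self.end > lens)[0]
                raise ValueError(
                    f"interval [{self.start[bad]}, {self.end[bad]}) exceeds "
                    f"{self.chrom[bad]} length {lens[bad]}"
                )

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self):
        for c, s, e, st in zip(self.chrom, self.start, self.end, self.strand):
            yield GenomicInterval(str(c), int(s), int(e), str(st))

    def __getitem__(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            str(self.chrom[i]), int(self.start[i]), int(self.end[i]), str(self.strand[i])
        )

    @classmethod
    def from_intervals(
        cls, intervals, chrom_sizes: dict[str, int] | None = None
    ) -> "IntervalSet":
        ivs = list(intervals)
        return cls(
            [iv.chrom for iv in ivs],
            [iv.start for iv in ivs],
            [iv.end for iv in ivs],
            [iv.strand for iv in ivs],
            chrom_sizes=chrom_sizes,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, chrom_sizes: dict[str, int] | None = None
    ) -> "IntervalSet":
        strand = df["strand"] if "strand" in df.columns else None
        return cls(df["chrom"], df["start"], df["end"], strand, chrom_sizes=chrom_sizes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom.astype(str),
                "start": self.start,
                "end": self.end,
                "strand": self.strand.astype(str),
            }
        )

    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def subset(self, mask_or_index) -> "IntervalSet":
        idx = np.asarray(mask_or_index)
        return IntervalSet(
            self.chrom[idx],
            self.start[idx],
            self.end[idx],
            self.strand[idx],
            chrom_sizes=self.chrom_sizes,
        )

    def by_chrom(self) -> dict[str, slice]:
        """Slices of the sorted arrays per chromosome."""
        if self._by_chrom is None:
            out: dict[str, slice] = {}
            chroms = self.chrom.astype(str)
            if len(chroms):
                boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
                starts = np.concatenate([[0], boundaries])
                ends = np.concatenate([boundaries, [len(chroms)]])
                for s, e in zip(starts, ends):
                    out[chroms[s]] = slice(int(s), int(e))
            self._by_chrom = out
        return self._by_chrom

    def merge(self) -> "IntervalSet":
        """Union of intervals: merged, disjoint, strand-agnostic."""
        chroms, starts, ends = [], [], []
        for c, sl in self.by_chrom().items():
            s = self.start[sl]
            e = self.end[sl]
            # already sorted by start within chromosome
            keep_s = [int(s[0])]
            keep_e = [int(e[0])]
            for a, b in zip(s[1:], e[1:]):
                if a <= keep_e[-1]:
                    keep_e[-1] = max(keep_e[-1], int(b))
                else:
                    keep_s.append(int(a))
                    keep_e.append(int(b))
            chroms.extend([c] * len(keep_s))
            starts.extend(keep_s)
            ends.extend(keep_e)
        return IntervalSet(chroms, starts, ends, chrom_sizes=self.chrom_sizes)

    def complement(self, chrom_sizes: dict[str, int] | None = None) -> "IntervalSet":
        """Genomic gaps: every base of every chromosome not covered here."""
        sizes = chrom_sizes or self.chrom_sizes
        if sizes is None:
            raise ValueError("complement requires a chromosome-size table")
        merged = self.merge()
        per_chrom = merged.by_chrom()
        chroms, starts, ends = [], [], []
        for c, length in sizes.items():
            cursor = 0
            sl = per_chrom.get(c)
            if sl is not None:
                for s, e in zip(merged.start[sl], merged.end[sl]):
                    if s > cursor:
                        chroms.append(c)
                        starts.append(cursor)
                        ends.append(int(s))
                    cursor = max(cursor, int(e))
            if cursor < length:
                chroms.append(c)
                starts.append(cursor)
                ends.append(length)
        return IntervalSet(chroms, starts, ends, chrom_sizes=sizes)

    def total_bases(self) -> int:
        """Number of distinct genomic bases covered (after merging)."""
        m = self.merge()
        return int(m.lengths().sum())

    def count_overlaps(self, query: "IntervalSet") -> np.ndarray:
        """Per-query count of intervals in self sharing >= 1 base.

        Strand is ignored. Returns counts aligned with the query's sorted
        order (the order ``query`` iterates in).
        """
        _check_shared_chroms(query, self)
        counts = np.zeros(len(query), dtype=np.int64)
        mine = self.by_chrom()
        for c, sl in query.by_chrom().items():
            if c not in mine:
                continue
            msl = mine[c]
            starts_sorted = np.sort(self.start[msl])
            ends_sorted = np.sort(self.end[msl])
            qs = query.start[sl]
            qe = query.end[sl]
            n_start_lt = np.searchsorted(starts_sorted, qe, side="left")
            n_end_le = np.searchsorted(ends_sorted, qs, side="right")
            counts[sl] = n_start_lt - n_end_le
        return counts

    def overlaps_any(self, query: "IntervalSet") -> np.ndarray:
        """Boolean per query interval: does it hit >= 1 interval in self."""
        return self.count_overlaps(query) > 0


def count_overlaps_starts_ends(
    starts_sorted: np.ndarray, ends_sorted: np.ndarray, qs: np.ndarray, qe: np.ndarray
) -> np.ndarray:
    """Overlap counts of queries against pre-sorted subject start/end arrays.

    Low-level single-chromosome kernel used by the bootstrap null, where the
    same subject set is queried hundreds of times.
    """
    return np.searchsorted(starts_sorted, qe, side="left") - np.searchsorted(
        ends_sorted, qs, side="right"
    )


def _chrom_rank(chrom: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(chrom.astype(str), return_inverse=True)
    return inv


def _check_shared_chroms(query: IntervalSet, subject: IntervalSet) -> None:
    qs, ss = query.chrom_sizes, subject.chrom_sizes
    if qs is not None and ss is not None and qs != ss:
        raise ValueError("query and subject use different chromosome-size tables")


def overlap_count(
    query: IntervalSet,
    subject: IntervalSet,
    subject_labels: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.Series | None]:
    """Overlap tallies between two interval sets.

    Returns ``(per_query, per_label)``: ``per_query[i]`` is the number of
    subject intervals overlapping query ``i`` (>= 1 shared base, strand
    ignored); ``per_label[lab]`` is the number of queries hitting at least
    one subject carrying label ``lab`` (presence counting — a query spanning
    several same-label instances contributes once). ``per_label`` is None
    when no labels are given.
    """
    per_query = subject.count_overlaps(query)
    per_label = None
    if subject_labels is not None:
        labels = np.asarray(subject_labels, dtype=object)
        if len(labels) != len(subject):
            raise ValueError("one label per subject interval required")
        # labels arrive in the subject's construction order; realign
        labels = labels[subject._order]
        tallies = {}
        for lab in pd.unique(labels):
            sub = subject.subset(labels == lab).merge()
            tallies[lab] = int(sub.overlaps_any(query).sum())
        per_label = pd.Series(tallies, dtype=np.int64)
    return per_query, per_label


def resize_around_summit(
    peak: GenomicInterval,
    summit: int,
    width: int,
    chrom_sizes: dict[str, int],
) -> GenomicInterval:
    """Resize a peak to a fixed width centered on its summit.

    The window is ``[summit - floor(width/2), summit + ceil(width/2))``. At a
    chromosome edge the window is shifted inward so the length is preserved;
    a chromosome shorter than ``width`` is an error.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if not (peak.start <= summit < peak.end):
        raise ValueError(
            f"summit {summit} outside peak [{peak.start}, {peak.end})"
        )
    chrom_len = chrom_sizes.get(peak.chrom)
    if chrom_len is None:
        raise KeyError(f"unknown chromosome {peak.chrom!r}")
    if chrom_len < width:
        raise ValueError(
            f"chromosome {peak.chrom} (length {chrom_len}) shorter than width {width}"
        )
    start = summit - width // 2
    end = summit + (width - width // 2)
    if start < 0:
        start, end = 0, width
    elif end > chrom_len:
        start, end = chrom_len - width, chrom_len
    return GenomicInterval(peak.chrom, start, end, peak.strand)
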