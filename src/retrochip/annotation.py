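"""Repeat and gene annotation containers and the fragment set.

``RepeatAnnotation`` mirrors RepeatMasker's three-level taxonomy: every
instance carries ``repeat_name`` (e.g. IAPEz-int), ``repeat_family`` (e.g.
ERVK) and ``repeat_class`` (e.g. LTR). ``GeneAnnotation`` holds transcripts
with strand-aware TSSs plus exon/intron structure. ``FragmentSet`` is one
sample's aligned fragments (paired-end mates collapsed to a single span)
together with its two size denominators: total genome fragments and total
exogenous spike-in fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet

REPEAT_LEVELS = ("repeat_name", "repeat_family", "repeat_class")


class RepeatAnnotation:
    """Repeat instances with name/family/class labels per instance.

    Constructed from one table with columns chrom, start, end, optional
    strand, repeat_name, repeat_family, repeat_class; rows are re-sorted by
    coordinate with labels kept aligned.
    """

    def __init__(
        self, table: pd.DataFrame, chrom_sizes: dict[str, int] | None = None
    ) -> None:
        for col in REPEAT_LEVELS:
            if col not in table.columns:
                raise ValueError(f"table must include column {col!r}")
            vals = table[col].astype(str)
            if (vals == "").any() or vals.isna().any():
                raise ValueError(f"empty {col} label")
        table = table.reset_index(drop=True)
        self.instances = IntervalSet.from_dataframe(table, chrom_sizes=chrom_sizes)
        self.labels = (
            table[list(REPEAT_LEVELS)]
            .iloc[self.instances._order]
            .reset_index(drop=True)
            .astype(str)
        )
        self._merged_cache: dict[tuple[str, str], IntervalSet] = {}

    def __len__(self) -> int:
        return len(self.instances)

    def to_dataframe(self) -> pd.DataFrame:
        df = self.instances.to_dataframe()
        return pd.concat([df, self.labels], axis=1)

    def groups(self, group_key: str) -> list[str]:
        if group_key not in REPEAT_LEVELS:
            raise ValueError(f"group_key must be one of {REPEAT_LEVELS}")
        return list(pd.unique(self.labels[group_key]))

    def merged_group(self, group_key: str, value: str) -> IntervalSet:
        """Merged (disjoint) intervals of one repeat group; cached."""
        key = (group_key, value)
        if key not in self._merged_cache:
            mask = (self.labels[group_key] == value).to_numpy()
            if not mask.any():
                known = self.groups(group_key)
                raise KeyError(
                    f"{value!r} not a known {group_key}; known: {known}"
                )
            self._merged_cache[key] = self.instances.subset(mask).merge()
        return self._merged_cache[key]

    def group_bases(self, group_key: str) -> pd.Series:
        """Distinct covered bases per group."""
        return pd.Series(
            {
                g: self.merged_group(group_key, g).total_bases()
                for g in self.groups(group_key)
            },
            dtype=np.int64,
        )


class GeneAnnotation:
    """Transcripts with TSSs and exon/intron intervals.

    ``transcripts`` columns: chrom, start, end, strand, transcript_id,
    gene_id. ``exons`` columns: chrom, start, end, strand, transcript_id.
    Intron intervals are the transcript span minus its exons.
    """

    def __init__(self, transcripts: pd.DataFrame, exons: pd.DataFrame,
                 chrom_sizes: dict[str, int] | None = None) -> None:
        if (~transcripts["strand"].isin(["+", "-"])).any():
            bad = transcripts.loc[~transcripts["strand"].isin(["+", "-"])]
            raise ValueError(
                f"transcript(s) without strand: {bad['transcript_id'].tolist()}"
            )
        self.transcripts = transcripts.reset_index(drop=True)
        self.exons = exons.reset_index(drop=True)
        self.chrom_sizes = chrom_sizes

    def tss_positions(self) -> pd.DataFrame:
        """Strand-aware TSS per transcript.

        For a plus-strand transcript the TSS is its start coordinate; for a
        minus-strand transcript it is its end coordinate (the half-open
        bound just past the first transcribed base).
        """
        t = self.transcripts
        tss = np.where(t["strand"] == "+", t["start"], t["end"])
        return pd.DataFrame(
            {
                "chrom": t["chrom"],
                "tss": tss,
                "strand": t["strand"],
                "transcript_id": t["transcript_id"],
            }
        )

    def tss_windows(self, upstream: int = 300) -> IntervalSet:
        """Promoter windows covering ``upstream`` bases 5' of each TSS.

        Plus strand: ``[tss - upstream, tss)``; minus strand: ``[tss,
        tss + upstream)``. Windows are clipped to chromosome bounds.
        """
        pos = self.tss_positions()
        start = np.where(pos["strand"] == "+", pos["tss"] - upstream, pos["tss"])
        end = start + upstream
        start = np.maximum(start, 0)
        if self.chrom_sizes is not None:
            lens = pos["chrom"].map(self.chrom_sizes).to_numpy()
            end = np.minimum(end, lens)
        keep = start < end
        return IntervalSet(
            pos["chrom"].to_numpy()[keep],
            start[keep],
            end[keep],
            pos["strand"].to_numpy()[keep],
            chrom_sizes=self.chrom_sizes,
        )

    def exon_intervals(self) -> IntervalSet:
        e = self.exons
        return IntervalSet(
            e["chrom"], e["start"], e["end"], e["strand"],
            chrom_sizes=self.chrom_sizes,
        )

    def intron_intervals(self) -> IntervalSet:
        """Transcript spans minus exons, per transcript."""
        chroms, starts, ends, strands = [], [], [], []
        exons_by_tx = {
            tx: grp for tx, grp in self.exons.groupby("transcript_id", sort=False)
        }
        for _, t in self.transcripts.iterrows():
            ex = exons_by_tx.get(t["transcript_id"])
            if ex is None:
                continue
            ex = ex.sort_values("start")
            cursor = int(t["start"])
            for _, row in ex.iterrows():
                if row["start"] > cursor:
                    chroms.append(t["chrom"])
                    starts.append(cursor)
                    ends.append(int(row["start"]))
                    strands.append(t["strand"])
                cursor = max(cursor, int(row["end"]))
            if cursor < int(t["end"]):
                chroms.append(t["chrom"])
                starts.append(cursor)
                ends.append(int(t["end"]))
                strands.append(t["strand"])
        return IntervalSet(chroms, starts, ends, strands, chrom_sizes=self.chrom_sizes)


def exclude_intronic_instances(
    repeats: RepeatAnnotation, genes: GeneAnnotation
) -> RepeatAnnotation:
    """Drop repeat instances overlapping any intron.

    Optional sensitivity filter for expression analyses: intron-resident
    repeats can soak up pre-mRNA signal from their host gene, so excluding
    them checks whether a differential call depends on them.
    """
    introns = genes.intron_intervals()
    if len(introns) == 0:
        return repeats
    keep = ~introns.merge().overlaps_any(repeats.instances)
    table = repeats.to_dataframe().loc[keep]
    return RepeatAnnotation(table, chrom_sizes=repeats.instances.chrom_sizes)


@dataclass
class FragmentSet:
    """Aligned fragments of one sample plus its size denominators.

    ``library_size`` is the total number of genome fragments sequenced for
    the sample (>= the number of fragments stored, which may be a subset);
    ``spikein_size`` is the total number of fragments from the exogenous
    spike-in chromatin, used as an alternative normalization denominator.
    """

    sample_id: str
    fragments: IntervalSet
    library_size: int
    spikein_size: int = 0

    def __post_init__(self) -> None:
        if self.library_size < len(self.fragments):
            raise ValueError(
                f"library_size {self.library_size} < fragment count "
                f"{len(self.fragments)} for {self.sample_id}"
            )
        if self.spikein_size < 0:
            raise ValueError("spikein_size must be >= 0")

    def __len__(self) -> int:
        return len(self.fragments)
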