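"""Readers and writers for the formats the pipeline touches.

Internal coordinates are always 0-based half-open. BED and narrowPeak are
already 0-based half-open on disk; GTF and RepeatMasker .out are 1-based
inclusive and converted on read (and back on write). FASTA goes through
Bio.SeqIO, GTF through pyranges, BAM through pysam.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import FragmentSet, GeneAnnotation, RepeatAnnotation
from .intervals import IntervalSet


class FormatError(ValueError):
    """A malformed line in an input file; carries line number and dialect."""

    def __init__(self, dialect: str, lineno: int, message: str) -> None:
        super().__init__(f"{dialect} line {lineno}: {message}")
        self.dialect = dialect
        self.lineno = lineno


# ---------------------------------------------------------------- chrom.sizes

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError("chromsizes", i, f"expected 2 columns, got {len(parts)}")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError:
                raise FormatError("chromsizes", i, f"non-integer size {parts[1]!r}")
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ------------------------------------------------------------------- BED

def read_bed(path, chrom_sizes: dict[str, int] | None = None) -> IntervalSet:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("bed", i, f"expected >= 3 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError("bed", i, "non-integer coordinates")
            strand = parts[5] if len(parts) >= 6 else "."
            rows.append((parts[0], start, end, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return IntervalSet.from_dataframe(df, chrom_sizes=chrom_sizes)


def write_bed(intervals: IntervalSet, path) -> None:
    df = intervals.to_dataframe()
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n")


# --------------------------------------------------------------- narrowPeak

NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "pvalue", "qvalue", "summit_offset",
]


def read_narrowpeak(path, chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """MACS2 narrowPeak as a table with an absolute ``summit`` column.

    The 10th column is the summit offset from ``start``; ``summit`` is the
    absolute 0-based summit position.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=NARROWPEAK_COLS, comment="#"
        )
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise FormatError("narrowpeak", 0, str(exc))
    if df["summit_offset"].isna().any():
        lineno = int(df["summit_offset"].isna().idxmax()) + 1
        raise FormatError("narrowpeak", lineno, "missing summit offset")
    df["summit"] = df["start"] + df["summit_offset"]
    bad = (df["summit"] < df["start"]) | (df["summit"] >= df["end"])
    if bad.any():
        raise FormatError(
            "narrowpeak", int(bad.idxmax()) + 1, "summit outside peak"
        )
    if chrom_sizes is not None:
        # constructing validates chroms and bounds
        IntervalSet.from_dataframe(df, chrom_sizes=chrom_sizes)
    return df


def write_narrowpeak(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "summit_offset" not in out.columns:
        out["summit_offset"] = out["summit"] - out["start"]
    for col, default in [
        ("name", "."), ("score", 0), ("strand", "."),
        ("signal", 0.0), ("pvalue", -1.0), ("qvalue", -1.0),
    ]:
        if col not in out.columns:
            out[col] = default
    out[NARROWPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------------- GTF

def read_gtf(path, chrom_sizes: dict[str, int] | None = None) -> GeneAnnotation:
    """Gene annotation from GTF (1-based inclusive on disk).

    pyranges performs the conversion to 0-based half-open.
    """
    import pyranges

    df = pyranges.read_gtf(str(path)).df
    df = df.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end",
                 "Strand": "strand", "Feature": "feature"}
    )
    df["chrom"] = df["chrom"].astype(str)
    df["strand"] = df["strand"].astype(str)
    tx = df[df["feature"] == "transcript"][
        ["chrom", "start", "end", "strand", "transcript_id", "gene_id"]
    ]
    ex = df[df["feature"] == "exon"][
        ["chrom", "start", "end", "strand", "transcript_id"]
    ]
    return GeneAnnotation(tx, ex, chrom_sizes=chrom_sizes)


def write_gtf(genes: GeneAnnotation, path, source: str = "retrochip") -> None:
    with open(path, "w") as fh:
        for _, t in genes.transcripts.iterrows():
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            ex = genes.exons[genes.exons["transcript_id"] == t.transcript_id]
            for _, e in ex.sort_values("start").iterrows():
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


# -------------------------------------------------------- RepeatMasker .out

_RMSK_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(
    path, chrom_sizes: dict[str, int] | None = None
) -> RepeatAnnotation:
    """RepeatMasker .out table (1-based inclusive) -> RepeatAnnotation."""
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("SW", "score")):
            continue  # the two header lines
        parts = stripped.split()
        if len(parts) < 13:
            raise FormatError(
                "repeatmasker_out", i, f"expected >= 13 fields, got {len(parts)}"
            )
        try:
            qbegin, qend = int(parts[5]), int(parts[6])
        except ValueError:
            raise FormatError("repeatmasker_out", i, "non-integer query coordinates")
        strand = "+" if parts[8] == "+" else "-"  # RepeatMasker uses 'C' for minus
        name = parts[9]
        clsfam = parts[10]
        if "/" in clsfam:
            rclass, rfamily = clsfam.split("/", 1)
        else:
            rclass, rfamily = clsfam, clsfam
        rows.append(
            (parts[4], qbegin - 1, qend, strand, name, rfamily, rclass)
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand",
                 "repeat_name", "repeat_family", "repeat_class"],
    )
    return RepeatAnnotation(df, chrom_sizes=chrom_sizes)


def write_repeatmasker_out(repeats: RepeatAnnotation, path) -> None:
    df = repeats.to_dataframe()
    with open(path, "w") as fh:
        fh.write(_RMSK_HEADER)
        for i, r in df.iterrows():
            strand = "C" if r.strand == "-" else "+"
            clsfam = (
                r.repeat_class
                if r.repeat_class == r.repeat_family
                else f"{r.repeat_class}/{r.repeat_family}"
            )
            fh.write(
                f"  100  0.0  0.0  0.0  {r.chrom}  {r.start + 1}  {r.end}  (0)  "
                f"{strand}  {r.repeat_name}  {clsfam}  1  {r.end - r.start}  (0)  "
                f"{i + 1}\n"
            )


# ------------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------- fragments

def write_fragments(fragset: FragmentSet, path) -> None:
    """Internal fragment TSV: header comments carry the size denominators."""
    with open(path, "w") as fh:
        fh.write(f"#sample_id={fragset.sample_id}\n")
        fh.write(f"#library_size={fragset.library_size}\n")
        fh.write(f"#spikein_size={fragset.spikein_size}\n")
        fh.write("chrom\tstart\tend\n")
        df = fragset.fragments.to_dataframe()
        df[["chrom", "start", "end"]].to_csv(fh, sep="\t", header=False, index=False)


def read_fragments(path, chrom_sizes: dict[str, int] | None = None) -> FragmentSet:
    meta: dict[str, str] = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].rstrip("\n").partition("=")
            meta[key] = val
        df = pd.read_csv(fh, sep="\t")
    for key in ("sample_id", "library_size", "spikein_size"):
        if key not in meta:
            raise FormatError("fragments", 1, f"missing #{key}= header")
    ivs = IntervalSet.from_dataframe(df, chrom_sizes=chrom_sizes)
    return FragmentSet(
        sample_id=meta["sample_id"],
        fragments=ivs,
        library_size=int(meta["library_size"]),
        spikein_size=int(meta["spikein_size"]),
    )


def fragments_from_bam(
    path,
    sample_id: str,
    spikein_size: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> FragmentSet:
    """Adapter: paired-end BAM/SAM -> FragmentSet.

    Proper pairs are collapsed to one fragment spanning both mates (taken
    from the leftmost mate's position and template length); unpaired reads
    contribute their own span. Secondary/supplementary alignments are
    skipped.
    """
    import pysam

    rows = []
    n_total = 0
    with pysam.AlignmentFile(str(path), "r") as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired:
                if not read.is_proper_pair:
                    continue
                if read.template_length <= 0:
                    continue  # count each pair once, from the leftmost mate
                rows.append(
                    (read.reference_name, read.reference_start,
                     read.reference_start + read.template_length)
                )
            else:
                rows.append(
                    (read.reference_name, read.reference_start, read.reference_end)
                )
            n_total += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    ivs = IntervalSet.from_dataframe(df, chrom_sizes=chrom_sizes)
    return FragmentSet(
        sample_id=sample_id,
        fragments=ivs,
        library_size=len(ivs),
        spikein_size=spikein_size,
    )


# --------------------------------------------------------------- dispatcher

_READERS = {
    "repeatmasker_out": read_repeatmasker_out,
    "gtf": read_gtf,
    "bed": read_bed,
    "narrowpeak": read_narrowpeak,
    "chromsizes": lambda path, chrom_sizes=None: read_chrom_sizes(path),
    "fasta": lambda path, chrom_sizes=None: read_fasta(path),
}


def read_annotation(path, dialect: str, chrom_sizes: dict[str, int] | None = None):
    """Read any supported annotation file into its typed object."""
    if dialect not in _READERS:
        raise ValueError(
            f"unknown dialect {dialect!r}; choose from {sorted(_READERS)}"
        )
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return _READERS[dialect](path, chrom_sizes=chrom_sizes)
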