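"""Stitched consensus models, ungapped read alignment, and coverage traces.

An LTR retrotransposon consensus is modeled as LTR + internal + LTR, the
arrangement of a full-length proviral copy, so reads from either terminal
repeat have a home at both ends of the model. Alignment is ungapped local
placement: exact k-mer seeds on both strands propose offsets, the full read
is scored at each proposed offset, and the best placement is reported when
its mismatch rate is acceptable. Ties go to the higher score, then the
leftmost consensus start, then the plus strand — a deterministic rule that
systematically favors the 5' copy of the two identical LTRs (the SD across
replicates does not hide this; see the methods note).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import FragmentSet, RepeatAnnotation
from .simulate import reverse_complement

VALID_BASES = set("ACGTN")


@dataclass
class ConsensusModel:
    """A named consensus sequence tiled by labeled segments."""

    name: str
    sequence: str
    segments: list[tuple[str, int, int]]  # (segment_name, start, end)

    def __post_init__(self) -> None:
        pos = 0
        for seg_name, s, e in self.segments:
            if s != pos or e <= s:
                raise ValueError(
                    f"segments must tile [0, length) without gaps; "
                    f"{seg_name} starts at {s}, expected {pos}"
                )
            pos = e
        if pos != len(self.sequence):
            raise ValueError("segments do not cover the full sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def segment_sequence(self, segment_name: str) -> str:
        for seg, s, e in self.segments:
            if seg == segment_name:
                return self.sequence[s:e]
        raise KeyError(segment_name)

    def segment_of(self, position: int) -> str:
        for seg, s, e in self.segments:
            if s <= position < e:
                return seg
        raise IndexError(position)


def _check_sequence(seq: str, what: str) -> str:
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{what} contains invalid characters {sorted(bad)}")
    return seq


def stitch_consensus(internal: str, ltr: str, name: str) -> ConsensusModel:
    """LTR + internal + LTR model of a full-length proviral copy."""
    internal = _check_sequence(internal, "internal")
    ltr = _check_sequence(ltr, "ltr")
    L, I = len(ltr), len(internal)
    return ConsensusModel(
        name=name,
        sequence=ltr + internal + ltr,
        segments=[("LTR_5p", 0, L), ("internal", L, L + I), ("LTR_3p", L + I, 2 * L + I)],
    )


def extract_repeat_fragments(
    fragments: FragmentSet,
    repeats: RepeatAnnotation,
    target_names: list[str],
    genome: dict[str, str],
) -> tuple[FragmentSet, list[str]]:
    """Fragments overlapping >= 1 instance of the target repeat names,
    paired with their genomic sequences."""
    known = set(repeats.groups("repeat_name"))
    missing = set(target_names) - known
    if missing:
        raise KeyError(
            f"unknown repeat_name(s) {sorted(missing)}; known: {sorted(known)}"
        )
    mask = repeats.labels["repeat_name"].isin(target_names).to_numpy()
    targets = repeats.instances.subset(mask).merge()
    keep = targets.overlaps_any(fragments.fragments)
    subset = fragments.fragments.subset(keep)
    seqs = [
        genome[str(subset.chrom[i])][subset.start[i]: subset.end[i]]
        for i in range(len(subset))
    ]
    return (
        FragmentSet(
            sample_id=fragments.sample_id,
            fragments=subset,
            library_size=fragments.library_size,
            spikein_size=fragments.spikein_size,
        ),
        seqs,
    )


@dataclass
class ConsensusAlignment:
    """One read's ungapped placement on a consensus model."""

    read_id: str
    consensus: str
    start: int
    end: int
    strand: str
    mismatches: int
    score: int


def _kmer_index(sequence: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sequence) - k + 1):
        index[sequence[i: i + k]].append(i)
    return index


def align_to_consensus(
    reads: list[str],
    model: ConsensusModel,
    seed_length: int = 15,
    max_mismatch_rate: float = 0.1,
    read_ids: list[str] | None = None,
) -> list[ConsensusAlignment | None]:
    """Best ungapped placement of each read on the model, both strands.

    Non-overlapping k-mer seeds propose candidate offsets; the whole read is
    scored (match +1, mismatch -1) at each offset where it fully fits. The
    exhaustive-offset optimum is guaranteed whenever the true placement
    contains an exact seed — always the case when the read has fewer than
    read_length / seed_length mismatches. Reads whose best placement
    exceeds ``max_mismatch_rate`` (or with no seed hit) come back as None.
    """
    if read_ids is None:
        read_ids = [f"read_{i}" for i in range(len(reads))]
    cons = model.sequence
    cons_arr = np.frombuffer(cons.encode(), dtype=np.uint8)
    index = _kmer_index(cons, seed_length)
    out: list[ConsensusAlignment | None] = []
    for rid, read in zip(read_ids, reads):
        read = read.upper()
        if seed_length > len(read):
            raise ValueError(
                f"seed_length {seed_length} > read length {len(read)} ({rid})"
            )
        if len(read) > len(cons):
            raise ValueError(f"read {rid} longer than consensus")
        best = None  # (score, start, strand_rank, mismatches, strand)
        for strand, seq in (("+", read), ("-", reverse_complement(read))):
            seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            n = len(seq)
            seed_starts = list(range(0, n - seed_length + 1, seed_length))
            if seed_starts[-1] != n - seed_length:
                seed_starts.append(n - seed_length)
            candidates = set()
            for so in seed_starts:
                for pos in index.get(seq[so: so + seed_length], ()):
                    start = pos - so
                    if 0 <= start <= len(cons) - n:
                        candidates.add(start)
            strand_rank = 0 if strand == "+" else 1
            for start in candidates:
                mism = int(
                    np.count_nonzero(seq_arr != cons_arr[start: start + n])
                )
                score = n - 2 * mism
                key = (-score, start, strand_rank)
                if best is None or key < best[0]:
                    best = (key, start, n, mism, strand, score)
        if best is None or best[3] / best[2] > max_mismatch_rate:
            out.append(None)
        else:
            _, start, n, mism, strand, score = best
            out.append(
                ConsensusAlignment(
                    read_id=rid,
                    consensus=model.name,
                    start=start,
                    end=start + n,
                    strand=strand,
                    mismatches=mism,
                    score=score,
                )
            )
    return out


@dataclass
class CoverageTrace:
    """Per-base normalized depth per sample with replicate mean and SD."""

    model: ConsensusModel
    samples: list[str]
    depth: np.ndarray  # samples x length, cpm
    mean: np.ndarray
    sd: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        L = len(self.model)
        df = pd.DataFrame(
            {
                "position": np.arange(L),
                "segment": [self.model.segment_of(p) for p in range(L)],
            }
        )
        for i, s in enumerate(self.samples):
            df[s] = self.depth[i]
        df["mean"] = self.mean
        df["sd"] = self.sd
        return df

    def segment_mean(self, segment_name: str) -> float:
        for seg, s, e in self.model.segments:
            if seg == segment_name:
                return float(self.mean[s:e].mean())
        raise KeyError(segment_name)


def consensus_coverage(
    alignments_per_sample: dict[str, list[ConsensusAlignment | None]],
    model: ConsensusModel,
    library_sizes: dict[str, int],
) -> CoverageTrace:
    """Per-base cpm depth per sample; mean and SD across replicates."""
    L = len(model)
    samples = list(alignments_per_sample)
    depth = np.zeros((len(samples), L))
    for i, s in enumerate(samples):
        delta = np.zeros(L + 1)
        for aln in alignments_per_sample[s]:
            if aln is None:
                continue
            if aln.start < 0 or aln.end > L:
                raise ValueError(
                    f"alignment [{aln.start}, {aln.end}) outside model of length {L}"
                )
            delta[aln.start] += 1
            delta[aln.end] -= 1
        depth[i] = np.cumsum(delta[:-1]) / library_sizes[s] * 1e6
    return CoverageTrace(
        model=model,
        samples=samples,
        depth=depth,
        mean=depth.mean(axis=0),
        sd=depth.std(axis=0, ddof=0),
    )
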