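"""Independent brute-force oracles the fast implementations are checked
against. Everything here is deliberately O(n*m) and dumb."""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_overlap_counts(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Per-query count of overlapping subjects by exhaustive comparison."""
    counts = np.zeros(len(query), dtype=np.int64)
    for i, q in enumerate(query.itertuples(index=False)):
        for s in subject.itertuples(index=False):
            if q.chrom == s.chrom and q.start < s.end and s.start < q.end:
                counts[i] += 1
    return counts


def brute_label_presence(
    query: pd.DataFrame, subject: pd.DataFrame, label_col: str
) -> pd.Series:
    """Per label: number of queries overlapping >= 1 subject of that label."""
    out: dict[str, int] = {}
    for lab in pd.unique(subject[label_col]):
        sub = subject[subject[label_col] == lab]
        hits = 0
        for q in query.itertuples(index=False):
            if any(
                q.chrom == s.chrom and q.start < s.end and s.start < q.end
                for s in sub.itertuples(index=False)
            ):
                hits += 1
        out[lab] = hits
    return pd.Series(out, dtype=np.int64)


def brute_per_query_label_membership(
    query: pd.DataFrame, subject: pd.DataFrame, label_col: str
) -> pd.DataFrame:
    """Boolean membership of each query in each subject label."""
    labs = list(pd.unique(subject[label_col]))
    out = np.zeros((len(query), len(labs)), dtype=bool)
    for j, lab in enumerate(labs):
        sub = subject[subject[label_col] == lab]
        for i, q in enumerate(query.itertuples(index=False)):
            out[i, j] = any(
                q.chrom == s.chrom and q.start < s.end and s.start < q.end
                for s in sub.itertuples(index=False)
            )
    return pd.DataFrame(out, columns=labs)


COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def exhaustive_best_alignment(read: str, consensus: str):
    """Best ungapped placement by scoring the read at every offset, both
    strands; ties to higher score, then leftmost start, then + strand.

    Returns (start, strand, mismatches) or None if the read is longer than
    the consensus.
    """
    n = len(read)
    if n > len(consensus):
        return None
    best = None
    for strand, seq in (("+", read), ("-", read.translate(COMPLEMENT)[::-1])):
        rank = 0 if strand == "+" else 1
        for start in range(len(consensus) - n + 1):
            mism = sum(a != b for a, b in zip(seq, consensus[start: start + n]))
            score = n - 2 * mism
            key = (-score, start, rank)
            if best is None or key < best[0]:
                best = (key, start, strand, mism)
    _, start, strand, mism = best
    return start, strand, mism


def exhaustive_best_alignment_fast(read: str, consensus: str):
    """Same all-offsets scan as :func:`exhaustive_best_alignment`, vectorized
    with numpy so thousand-read fixtures stay fast. Scores every offset on
    both strands; ties to higher score, then leftmost start, then + strand."""
    n = len(read)
    if n > len(consensus):
        return None
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(cons, n)
    best = None
    for strand, seq in (("+", read), ("-", read.translate(COMPLEMENT)[::-1])):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        mism = (windows != arr).sum(axis=1)
        start = int(mism.argmin())  # argmin is leftmost on ties
        rank = 0 if strand == "+" else 1
        key = (int(mism[start]), start, rank)  # min mismatches = max score
        if best is None or key < best[0]:
            best = (key, start, strand, int(mism[start]))
    _, start, strand, mism = best
    return start, strand, mism


def two_feature_em_fixed_point(
    n_a_unique: int, n_b_unique: int, n_shared: int, tol: float = 1e-12
) -> tuple[float, float]:
    """Fixed point of two-feature EM: iterate the update map to machine
    precision (independent of the implementation under test)."""
    total = n_a_unique + n_b_unique + n_shared
    pa = 0.5
    for _ in range(100_000):
        share_a = n_shared * pa / (pa + (1 - pa))  # abundances sum to 1
        # E-step with abundances (pa, 1-pa): shared reads split pa : 1-pa
        ca = n_a_unique + n_shared * pa
        pa_new = ca / total
        if abs(pa_new - pa) < tol:
            pa = pa_new
            break
        pa = pa_new
    return pa * total, (1 - pa) * total


def random_region_hit_probability(
    merged: list[tuple[int, int]], region_length: int, chrom_length: int
) -> float:
    """Exact probability that a random region of the given length placed
    uniformly (start in [0, chrom_length - L]) overlaps the merged
    intervals. Computed by exact integration over the discrete placements:
    region [x, x+L) hits [a, b) iff x in [a-L+1, b-1], clipped to the
    placement range."""
    L = region_length
    n_placements = chrom_length - L + 1
    hit = [(max(0, a - L + 1), min(n_placements - 1, b - 1)) for a, b in merged]
    # merged inputs are disjoint and sorted; their expansions may touch
    covered = 0
    prev_end = -1
    for lo, hi in hit:
        lo = max(lo, prev_end + 1)
        if hi >= lo:
            covered += hi - lo + 1
            prev_end = hi
    return covered / n_placements
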