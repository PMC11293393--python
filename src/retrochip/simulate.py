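"""Synthetic genomes, ChIP fragment sets, and NB count matrices.

Every simulator is a pure function of its config (seed included). One
global integer seed expands into independent per-stage substreams through a
counter-based scheme (Philox keyed by the seed with a fixed per-stage
counter), so adding a stage never perturbs the streams of earlier stages.

The generators emulate the statistical structure of a repeat-centric ChIP
experiment: a genome carrying mutated copies of repeat consensus sequences,
input libraries uniform over the genome, ChIP libraries enriched over
chosen repeat families by known factors, an exogenous spike-in represented
by its read total, and negative-binomial count matrices with implanted
log2 fold changes. Ground truth is always returned alongside.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import FragmentSet, RepeatAnnotation
from .intervals import IntervalSet
from .signal import CountMatrix

ALPHABET = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one named stage of one global seed."""
    counter = zlib.crc32(stage.encode())
    return np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, 0, counter]))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ------------------------------------------------------------------ genome

@dataclass
class RepeatSpec:
    """One repeat family to implant: consensus plus placement targets."""

    repeat_name: str
    repeat_family: str
    repeat_class: str
    consensus: str | int  # explicit sequence, or a length to draw randomly
    n_instances: int | None = None
    target_fraction: float | None = None  # of total genome bases
    divergence: float = 0.05  # substitutions per base per instance

    def __post_init__(self) -> None:
        if (self.n_instances is None) == (self.target_fraction is None):
            raise ValueError(
                f"{self.repeat_name}: give exactly one of n_instances / target_fraction"
            )
        if self.target_fraction is not None and not (0 <= self.target_fraction < 1):
            raise ValueError("target_fraction must be in [0, 1)")
        if not (0 <= self.divergence < 1):
            raise ValueError("divergence must be in [0, 1)")


@dataclass
class GenomeConfig:
    seed: int
    chrom_lengths: list[int]
    repeat_catalog: list[RepeatSpec]

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")


@dataclass
class GenomeSimulation:
    """Simulated genome: sequences, sizes, annotation, consensus catalog."""

    sequences: dict[str, str]
    chrom_sizes: dict[str, int]
    repeats: RepeatAnnotation
    consensus: dict[str, str]  # repeat_name -> consensus sequence
    config: GenomeConfig


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases at the given per-base rate (always to a new base)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.flatnonzero(hit)
        shift = rng.integers(1, 4, size=len(idx))
        codes = np.searchsorted(ALPHABET, arr[idx])
        arr[idx] = ALPHABET[(codes + shift) % 4]
    return "".join(arr)


def simulate_genome(config: GenomeConfig) -> GenomeSimulation:
    """Random background genome with implanted, non-overlapping repeats.

    Instances are full-length consensus copies mutated at the family's
    divergence rate, placed uniformly with rejection of overlaps; half are
    inserted reverse-complemented (minus strand).
    """
    rng = substream(config.seed, "genome")
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    chrom_sizes = dict(zip(chrom_names, config.chrom_lengths))
    total = sum(config.chrom_lengths)

    consensus: dict[str, str] = {}
    plan: list[tuple[RepeatSpec, int]] = []
    requested = 0
    for spec in config.repeat_catalog:
        seq = (
            spec.consensus
            if isinstance(spec.consensus, str)
            else _random_seq(rng, spec.consensus)
        ).upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{spec.repeat_name}: invalid consensus characters")
        consensus[spec.repeat_name] = seq
        n = (
            spec.n_instances
            if spec.n_instances is not None
            else int(round(spec.target_fraction * total / len(seq)))
        )
        plan.append((spec, n))
        requested += n * len(seq)
    if requested >= total:
        raise ValueError(
            f"requested repeat bases ({requested}) do not fit genome ({total})"
        )

    # place instances by rejection against already-claimed spans
    claimed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    chrom_prob = np.array(config.chrom_lengths, dtype=float) / total
    rows = []
    for spec, n in plan:
        L = len(consensus[spec.repeat_name])
        placed = 0
        attempts = 0
        while placed < n:
            attempts += 1
            if attempts > 200 * max(n, 1):
                raise ValueError(
                    f"could not place {n} instances of {spec.repeat_name} "
                    f"without overlap"
                )
            ci = rng.choice(len(chrom_names), p=chrom_prob)
            c = chrom_names[ci]
            if chrom_sizes[c] < L:
                continue
            s = int(rng.integers(0, chrom_sizes[c] - L + 1))
            e = s + L
            if any(s < b and a < e for a, b in claimed[c]):
                continue
            claimed[c].append((s, e))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                (c, s, e, strand, spec.repeat_name, spec.repeat_family,
                 spec.repeat_class, spec.divergence)
            )
            placed += 1

    # write sequences: background then implants
    seqs = {c: list(_random_seq(rng, chrom_sizes[c])) for c in chrom_names}
    for c, s, e, strand, name, _, _, div in rows:
        inst = _mutate(rng, consensus[name], div)
        if strand == "-":
            inst = reverse_complement(inst)
        seqs[c][s:e] = list(inst)
    sequences = {c: "".join(v) for c, v in seqs.items()}

    table = pd.DataFrame(
        [r[:7] for r in rows],
        columns=["chrom", "start", "end", "strand",
                 "repeat_name", "repeat_family", "repeat_class"],
    )
    repeats = RepeatAnnotation(table, chrom_sizes=chrom_sizes)
    return GenomeSimulation(sequences, chrom_sizes, repeats, consensus, config)


# ------------------------------------------------------------- ChIP fragments

@dataclass
class ChipSimConfig:
    seed: int
    n_replicates: int = 3
    fragments_per_replicate: int = 100_000
    fragment_length_mean: float = 170.0
    fragment_length_sd: float = 30.0
    min_fragment_length: int = 50
    enrichment: dict[str, float] = field(default_factory=dict)  # family -> fold
    spikein_fraction: float = 0.05
    group_key: str = "repeat_family"

    def __post_init__(self) -> None:
        if self.fragments_per_replicate <= 0:
            raise ValueError("zero fragments requested")
        if not (0 <= self.spikein_fraction < 1):
            raise ValueError("spikein_fraction must be in [0, 1)")
        if any(v < 0 for v in self.enrichment.values()):
            raise ValueError("enrichment factors must be >= 0")


@dataclass
class ChipSimResult:
    chip: list[FragmentSet]
    input: list[FragmentSet]
    truth: pd.DataFrame  # group, covered bases, enrichment factor


def _draw_fragments(
    rng: np.random.Generator,
    n: int,
    genome: GenomeSimulation,
    weights_regions: list[tuple[IntervalSet | None, float]],
    cfg: ChipSimConfig,
) -> IntervalSet:
    """Fragments with midpoint uniform within a weight-chosen region class.

    ``weights_regions`` pairs a merged interval set (None = whole genome)
    with its sampling weight; fragment length is truncated normal with a
    floor, fragments clipped to chromosome bounds.
    """
    w = np.array([w for _, w in weights_regions], dtype=float)
    w = w / w.sum()
    choice = rng.choice(len(weights_regions), size=n, p=w)
    chrom_names = list(genome.chrom_sizes)
    chrom_lens = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    lengths = rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, size=n)
    lengths = np.maximum(np.round(lengths), cfg.min_fragment_length).astype(np.int64)

    chroms = np.empty(n, dtype=object)
    mids = np.empty(n, dtype=np.int64)
    for ri, (regions, _) in enumerate(weights_regions):
        idx = np.flatnonzero(choice == ri)
        if len(idx) == 0:
            continue
        if regions is None:  # uniform over genome
            ci = rng.choice(len(chrom_names), size=len(idx), p=chrom_p)
            for k, i in enumerate(idx):
                chroms[i] = chrom_names[ci[k]]
            mids[idx] = (rng.random(len(idx)) * chrom_lens[ci]).astype(np.int64)
        else:
            ivlens = regions.lengths().astype(float)
            pick = rng.choice(len(regions), size=len(idx), p=ivlens / ivlens.sum())
            offs = (rng.random(len(idx)) * ivlens[pick]).astype(np.int64)
            for k, i in enumerate(idx):
                chroms[i] = str(regions.chrom[pick[k]])
            mids[idx] = regions.start[pick] + offs

    clens = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.int64)
    start = mids - lengths // 2
    end = start + lengths
    start = np.clip(start, 0, None)
    end = np.minimum(end, clens)
    start = np.minimum(start, end - 1)  # keep >= 1 bp after clipping
    return IntervalSet(chroms, start, end, chrom_sizes=genome.chrom_sizes)


def simulate_chip_fragments(
    genome: GenomeSimulation, config: ChipSimConfig
) -> ChipSimResult:
    """Multi-replicate ChIP and input libraries over a simulated genome.

    Input fragments fall uniformly; ChIP fragments fall in repeat group f
    with probability proportional to covered_bases(f) x enrichment_f, and in
    the non-repeat background with weight equal to its bases (enrichment 1).
    With all factors at 1 the ChIP library is statistically identical to
    input. The recorded spike-in total is a binomial draw at the configured
    fraction of the replicate's fragment count.
    """
    key = config.group_key
    known = set(genome.repeats.groups(key))
    unknown = set(config.enrichment) - known
    if unknown:
        raise KeyError(f"enrichment for unknown {key}(s): {sorted(unknown)}")

    group_bases = genome.repeats.group_bases(key)
    total = sum(genome.chrom_sizes.values())
    background = total - int(group_bases.sum())

    nonrepeat = genome.repeats.instances.merge().complement(genome.chrom_sizes)
    chip_regions: list[tuple[IntervalSet | None, float]] = [
        (nonrepeat, float(background))
    ]
    for g in group_bases.index:
        enr = config.enrichment.get(g, 1.0)
        chip_regions.append(
            (genome.repeats.merged_group(key, g), float(group_bases[g]) * enr)
        )

    chip_sets, input_sets = [], []
    n = config.fragments_per_replicate
    for rep in range(1, config.n_replicates + 1):
        rng_c = substream(config.seed, f"chip-rep{rep}")
        rng_i = substream(config.seed, f"input-rep{rep}")
        chip_frags = _draw_fragments(rng_c, n, genome, chip_regions, config)
        input_frags = _draw_fragments(rng_i, n, genome, [(None, 1.0)], config)
        spike_c = int(rng_c.binomial(n, config.spikein_fraction))
        spike_i = int(rng_i.binomial(n, config.spikein_fraction))
        chip_sets.append(
            FragmentSet(f"chip_rep{rep}", chip_frags, library_size=n,
                        spikein_size=spike_c)
        )
        input_sets.append(
            FragmentSet(f"input_rep{rep}", input_frags, library_size=n,
                        spikein_size=spike_i)
        )

    truth = pd.DataFrame(
        {
            "group": group_bases.index,
            "covered_bases": group_bases.to_numpy(),
            "enrichment": [config.enrichment.get(g, 1.0) for g in group_bases.index],
        }
    )
    return ChipSimResult(chip=chip_sets, input=input_sets, truth=truth)


# ------------------------------------------------------------- count matrices

@dataclass
class CountSimConfig:
    seed: int
    n_features: int = 200
    samples_per_group: int = 3
    baseline_mean: float = 200.0
    baseline_log_sd: float = 1.0  # lognormal spread of per-feature means
    dispersion: float = 0.1
    implanted: dict[str, float] = field(default_factory=dict)  # feature -> log2FC

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")


def simulate_count_matrix(
    config: CountSimConfig,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Two-group NB count matrix with implanted log2 fold changes.

    Per-feature baseline means are lognormal around ``baseline_mean``;
    counts are NB with variance mu + dispersion * mu^2; implanted features
    have the second group's mean scaled by 2^log2FC. Returns the matrix and
    a truth table (feature, baseline mean, true log2FC).
    """
    rng = substream(config.seed, "counts")
    feats = [f"feature_{i:04d}" for i in range(config.n_features)]
    bad = set(config.implanted) - set(feats)
    if bad:
        raise ValueError(f"implanted features not in matrix: {sorted(bad)}")
    mu = config.baseline_mean * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=config.n_features)
        - config.baseline_log_sd**2 / 2
    )
    lfc = np.array([config.implanted.get(f, 0.0) for f in feats])
    k = config.samples_per_group
    r = 1.0 / config.dispersion  # NB size parameter

    def draw(means: np.ndarray) -> np.ndarray:
        p = r / (r + means[:, None])
        return rng.negative_binomial(r, p, size=(config.n_features, k))

    g1 = draw(mu)
    g2 = draw(mu * 2.0**lfc)
    cols = [f"ctrl_{i + 1}" for i in range(k)] + [f"treat_{i + 1}" for i in range(k)]
    counts = pd.DataFrame(np.hstack([g1, g2]), index=feats, columns=cols)
    lib = counts.sum(axis=0)
    matrix = CountMatrix(
        counts=counts,
        library_size=lib,
        spikein_size=pd.Series(0, index=cols),
        group_key="feature",
    )
    truth = pd.DataFrame({"feature": feats, "baseline_mean": mu, "log2fc": lfc})
    return matrix, truth
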