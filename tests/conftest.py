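import numpy as np
import pandas as pd
import pytest

import retrochip as rc


def random_interval_frame(
    rng: np.random.Generator,
    n: int,
    chrom_sizes: dict[str, int],
    max_len: int = 500,
) -> pd.DataFrame:
    names = list(chrom_sizes)
    chroms = rng.choice(names, size=n)
    lengths = rng.integers(1, max_len + 1, size=n)
    starts = np.array(
        [rng.integers(0, chrom_sizes[c] - l + 1) for c, l in zip(chroms, lengths)]
    )
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + lengths}
    )


@pytest.fixture(scope="session")
def toy_genome():
    """Small two-chromosome genome with two repeat families."""
    cfg = rc.GenomeConfig(
        seed=11,
        chrom_lengths=[200_000, 100_000],
        repeat_catalog=[
            rc.RepeatSpec("IAPEz-int", "ERVK", "LTR", 2000, target_fraction=0.10),
            rc.RepeatSpec("L1Md_A", "L1", "LINE", 3000, target_fraction=0.05),
        ],
    )
    return rc.simulate_genome(cfg)


@pytest.fixture(scope="session")
def toy_chip(toy_genome):
    """Three ChIP + input replicates, ERVK enriched 8x."""
    cfg = rc.ChipSimConfig(
        seed=12,
        n_replicates=3,
        fragments_per_replicate=20_000,
        enrichment={"ERVK": 8.0},
        spikein_fraction=0.05,
        group_key="repeat_family",
    )
    return rc.simulate_chip_fragments(toy_genome, cfg)


@pytest.fixture(scope="session")
def toy_genes(toy_genome):
    """Hand-placed transcripts on the toy genome (plus and minus strand)."""
    tx = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [10_000, 50_000, 20_000],
            "end": [15_000, 58_000, 26_000],
            "strand": ["+", "-", "+"],
            "transcript_id": ["t1", "t2", "t3"],
            "gene_id": ["g1", "g2", "g3"],
        }
    )
    ex = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr1", "chr2"],
            "start": [10_000, 13_000, 50_000, 56_000, 20_000],
            "end": [11_000, 15_000, 52_000, 58_000, 26_000],
            "strand": ["+", "+", "-", "-", "+"],
            "transcript_id": ["t1", "t1", "t2", "t2", "t3"],
        }
    )
    return rc.GeneAnnotation(tx, ex, chrom_sizes=toy_genome.chrom_sizes)
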