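#!/usr/bin/env python
"""Simulate the study's data structure at desk scale.

Builds a toy two-chromosome genome carrying diverged copies of an
ERVK-family element (IAPEz-like, 10% of the genome) and a LINE element
(L1-like, 5%), then draws three ChIP and three input replicates with the
ERVK family enriched 8-fold and a 5% human-chromatin spike-in, plus a
negative-binomial count matrix with ten families implanted at log2FC 1.5.
All downstream analyses read these files from results/simulated/.
"""

from pathlib import Path

import retrochip as rc
from retrochip import io as rio

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    genome = rc.simulate_genome(
        rc.GenomeConfig(
            seed=SEED,
            chrom_lengths=[200_000, 100_000],
            repeat_catalog=[
                rc.RepeatSpec("IAPEz-int", "ERVK", "LTR", 2000, target_fraction=0.10),
                rc.RepeatSpec("L1Md_A", "L1", "LINE", 3000, target_fraction=0.05),
            ],
        )
    )
    rio.write_fasta(genome.sequences, OUT / "genome.fa")
    rio.write_repeatmasker_out(genome.repeats, OUT / "repeats.out")
    rio.write_chrom_sizes(genome.chrom_sizes, OUT / "genome.chrom.sizes")
    rio.write_fasta(
        {name: seq for name, seq in genome.consensus.items()},
        OUT / "consensus.fa",
    )

    chip = rc.simulate_chip_fragments(
        genome,
        rc.ChipSimConfig(
            seed=SEED + 1,
            n_replicates=3,
            fragments_per_replicate=50_000,
            enrichment={"ERVK": 8.0},
            spikein_fraction=0.05,
            group_key="repeat_family",
        ),
    )
    for fs in chip.chip + chip.input:
        rio.write_fragments(fs, OUT / f"{fs.sample_id}.fragments.tsv")
    chip.truth.to_csv(OUT / "chip_truth.tsv", sep="\t", index=False)

    counts, truth = rc.simulate_count_matrix(
        rc.CountSimConfig(
            seed=SEED + 2,
            n_features=200,
            samples_per_group=3,
            baseline_mean=200.0,
            baseline_log_sd=0.0,
            dispersion=0.1,
            implanted={f"feature_{i:04d}": 1.5 for i in range(10)},
        )
    )
    counts.counts.to_csv(OUT / "te_counts.tsv", sep="\t")
    truth.to_csv(OUT / "te_truth.tsv", sep="\t", index=False)

    fam_bases = genome.repeats.group_bases("repeat_family")
    total = sum(genome.chrom_sizes.values())
    print(f"genome: {total:,} bp over {len(genome.chrom_sizes)} chromosomes")
    for fam, b in fam_bases.items():
        print(f"  {fam}: {b:,} bp ({b / total:.1%} of genome)")
    print(f"ChIP/input: 3+3 replicates x 50,000 fragments, ERVK enriched 8x")
    print(f"spike-in totals (ChIP): {[fs.spikein_size for fs in chip.chip]}")
    print(f"count matrix: 200 families x 6 samples, 10 implanted at log2FC 1.5")
    print(f"wrote {len(list(OUT.iterdir()))} files to {OUT}")


if __name__ == "__main__":
    main()
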