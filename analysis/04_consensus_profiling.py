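#!/usr/bin/env python
"""Stitched-consensus coverage profiling.

Stitches an LTR onto both ends of the internal consensus (the layout of a
full-length proviral copy), extracts ChIP fragments overlapping IAPEz-int
instances, aligns their genomic sequences to the stitched model with the
seeded ungapped aligner, and writes per-base cpm traces with the replicate
mean and SD plus segment boundaries.
"""

from pathlib import Path

import retrochip as rc
from retrochip import io as rio
from retrochip.simulate import substream, _random_seq

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "simulated"
SEED = 2024


def main() -> None:
    sizes = rio.read_chrom_sizes(SIM / "genome.chrom.sizes")
    repeats = rio.read_repeatmasker_out(SIM / "repeats.out", chrom_sizes=sizes)
    genome = rio.read_fasta(SIM / "genome.fa")
    consensus = rio.read_fasta(SIM / "consensus.fa")

    # model: simulated LTR stitched to both ends of the internal consensus
    rng = substream(SEED + 20, "ltr-consensus")
    ltr = _random_seq(rng, 350)
    model = rc.stitch_consensus(consensus["IAPEz-int"], ltr, "IAPEz-stitched")
    print(f"stitched model {model.name}: {len(model)} bp, segments "
          + ", ".join(f"{s}[{a}:{b}]" for s, a, b in model.segments))

    alignments, libs = {}, {}
    for i in (1, 2, 3):
        fs = rio.read_fragments(SIM / f"chip_rep{i}.fragments.tsv")
        sub, seqs = rc.extract_repeat_fragments(
            fs, repeats, ["IAPEz-int"], genome
        )
        reads = [s for s in seqs if 20 <= len(s) <= len(model)]
        alns = rc.align_to_consensus(reads, model, seed_length=15,
                                     max_mismatch_rate=0.15)
        aligned = sum(a is not None for a in alns)
        print(f"chip_rep{i}: {len(sub)} repeat fragments, "
              f"{aligned}/{len(reads)} aligned to the model")
        alignments[fs.sample_id] = alns
        libs[fs.sample_id] = fs.library_size

    trace = rc.consensus_coverage(alignments, model, libs)
    trace.to_dataframe().to_csv(BASE / "consensus_trace_iapez.tsv",
                                sep="\t", index=False)
    for seg in ("LTR_5p", "internal", "LTR_3p"):
        print(f"  mean depth over {seg}: {trace.segment_mean(seg):.1f} cpm")


if __name__ == "__main__":
    main()
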