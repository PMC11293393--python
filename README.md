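# retrochip

Repeat-centric ChIP-seq and RNA-seq analysis for studying protein binding
to transposable elements — endogenous retroviruses (ERVs), LINEs and
SINEs — and its consequences for their expression.

Standard peak-centric ChIP-seq tooling handles repetitive DNA poorly:
reads from the thousands of near-identical copies of a repeat family
multimap, peak callers ignore them, and a genuinely *global* loss of
binding is invisible once every library is scaled to its own depth. This
package implements the repeat-aware workflow used to characterize such
binding, end to end, with a synthetic-data generator so every stage runs
and is testable at desk scale with known ground truth:

- **Peak post-processing** — resizing peaks to a fixed width around their
  summit, and keeping only peaks enriched >1.2-fold over input in ≥3
  replicates (depth-normalized, pseudocount 1).
- **Feature annotation** — strand-aware promoter windows (300 bp upstream
  of the TSS), exon/intron/repeat overlap with Upset-style non-exclusive
  category counts.
- **Randomized-region enrichment null** — for each repeat label, observed
  peak overlaps are compared with *N* bootstrap sets of random regions
  matched in number and length-multiset; the report is
  `z = (observed − null_mean) / null_sd` and `fold = observed / null_mean`.
- **Per-family signal and spike-in normalization** — fragment counts per
  repeat name/family/class, normalized as
  `cpm_ij = (count_ij + p·s_j/mean(s)) / s_j × 10⁶` where `s_j` is either
  the library size or the exogenous spike-in total and `p` is a prior
  count (default 3). Spike-in mode is what makes a genome-wide binding
  change measurable.
- **Stitched-consensus profiling** — an LTR–internal–LTR consensus model
  (the layout of a full-length proviral copy), an exact-seed ungapped
  local aligner, and per-base coverage traces with replicate mean ± SD.
- **TE-aware quantification** — EM fractional assignment of multimapping
  reads (abundance-proportional E-step, count-sum M-step, monotone
  likelihood), and a negative-binomial likelihood-ratio test with
  moment-estimated, shrunk dispersions, TMM-style compositional factors,
  prior-stabilized log₂ fold changes and Benjamini–Hochberg FDR, with the
  significance rule FDR < 0.05 and |log₂FC| > 0.9.

## Layout

The analysis is organized as numbered drivers over a library:

```
analysis/01_simulate_data.py            toy genome + ChIP/input + counts
analysis/02_peak_filtering_enrichment.py  filter + bootstrap enrichment
analysis/03_repeat_signal_spikein.py    per-family cpm, spike-in contrast
analysis/04_consensus_profiling.py      stitched-consensus coverage
analysis/05_te_differential_expression.py  EM + NB differential test
src/retrochip/                          all computation (import retrochip)
```

Each driver writes its tables under `results/` and prints what it found.
A thin `retrochip` command-line wrapper exposes the same operations
(`retrochip filter-peaks`, `repeat-enrich`, `repeat-count`, `signal`,
`bins`, `consensus-map`, `diff`, `em-assign`).

## Worked example

```bash
python analysis/01_simulate_data.py
python analysis/02_peak_filtering_enrichment.py
```

prints, for a 300-kb toy genome with an ERVK-like family at 10% of the
genome enriched 8× in ChIP:

```
filter (>1.2-fold in >=3 replicates): kept 166/300 candidates (150 of 150 planted, 16 of 150 background)

repeat-family enrichment vs randomized regions (n_boot=100):
       observed  null_mean  null_sd      z  fold
label
ERVK        166      19.38     4.46  32.89  8.57
L1            0       9.11     2.74  -3.33  0.00
```

All 150 peaks planted inside ERVK instances survive the replicate filter
(plus 16 background peaks that happen to lie in enriched regions); against
100 random matched region sets the surviving peaks overlap ERVK 8.6-fold
more often than chance (z ≈ 33), while the un-enriched L1 family sits at
the null. `analysis/03_repeat_signal_spikein.py` then shows the spike-in
contrast: after a simulated global 2× ChIP-efficiency loss the
library-size-normalized mutant/wild-type ratio stays at ~1.0 (the loss is
invisible) while the spike-in-normalized ratio reads ~0.5.

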