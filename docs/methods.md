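# Methods

This note documents the models, conventions, and numerical choices behind
`retrochip`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates and overlap

All internal coordinates are 0-based half-open `[start, end)`; 1-based
inclusive formats (GTF, RepeatMasker `.out`) are converted at the I/O
boundary only. Two intervals overlap iff they share ≥1 base on the same
chromosome; strand is never consulted for overlap. The overlap engine uses
sorted-array `searchsorted` counting — for a query `[s, e)` the number of
overlapping subjects is `#(start < e) − #(end ≤ s)` — and presence against
a repeat label is tested against the *merged* (disjoint) intervals of that
label. Both paths are verified exactly against an exhaustive O(n·m) oracle
in the test suite, so any future optimization must preserve bit-exact
tallies.

Peak resizing to width *w* around a summit uses the window
`[summit − ⌊w/2⌋, summit + ⌈w/2⌉)`; at a chromosome edge the window is
shifted inward so the length is always exactly *w* (a chromosome shorter
than *w* is an error). Promoter windows are strand-aware: `[TSS−u, TSS)`
on the plus strand and `[TSS, TSS+u)` on the minus strand (u = 300 bp by
default), clipped at chromosome bounds. Fragments — paired mates collapsed
to one span — are the counting unit everywhere; a fragment overlapping a
feature by ≥1 bp counts once, and once only per repeat group even when it
bridges two same-group instances (it still counts for each *distinct*
group it touches).

## Peak filtering

A peak survives iff its depth-normalized ChIP/input ratio exceeds the fold
threshold (default 1.2, strict) in at least `min_reps` replicates (default
3). The ratio per replicate pair is
`((chip+1)/chip_lib) / ((input+1)/input_lib)`; the pseudocount of one
fragment on both counts keeps empty peaks defined and biases weakly toward
rejection at very low counts. The filter is monotone in both thresholds by
construction.

## Randomized-region enrichment null

Each of `n_boot` null sets (default 100) reproduces the observed peaks'
count and exact multiset of lengths. A region of length L is placed by
choosing a chromosome with probability proportional to its length among
chromosomes with length ≥ L, then a start uniform on `[0, chrom_len − L]`.
Null regions may overlap each other; no mappability or gap exclusion is
applied (the toy genomes have neither). Observed and null overlaps are
tallied identically with presence counting — one peak hitting *k*
instances of a label contributes 1 — which keeps both on one scale. The
spread reported is the SD across bootstrap sets, and the headline statistic
is the empirical z-score; no multiple-testing correction is applied to
z-scores. The null tally is validated two ways: against the exact
analytically-integrated hit probability of a random region (within 3
Monte-Carlo SEs at n_boot = 1000), and by exchangeability (a bootstrap set
fed back as "observed" scores |z| < 4 in ≥99% of trials).

## Normalization

`cpm_ij = (count_ij + p·s_j/mean(s)) / s_j × 10⁶`, where `s_j` is the
library size or the spike-in total and p is the prior count (default 3).
Scaling the prior by relative depth makes equal counts at equal depth give
equal values and keeps zero counts finite and comparable; exact invariance
under joint scaling of counts and denominators holds at p = 0 and
approximately otherwise. Spike-in totals as denominators are what expose
global binding changes: a simulated 2× loss of ChIP efficiency with fixed
spike-ins reads ~1.0 under library-size mode and ~0.5 under spike-in mode.

TMM compositional factors use the unweighted trimmed mean of M-values
(trim 30% of M, 5% of A; features zero in either sample excluded),
renormalized to geometric mean 1 and multiplied by the chosen denominator.
edgeR's `calcNormFactors` additionally weights M-values by inverse
variance; a cross-check test accepts 5% relative deviation from edgeR on a
random NB matrix for that reason. Note that TMM assumes a stable majority
of features — applied to a feature set that changes globally it will
re-absorb the global shift, which is precisely why the spike-in
denominator (not TMM alone) carries global changes.

## Binned signal

Waterfall/metaplot matrices count fragments per fixed-width bin in a
`[mid − flank, mid + flank)` window per anchor (defaults flank 3000,
bin 50), cpm-scaled; bins extending past a chromosome are recorded as
missing (NaN), not zero, and rows are ordered by descending row mean (the
sort key is a display choice, not load-bearing). Genome-wide bins tile
each chromosome with non-overlapping windows (default 1 kb, last bin
truncated); a fragment counts in every bin it overlaps, so bin sums exceed
fragment counts exactly when fragments span bin boundaries.

## Stitched consensus and alignment

An LTR retroelement model is `LTR + internal + LTR` with segments
`LTR_5p`, `internal`, `LTR_3p` tiling the sequence — the arrangement of a
full-length proviral copy, so reads from either terminal repeat have a
home at both ends. Alignment is ungapped and local on the consensus:
non-overlapping exact k-mer seeds (default k = 15, plus a final seed
flush with the read end) propose offsets on both strands, the full read is
scored (match +1 / mismatch −1) at each offset where it fits, and the best
placement is kept iff its mismatch rate is ≤ `max_mismatch_rate`
(default 0.1). Ties break to higher score, then leftmost consensus start,
then plus strand. The seeded search provably equals the exhaustive
all-offsets optimum whenever the best placement contains an exact seed —
guaranteed when a read has fewer than `read_len / k` mismatches — and the
test suite asserts that equality on a thousand mutated reads.

The deterministic leftmost tie-break sends reads mapping equally to both
identical LTR copies to `LTR_5p`. This biases `LTR_5p` vs `LTR_3p` depth
in a way replicate SD cannot reveal (every replicate shares the bias);
interpret the two LTR segments jointly. Coverage is the alignment span
(no fragment extension on the consensus), cpm-scaled per sample, with mean
and SD across replicates; coverage mass equals the summed aligned lengths
exactly. The flatness check for uniformly sampled reads is run at 20 reads
per start position, giving per-base depth high enough (~20 × read length)
that the ±25% band over the central 90% of bases tests systematic bias
rather than Poisson noise.

## Differential testing

Counts are modeled as NB with mean `μ_i · s_j` (effective size factor
`s_j`, normalized to mean 1) and variance `μ + αμ²`. Dispersion: the
per-feature method-of-moments estimate on factor-normalized counts —
pooled within groups, excess of variance over the Poisson part divided by
the squared mean — is left unfloored and shrunk toward the common
dispersion with weight `df/(df + 4)` (df = samples − 2 group means; 0.5
for 3 vs 3); the common dispersion is the pooled ratio of summed excess
variances to summed squared means, which avoids the downward bias a median
of zero-floored estimates would have. The shrunk value is floored at 10⁻⁸.
Group means are NB MLEs via Newton iteration on the score equation with
expected-information steps; the likelihood-ratio statistic is referred to
χ²(1). Measured size at α = 0.05 is ~0.07 under the package's null
simulation (3 vs 3, dispersion 0.1). Fold changes are computed on the
normalized scale with the depth-scaled prior (default 3), so zero groups
give finite log₂FC; all-zero features report p = 1, log₂FC = 0. FDR is
Benjamini–Hochberg; the default significance rule is FDR < 0.05 and
|log₂FC| > 0.9. An optional intron-overlap filter can exclude
intron-associated repeat features before testing; it is off by default.

Power context: with 3 vs 3 samples, baseline mean 200 and dispersion 0.1,
an implanted log₂FC of 1.5 sits at effect z ≈ 3.9 while the BH threshold
for 10/200 true effects sits near z ≈ 3.3, capping achievable recovery at
roughly 74% — the known-dispersion LRT and edgeR's QL F-test both measure
~0.74 on identical matrices, and this implementation performs at that
ceiling (~0.73–0.77).

## EM multimapper assignment

Given a reads × features 0/1 compatibility matrix, abundances start
uniform; the E-step splits each read over its compatible features in
proportion to current abundances, the M-step sets abundances to the summed
fractional assignments, and iteration stops when the largest relative
abundance change falls below `tol` (default 10⁻⁶, max 100 iterations).
Fractional counts sum exactly to the number of reads after every
iteration, and the observed-data log-likelihood is non-decreasing (both
asserted in tests). Instance-level EM results can be rolled up to family
level afterward (`rollup_counts`); constructing the compatibility matrix
from genome alignments is the caller's adapter.

## Synthetic data

The generator emulates the *statistical structure* of a repeat-centric
ChIP experiment, not sequencing physics:

- **Genome**: random background with full-length consensus copies placed
  without overlap (uniform with rejection), half reverse-complemented,
  each mutated by per-base substitution at the family's divergence rate
  (default 0.05). Real genomes nest and truncate repeats; nesting adds no
  power to the oracle tests, so instances here are whole and disjoint.
- **ChIP/input fragments**: input is midpoint-uniform over the genome.
  ChIP chooses the non-repeat background (weight = its bases) or a repeat
  family (weight = covered bases × enrichment factor), then places the
  midpoint uniformly within the chosen region class; with all factors at 1
  ChIP is statistically identical to input. Fragment lengths are truncated
  normal (mean 170, SD 30, floor 50 bp), clipped at chromosome ends.
  Spike-ins are represented by their totals only — a binomial draw at the
  configured fraction of the replicate's fragment count — because the
  pipeline uses spike-in totals purely as scaling denominators.
- **Counts**: per-feature baselines are lognormal around the configured
  mean (spread 1.0 by default; the calibration and power simulations pin
  all baselines to the stated mean exactly), counts NB with the configured
  dispersion, implanted features scale the second group's mean by
  2^log₂FC, and a truth table always accompanies the matrix.

No sequencing-error, PCR-duplicate, or mappability model is included, and
no real genome is handled at simulation time; passing tests demonstrate
correctness of the *computational* pipeline against known truth, not
robustness to artifacts real libraries carry. One global seed expands into
per-stage substreams via a counter-based scheme (Philox keyed by the seed,
counter from the stage name), so adding a stage never perturbs earlier
streams and every simulator is bitwise reproducible.

## Problem sizes

The bundled analyses and checks run on toy genomes of 0.1–1 Mb, 2 × 10⁴ –
10⁵ fragments per replicate, 200-feature count matrices with 200 null
replicates and 20 power seeds, and 10³ bootstrap sets — sizes chosen so
the full suite and the acceptance script each complete in minutes on one
CPU while keeping every statistical check adequately powered.
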