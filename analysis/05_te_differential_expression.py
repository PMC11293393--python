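#!/usr/bin/env python
"""TE-aware differential expression: EM multimapper assignment and the NB
test at the study's significance rule (FDR < 0.05, |log2FC| > 0.9).

First demonstrates EM fractional assignment on an ambiguous two-element
compatibility fixture, then runs the NB likelihood-ratio test on the
simulated count matrix with ten families implanted at log2FC 1.5 and
reports recovery against the truth table.
"""

from pathlib import Path

import pandas as pd

import retrochip as rc
from retrochip.signal import CountMatrix

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "simulated"


def main() -> None:
    # EM on an ambiguous fixture: 9 reads unique to elementA, 1 unique to
    # elementB, 10 compatible with both (e.g. reads in the shared LTR)
    lists = [["elementA"]] * 9 + [["elementB"]] * 1 + [["elementA", "elementB"]] * 10
    res = rc.em_assign_multireads(rc.compatibility_from_lists(lists), tol=1e-10)
    print("EM assignment of 10 ambiguous reads (unique support 9 vs 1):")
    print(res.counts.round(3).to_string())
    print(f"  converged in {res.n_iter} iterations; "
          f"total mass {res.counts.sum():.9f} (= 20 reads)\n")

    counts = pd.read_csv(SIM / "te_counts.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(SIM / "te_truth.tsv", sep="\t").set_index("feature")
    matrix = CountMatrix(
        counts=counts,
        library_size=counts.sum(axis=0),
        spikein_size=pd.Series(0, index=counts.columns),
    )
    groups = ["ctrl"] * 3 + ["treat"] * 3
    out = rc.nb_differential(matrix, groups, prior_count=3.0,
                             fdr_threshold=0.05, lfc_threshold=0.9)
    out.table.to_csv(BASE / "te_differential.tsv", sep="\t")

    implanted = truth.index[truth["log2fc"] != 0]
    sig = out.table["significant"]
    tp = int(sig[implanted].sum())
    fp = int(sig[~sig.index.isin(implanted)].sum())
    print(f"NB differential test (FDR<0.05, |log2FC|>0.9): "
          f"{int(sig.sum())} significant families")
    print(f"  {tp}/{len(implanted)} implanted (log2FC 1.5) recovered, "
          f"{fp} false positives among {len(counts) - len(implanted)} nulls")
    print("\ntop hits:")
    print(out.table.sort_values("pvalue").head(12).round(4))


if __name__ == "__main__":
    main()
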