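#!/usr/bin/env python
"""Exact tests for the CRISPR validation crosses and the screen power model.

For each cross: the two-sided Fisher test of the modifier allele among
rescues (Mendelian segregation assumed for ungenotyped non-rescue
littermates), the companion exact binomial, and the penetrance estimate
against the Mendelian expected count of rescue-genotype carriers. Closes
with the screen-scale burden power calculation: how many suppressor genes
would accumulate five or more hits if 30 (or 500) genes could rescue.
"""

import argparse
from pathlib import Path

import pandas as pd

from enuscreen import (
    PowerModel,
    binomial_allele_test,
    bundled_cross_table,
    penetrance_estimate,
    rescue_allele_fisher,
    suppressor_gene_power,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/crosses"))
    args = ap.parse_args()

    rows = []
    for cross in bundled_cross_table():
        fisher = rescue_allele_fisher(cross)
        row = {"gene": cross.name, "n": cross.n_total,
               "rescues_with": cross.rescues_with,
               "rescues_without": cross.rescues_without,
               "fisher_p": round(fisher.p_value, 4)}
        if cross.n_rescues:
            row["binomial_p"] = round(
                binomial_allele_test(cross.rescues_with, cross.rescues_without), 4)
            pen = penetrance_estimate(cross)
            row["penetrance"] = round(pen.estimate, 3)
            row["penetrance_ci"] = f"[{pen.ci_low:.2f}, {pen.ci_high:.2f}]"
        rows.append(row)
    df = pd.DataFrame(rows)
    print(df.to_string(index=False))

    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "cross_tests.tsv", sep="\t", index=False)

    print("\nburden power model (107 mice, hit threshold k = 5):")
    for g in (30, 500):
        res = suppressor_gene_power(PowerModel(107, g, 5), "analytic")
        print(f"  {g} suppressor genes -> {res.mean_per_gene:.2f} hits/gene, "
              f"{res.expected_genes_at_k:.1f} genes expected with >= 5 hits")


if __name__ == "__main__":
    main()
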