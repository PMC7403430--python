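#!/usr/bin/env python
"""Optional check on a real per-patient cohort table.

Given a locally available cohort CSV/TSV with one row per patient and
{yes,no,NA}-coded columns for MGMT promoter hypomethylation, DNA
hypermutation and MGMT fusion, run the mutual-exclusivity bootstrap and the
fusion-frequency Clopper-Pearson interval on the real data. The table is
not distributed with this package; supply your own export.

Usage:
    python scripts/real_cohort_exclusivity.py --table cohort.csv \
        --alterations hypomethylation,hypermutation,fusion --reps 10000 --seed 1
"""

from __future__ import annotations

import argparse
import json

import pandas as pd

from fusionscape.exclusivity import bootstrap_exclusivity, exclusivity_from_landscape
from fusionscape.landscape import binomial_ci


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--table", required=True)
    parser.add_argument("--alterations", default="hypomethylation,hypermutation,fusion")
    parser.add_argument("--fusion-column", default="fusion")
    parser.add_argument("--reps", type=int, default=10_000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    sep = "\t" if args.table.endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(args.table, sep=sep, dtype=str, keep_default_na=False)
    names = args.alterations.split(",")
    inp = exclusivity_from_landscape(table, names)
    test = bootstrap_exclusivity(inp, n_reps=args.reps, seed=args.seed)
    x = int((table[args.fusion_column] == "yes").sum())
    ci = binomial_ci(x, len(table))
    print(
        json.dumps(
            {
                "n_patients": len(table),
                "fusion_positive": x,
                "fusion_ci_95": [ci.lower, ci.upper],
                "observed_coverage": test.observed_coverage,
                "p_value": test.p_value,
                "p_tie_inclusive": test.p_tie_inclusive,
                "n_reps": test.n_reps,
                "seed": test.seed,
            },
            indent=2,
        )
    )


if __name__ == "__main__":
    main()
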