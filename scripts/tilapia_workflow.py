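#!/usr/bin/env python
"""Optional real-data workflow for the tilapia pansteatitis lipidomics study.

This script is NOT run by the test suite or by scripts/acceptance.py: it
requires data the user must download themselves from the Metabolomics
Workbench (Project PR000705, DOI 10.21228/M8JH5X), exported as three CSV
files in the layouts this package reads:

  abundance.csv    samples as rows, lipids as columns
  samples.csv      sample covariates incl. a continuous 'age' column
  annotations.csv  triglyceride annotations with continuous
                   'total_carbon' and 'double_bonds' columns

It then runs the package's standard pipeline — PQN, log2, adjusted and
unadjusted bilinear fits of the age effect over carbon/double-bond bins,
and the two-step ORA comparator — and prints the per-category p-values
so the qualitative pattern (significant mid-range carbon effects under
the adjusted model, null double-bond effects) can be inspected.

Usage:
    python scripts/tilapia_workflow.py --abundance abundance.csv \
        --samples samples.csv --annotations annotations.csv
"""

from __future__ import annotations

import argparse

from matlm import (
    ZSpec,
    ZVariable,
    adaptive_bh,
    build_x,
    build_z,
    fit_mlm,
    log_transform,
    pqn_normalize,
    read_matrix_csv,
    read_table_csv,
    two_step_enrichment,
    wald_inference,
)

CARBON_EDGES = [50, 55, 60, 65]
DB_EDGES = [3, 6, 9, 12]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--abundance", required=True)
    ap.add_argument("--samples", required=True)
    ap.add_argument("--annotations", required=True)
    ap.add_argument("--age-column", default="age")
    ap.add_argument("--covariates", default=None,
                    help="comma-separated extra covariates (e.g. health,sex)")
    args = ap.parse_args()

    Y = read_matrix_csv(args.abundance)
    samples = read_table_csv(args.samples, kind="sample").reindexed(Y.sample_ids)
    annotations = read_table_csv(
        args.annotations, kind="annotation",
        schema={"total_carbon": "continuous", "double_bonds": "continuous"},
    ).reindexed(Y.metabolite_ids)

    Y = log_transform(pqn_normalize(Y), base="2")
    covars = [args.age_column] + (
        args.covariates.split(",") if args.covariates else []
    )
    X = build_x(samples, covars, intercept=True)
    focus = args.age_column

    specs = {
        "adjusted": ZSpec(
            [ZVariable("total_carbon", CARBON_EDGES),
             ZVariable("double_bonds", DB_EDGES)],
            "adjusted",
        ),
        "unadjusted_carbon": ZSpec([ZVariable("total_carbon", CARBON_EDGES)],
                                   "unadjusted"),
        "unadjusted_db": ZSpec([ZVariable("double_bonds", DB_EDGES)],
                               "unadjusted"),
    }
    for name, zspec in specs.items():
        Z = build_z(annotations, zspec)
        inf = wald_inference(fit_mlm(Y, X, Z), fdr="none")
        row = inf[inf.x_label == focus].copy()
        row["q"] = adaptive_bh(row["p"].to_numpy())[0]
        print(f"\n=== {name} model: {focus} effect by annotation category ===")
        print(row[["z_label", "effect", "se", "p", "q"]].to_string(index=False))

    from matlm import bin_numeric

    membership = bin_numeric(
        annotations.column("total_carbon").to_numpy(), CARBON_EDGES
    )
    ora = two_step_enrichment(Y, X, focus, membership)
    print("\n=== ORA comparator (carbon bins) ===")
    print(ora.to_string(index=False))


if __name__ == "__main__":
    main()
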