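#!/usr/bin/env python
"""Quality-filter samples and impute missing concentrations.

Keeps samples with more than 70 observed proteins, imputes missing
cells by per-protein OLS on sample loading factors, and records the
per-(protein, group) inclusion decisions. Reads results/cohort/,
writes results/qc/.
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from plasmapipe.io_formats import read_manifest, read_quant_table, write_quant_table
from plasmapipe.qc import filter_samples, impute_ols, inclusion_filter


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/qc"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix = read_quant_table(args.cohort / "quant_table.tsv")
    manifest = read_manifest(args.cohort / "manifest.tsv")

    filtered = filter_samples(matrix)
    dropped = set(matrix.sample_ids) - set(filtered.sample_ids)
    imputed = impute_ols(filtered, anchor_fraction=0.9)
    manifest = manifest.subset(filtered.sample_ids)
    decisions = inclusion_filter(imputed, manifest)

    write_quant_table(imputed, args.out / "imputed_matrix.tsv")
    pd.DataFrame([asdict(d) for d in decisions]).to_csv(
        args.out / "inclusion_decisions.tsv", sep="\t", index=False)

    n_filled = int(imputed.imputed.to_numpy().sum())
    n_inc = sum(d.included for d in decisions)
    print(f"sample filter: kept {filtered.n_samples}/{matrix.n_samples} "
          f"samples (dropped: {sorted(dropped) or 'none'})")
    print(f"imputation: filled {n_filled} cells by OLS on loading factors")
    print(f"inclusion: {n_inc}/{len(decisions)} (protein, group) pairs pass "
          "the >=50% presence / <=50% imputed rules")


if __name__ == "__main__":
    main()
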