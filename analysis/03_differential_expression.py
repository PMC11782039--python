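#!/usr/bin/env python
"""Differential expression: signed fold changes, Mann-Whitney, BH, DEPs.

Tests every included protein in KD vs CNTR and KC vs CNTR, adjusts
within each comparison, and selects DEPs at |FC| > 1.5 and adjusted
p < 0.05. Reads results/qc/, writes results/differential/.
"""

import argparse
from pathlib import Path

from plasmapipe.differential import records_to_frame, run_differential, select_deps
from plasmapipe.io_formats import read_manifest, read_quant_table
from plasmapipe.qc import inclusion_filter

COMPARISONS = [("KD", "CNTR"), ("KC", "CNTR")]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--qc", type=Path, default=Path("results/qc"))
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/differential"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix = read_quant_table(args.qc / "imputed_matrix.tsv")
    manifest = read_manifest(args.cohort / "manifest.tsv").subset(
        matrix.sample_ids)
    decisions = inclusion_filter(matrix, manifest)
    records = run_differential(matrix, manifest, decisions, COMPARISONS)
    for (test, ctrl), recs in records.items():
        frame = records_to_frame(recs)
        frame.to_csv(args.out / f"dep_{test}_vs_{ctrl}.tsv", sep="\t",
                     index=False)
        n_sig = int((frame["p_adj"] < 0.05).sum())
        print(f"{test} vs {ctrl}: {len(frame)} proteins tested, "
              f"{n_sig} at adjusted p < 0.05")
    deps = select_deps(records)
    deps.to_csv(args.out / "dep_table.tsv", sep="\t", index=False)
    print(f"DEP table (|FC| > 1.5, adj p < 0.05 in >=1 comparison): "
          f"{len(deps)} proteins")
    if not deps.empty:
        print(deps.to_string(index=False, float_format="%.3g"))


if __name__ == "__main__":
    main()
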