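#!/usr/bin/env python
"""Segment samples by PCA and sparse PLS-DA with cross-validated AUC.

Selects proteins observed in at least 20 samples, standardizes the
log10 matrix, and reports PCA variance, sPLS-DA components (keepX by
cross-validated grid search), 0.95 confidence ellipses, CV accuracy
and one-vs-rest ROC AUC. Reads results/qc/, writes
results/multivariate/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from plasmapipe import multivariate as mv
from plasmapipe.io_formats import read_manifest, read_quant_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--qc", type=Path, default=Path("results/qc"))
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/multivariate"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix = read_quant_table(args.qc / "imputed_matrix.tsv")
    manifest = read_manifest(args.cohort / "manifest.tsv").subset(
        matrix.sample_ids)

    selection = mv.select_features(matrix, min_samples_present=20)
    prepared = mv.prepare_matrix(matrix, selection)
    labels = manifest.assignments.loc[prepared.index]
    print(f"feature selection: {len(selection.selected_protein_ids)} "
          "proteins observed in >= 20 samples")

    pca_res = mv.pca(prepared)
    pca_res.scores.to_csv(args.out / "pca_scores.tsv", sep="\t")
    print("PCA explained variance: "
          + ", ".join(f"PC{i+1} = {v:.1f}%" for i, v in
                      enumerate(pca_res.explained_variance_pct)))

    keepx = mv.tune_keepx(prepared, labels, seed=args.seed)
    model = mv.splsda_fit(prepared, labels, keepX=keepx)
    model.scores.to_csv(args.out / "splsda_scores.tsv", sep="\t")
    pd.DataFrame(model.loadings, index=model.feature_ids,
                 columns=model.scores.columns).to_csv(
        args.out / "splsda_loadings.tsv", sep="\t")
    print(f"sPLS-DA: keepX = {keepx}, explained variance "
          + ", ".join(f"comp{i+1} = {v:.1f}%" for i, v in
                      enumerate(model.explained_variance_pct)))

    n_heavy = int((abs(pd.DataFrame(model.loadings)) > 0.1).any(
        axis=1).sum())
    print(f"{n_heavy} proteins carry |w| > 0.1 on some component")

    ellipses = {}
    for cls in model.classes:
        ell = mv.confidence_ellipse(
            model.scores.loc[labels == cls].iloc[:, :2].to_numpy())
        ellipses[cls] = {"center": ell.center.tolist(),
                         "semi_axes": ell.semi_axes.tolist(),
                         "angle_deg": ell.angle_deg}

    report = mv.cross_validate_splsda(prepared, labels, keepX=keepx,
                                      seed=args.seed)
    roc_rows = [{"class": cls, "fpr": f, "tpr": t}
                for cls, (fpr, tpr, _) in report.roc_curves.items()
                for f, t in zip(fpr, tpr)]
    pd.DataFrame(roc_rows).to_csv(args.out / "roc_points.tsv", sep="\t",
                                  index=False)
    (args.out / "summary.json").write_text(json.dumps({
        "keepX": keepx,
        "pca_explained_variance_pct":
            pca_res.explained_variance_pct.tolist(),
        "splsda_explained_variance_pct":
            model.explained_variance_pct.tolist(),
        "cv_accuracy": report.accuracy,
        "auc": report.auc,
        "ellipses_95pct": ellipses,
        "seed": args.seed,
    }, indent=2, sort_keys=True) + "\n")
    print(f"5-fold CV accuracy: {report.accuracy:.1%}; ROC AUC: "
          + ", ".join(f"{c} = {a:.2f}" for c, a in report.auc.items()))


if __name__ == "__main__":
    main()
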