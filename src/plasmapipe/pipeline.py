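"""End-to-end orchestration: ingest -> QC -> DEP -> multivariate -> PTM map.

Each stage writes its table as TSV plus a JSON provenance record
(parameters, seed, entity counts in/out) into the run directory, and
logs every filtered entity with its reason. Reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential, interface, multivariate, qc
from .io_formats import (
    GroupManifest,
    IntensityMatrix,
    apply_two_peptide_rule,
    read_manifest,
    read_psm_table,
    read_quant_table,
    read_structure,
    write_quant_table,
)

logger = logging.getLogger("plasmapipe")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run."""

    quant_table: str | None = None
    psm_table: str | None = None
    manifest: str = ""
    structures_dir: str | None = None
    peptides_table: str | None = None
    output_dir: str = "run"
    missing_dialect: str = "empty"

    min_unique_proteins: int = 70
    impute_anchor_fraction: float = 0.9
    presence_fraction: float = 0.5
    imputed_fraction: float = 0.5
    fc_cut: float = 1.5
    p_cut: float = 0.05
    control_group: str = "CNTR"
    min_samples_present: int = 20

    n_components: int = 2
    keepx: int | None = None
    keepx_grid: tuple[int, ...] = (5, 10, 20, 50)
    cv_folds: int = 5
    seed: int = 0

    sasa_probe: float = 1.4
    sasa_points: int = 960
    k_in: float = 0.9
    k_near: float = 1.1
    near_distance: float = 8.0

    run_multivariate: bool = True
    run_ptm: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "keepx_grid" in raw:
            raw["keepx_grid"] = tuple(raw["keepx_grid"])
        return cls(**raw)

    def validate(self) -> None:
        if not (0 <= self.presence_fraction <= 1
                and 0 <= self.imputed_fraction <= 1):
            raise ValueError("inclusion fractions outside [0, 1]")
        if self.fc_cut < 1:
            raise ValueError("fc_cut must be >= 1")
        if not 0 <= self.p_cut <= 1:
            raise ValueError("p_cut outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _provenance(out: Path, stage: str, params: dict, counts: dict) -> None:
    rec = {"stage": stage, "parameters": params, "counts": counts}
    (out / f"{stage}.provenance.json").write_text(
        json.dumps(rec, indent=2, sort_keys=True, default=str) + "\n"
    )


def run_pipeline(
    config: PipelineConfig,
    matrix: IntensityMatrix | None = None,
    manifest: GroupManifest | None = None,
) -> Path:
    """Execute all configured stages; returns the run directory.

    ``matrix``/``manifest`` may be passed in-memory (e.g. straight from
    the simulator); otherwise they are read from the configured paths.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out, matrix, manifest)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path,
         matrix: IntensityMatrix | None,
         manifest: GroupManifest | None) -> Path:
    # --- ingest ---------------------------------------------------------
    if manifest is None:
        manifest = read_manifest(config.manifest)
    if matrix is None:
        if config.quant_table:
            matrix = read_quant_table(config.quant_table,
                                      config.missing_dialect)
        elif config.psm_table:
            psm = read_psm_table(config.psm_table)
            passing = apply_two_peptide_rule(psm)
            dropped = set(psm.protein_ids) - passing
            for pid in sorted(dropped):
                logger.info("two-peptide rule drops %s", pid)
            psm = type(psm)(psm.rows[psm.rows["protein_id"].isin(passing)],
                            psm.site_convention)
            matrix = qc.psm_to_protein(psm)
        else:
            raise ValueError("config names neither quant_table nor psm_table")
    _provenance(out, "ingest", {"source": config.quant_table
                                or config.psm_table or "in-memory"},
                {"proteins": matrix.n_proteins, "samples": matrix.n_samples})

    # --- sample filter --------------------------------------------------
    before = set(matrix.sample_ids)
    filtered = qc.filter_samples(matrix, config.min_unique_proteins)
    for sid in sorted(before - set(filtered.sample_ids)):
        logger.info("sample filter drops %s (<= %d proteins)", sid,
                    config.min_unique_proteins)
    _provenance(out, "sample_filter",
                {"min_unique_proteins": config.min_unique_proteins},
                {"samples_in": len(before),
                 "samples_out": filtered.n_samples})
    manifest = manifest.subset(filtered.sample_ids)

    # --- imputation -----------------------------------------------------
    imputed = qc.impute_ols(filtered,
                            anchor_fraction=config.impute_anchor_fraction)
    n_filled = int((imputed.imputed & ~filtered.imputed).to_numpy().sum())
    write_quant_table(imputed, out / "imputed_matrix.tsv")
    _provenance(out, "impute",
                {"model": "log10 ~ sample loading factor (OLS)",
                 "anchor_fraction": config.impute_anchor_fraction},
                {"cells_filled": n_filled})

    # --- inclusion + DEP ------------------------------------------------
    decisions = qc.inclusion_filter(imputed, manifest,
                                    config.presence_fraction,
                                    config.imputed_fraction)
    dec_df = pd.DataFrame([asdict(d) for d in decisions])
    dec_df.to_csv(out / "inclusion_decisions.tsv", sep="\t", index=False)
    for d in decisions:
        if not d.included:
            logger.info("inclusion excludes %s in %s (obs %d, imp %d of %d)",
                        d.protein_id, d.group, d.n_observed, d.n_imputed,
                        d.n_samples_in_group)

    groups = manifest.groups
    comparisons = [(g, config.control_group) for g in groups
                   if g != config.control_group]
    records = differential.run_differential(imputed, manifest, decisions,
                                            comparisons)
    all_recs = pd.concat(
        [differential.records_to_frame(r) for r in records.values()],
        ignore_index=True,
    )
    all_recs.to_csv(out / "differential.tsv", sep="\t", index=False)
    deps = differential.select_deps(records, config.fc_cut, config.p_cut)
    deps.to_csv(out / "dep_table.tsv", sep="\t", index=False)
    _provenance(out, "differential",
                {"fc_cut": config.fc_cut, "p_cut": config.p_cut,
                 "comparisons": [f"{t}_vs_{c}" for t, c in comparisons]},
                {"tested": len(all_recs), "deps": len(deps)})

    # --- multivariate ---------------------------------------------------
    if config.run_multivariate:
        selection = multivariate.select_features(imputed,
                                                 config.min_samples_present)
        prepared = multivariate.prepare_matrix(imputed, selection)
        pca_res = multivariate.pca(prepared, config.n_components)
        pca_res.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        labels = manifest.assignments.loc[prepared.index]
        keepx = config.keepx
        if keepx is None:
            keepx = multivariate.tune_keepx(
                prepared, labels, grid=config.keepx_grid,
                n_components=config.n_components,
                n_folds=config.cv_folds, seed=config.seed)
        model = multivariate.splsda_fit(prepared, labels, keepX=keepx,
                                        n_components=config.n_components)
        model.scores.to_csv(out / "splsda_scores.tsv", sep="\t")
        pd.DataFrame(model.loadings, index=model.feature_ids,
                     columns=model.scores.columns).to_csv(
            out / "splsda_loadings.tsv", sep="\t")
        ellipses = {}
        for cls in model.classes:
            pts = model.scores.loc[labels == cls].iloc[:, :2]
            ell = multivariate.confidence_ellipse(pts.to_numpy())
            ellipses[cls] = {"center": ell.center.tolist(),
                             "semi_axes": ell.semi_axes.tolist(),
                             "angle_deg": ell.angle_deg}
        report = multivariate.cross_validate_splsda(
            prepared, labels, keepX=keepx,
            n_components=config.n_components,
            n_folds=config.cv_folds, seed=config.seed)
        roc_rows = []
        for cls, (fpr, tpr, _) in report.roc_curves.items():
            for f, t in zip(fpr, tpr):
                roc_rows.append({"class": cls, "fpr": f, "tpr": t})
        pd.DataFrame(roc_rows).to_csv(out / "roc_points.tsv", sep="\t",
                                      index=False)
        (out / "multivariate.json").write_text(json.dumps({
            "keepX": keepx,
            "pca_explained_variance_pct":
                pca_res.explained_variance_pct.tolist(),
            "splsda_explained_variance_pct":
                model.explained_variance_pct.tolist(),
            "cv_accuracy": report.accuracy,
            "auc": report.auc,
            "ellipses": ellipses,
            "seed": config.seed,
        }, indent=2, sort_keys=True) + "\n")
        _provenance(out, "multivariate",
                    {"min_samples_present": config.min_samples_present,
                     "keepX": keepx, "cv_folds": config.cv_folds,
                     "seed": config.seed},
                    {"proteins_selected":
                         len(selection.selected_protein_ids)})

    # --- PTM structural mapping -----------------------------------------
    if config.run_ptm and config.peptides_table and config.structures_dir:
        run_ptm_mapping(config, out)
    return out


def run_ptm_mapping(config: PipelineConfig, out: Path) -> pd.DataFrame:
    """Map peptide queries onto every structure in the configured dir."""
    peps = pd.read_csv(config.peptides_table, sep="\t")
    structures = sorted(Path(config.structures_dir).glob("*.pdb")) + \
        sorted(Path(config.structures_dir).glob("*.cif"))
    rows = []
    reports = []
    for _, row in peps.iterrows():
        query = interface.PeptideQuery(
            peptide=row["peptide"], protein_id=row.get("accession", ""))
        descs = []
        for spath in structures:
            structure = read_structure(spath)
            d = interface.describe_complex(
                query, structure, probe_radius=config.sasa_probe,
                n_points=config.sasa_points)
            if d is None:
                logger.info("peptide %s not found in %s", query.peptide,
                            spath.name)
                continue
            descs.append(d)
            rows.append({"peptide": query.peptide,
                         "structure": d.structure_id, "chain": d.chain,
                         "K_SASA": d.k_sasa, "HB": d.hb, "HP": d.hp,
                         "min_partner_distance": d.min_partner_distance})
        if descs:
            rep = interface.aggregate_complexes(
                query, descs, n_structures_screened=len(structures))
            reports.append({
                "peptide": rep.peptide, "protein_id": rep.protein_id,
                "PDB_counts": rep.pdb_counts,
                "K_SASA": rep.k_mean, "K_sd": rep.k_sd,
                "HB": rep.hb_mean, "HB_sd": rep.hb_sd,
                "HP": rep.hp_mean, "HP_sd": rep.hp_sd,
                "Interface": rep.location_class,
                "surface": rep.surface_flag,
            })
    per_complex = pd.DataFrame(rows)
    per_complex.to_csv(out / "ptm_per_complex.tsv", sep="\t", index=False)
    agg = pd.DataFrame(reports)
    agg.to_csv(out / "ptm_interface.tsv", sep="\t", index=False)
    (out / "ptm_interface.json").write_text(
        json.dumps(reports, indent=2, sort_keys=True, default=str) + "\n")
    _provenance(out, "ptm",
                {"probe": config.sasa_probe, "points": config.sasa_points},
                {"peptides": len(peps), "structures": len(structures),
                 "mapped": len(rows)})
    return agg
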