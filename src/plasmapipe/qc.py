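"""Sample filtering, OLS imputation, and per-group inclusion rules.

The quantitation tables go through three gates before differential
analysis:

1. *Sample filter* — a sample is kept only if strictly more than
   ``min_unique_proteins`` (default 70) proteins were observed in it;
   sparse injections are unreliable.
2. *OLS imputation* — a missing cell is predicted from a per-protein
   ordinary least-squares fit of log10 intensity against a per-sample
   loading factor (the sample's median log10 intensity over proteins
   observed in every retained sample). Proteins with fewer than three
   observations are left missing. Imputed cells are flagged, never
   confused with measurements.
3. *Inclusion rules* — a protein enters a group's statistics only if
   it is present (observed or imputed) in at least half the group's
   samples and no more than half of those present values are imputed.

Protein-level abundances can also be derived from PSM tables by Hi-3
quantitation (mean of the three most intense unique peptides).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GroupManifest, IntensityMatrix, PSMTable

__all__ = [
    "InclusionDecision",
    "filter_samples",
    "impute_ols",
    "inclusion_filter",
    "included_proteins",
    "psm_to_protein",
]

MIN_UNIQUE_PROTEINS = 70
MIN_OBS_FOR_FIT = 3
PRESENCE_FRACTION = 0.5
IMPUTED_FRACTION = 0.5


def filter_samples(
    matrix: IntensityMatrix,
    min_unique_proteins: int = MIN_UNIQUE_PROTEINS,
) -> IntensityMatrix:
    """Keep samples with > ``min_unique_proteins`` observed proteins.

    The threshold is strict ("more than 70"), so a 70-protein sample is
    dropped and a 71-protein sample kept. Column order is preserved.
    Idempotent. Raises if nothing survives.
    """
    counts = matrix.values.notna().sum(axis=0)
    keep = counts.index[counts > min_unique_proteins]
    if len(keep) == 0:
        raise ValueError(
            f"sample filter removed every sample (threshold "
            f">{min_unique_proteins}); review the threshold"
        )
    return matrix.subset_samples(keep)


def impute_ols(matrix: IntensityMatrix,
               anchor_fraction: float = 1.0) -> IntensityMatrix:
    """Fill missing cells from per-protein OLS on sample loading factors.

    Loading factor of a sample = median log10 intensity over the
    anchor proteins: those observed in at least ``anchor_fraction`` of
    the retained samples (1.0 = observed everywhere; at least three
    anchors are required, else the matrix is rejected). At larger
    cohort sizes complete observation becomes rare, so pipelines
    typically relax ``anchor_fraction`` to ~0.9; the median then skips
    an anchor's few missing cells. For each protein with >= 3 observed
    values, log10(intensity) = alpha + beta * loading is fitted by
    least squares and evaluated at the missing samples' loadings; the
    prediction is back-transformed to the linear scale and flagged in
    ``imputed``. Observed cells are never altered.
    """
    values = matrix.values
    observed = values.notna()
    anchors = observed.sum(axis=1) >= anchor_fraction * matrix.n_samples
    if anchors.sum() < MIN_OBS_FOR_FIT:
        raise ValueError(
            f"only {int(anchors.sum())} fully-observed proteins; "
            f">= {MIN_OBS_FOR_FIT} needed to define loading factors"
        )
    loading = np.log10(values.loc[anchors]).median(axis=0, skipna=True)
    if loading.isna().any():
        raise ValueError("a sample has no observed anchor protein")

    out = values.copy()
    imputed = matrix.imputed.copy()
    x = loading.to_numpy()
    for pid, row in values.iterrows():
        present = row.notna().to_numpy()
        n_obs = int(present.sum())
        if n_obs < MIN_OBS_FOR_FIT or n_obs == len(row):
            continue
        y = np.log10(row.to_numpy(dtype=float)[present])
        design = np.column_stack([np.ones(n_obs), x[present]])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        pred = coef[0] + coef[1] * x[~present]
        out.loc[pid, row.index[~present]] = 10.0 ** pred
        imputed.loc[pid, row.index[~present]] = True
    return IntensityMatrix(out, imputed)


@dataclass
class InclusionDecision:
    """Whether one protein enters one group's statistics."""

    protein_id: str
    group: str
    n_observed: int
    n_imputed: int
    n_samples_in_group: int
    included: bool


def inclusion_filter(
    matrix: IntensityMatrix,
    manifest: GroupManifest,
    presence_fraction: float = PRESENCE_FRACTION,
    imputed_fraction: float = IMPUTED_FRACTION,
) -> list[InclusionDecision]:
    """Per-(protein, group) inclusion decisions.

    Included iff present (observed or imputed) in at least
    ``presence_fraction`` of the group's samples *and* the imputed
    share of the present values is at most ``imputed_fraction``. The
    two criteria are deliberately non-redundant: the first counts
    coverage, the second bounds how much of that coverage is imputed.
    """
    missing_samples = set(matrix.sample_ids) - set(manifest.sample_ids)
    if missing_samples:
        raise ValueError(
            f"samples absent from manifest: {sorted(missing_samples)[:5]}"
        )
    decisions = []
    for group in manifest.groups:
        samples = [s for s in manifest.samples_in(group)
                   if s in set(matrix.sample_ids)]
        if not samples:
            continue
        sub_vals = matrix.values[samples]
        sub_imp = matrix.imputed[samples]
        n_group = len(samples)
        present = sub_vals.notna()
        n_imp = (present & sub_imp).sum(axis=1)
        n_obs = (present & ~sub_imp).sum(axis=1)
        for pid in matrix.protein_ids:
            no, ni = int(n_obs[pid]), int(n_imp[pid])
            n_present = no + ni
            ok = (n_present >= presence_fraction * n_group
                  and n_present > 0
                  and ni <= imputed_fraction * n_present)
            decisions.append(InclusionDecision(pid, group, no, ni,
                                               n_group, ok))
    return decisions


def included_proteins(decisions: list[InclusionDecision],
                      groups: tuple[str, str]) -> list[str]:
    """Proteins included in *both* groups of a two-group comparison."""
    by_group: dict[str, set[str]] = {}
    for d in decisions:
        if d.included:
            by_group.setdefault(d.group, set()).add(d.protein_id)
    for g in groups:
        if not any(d.group == g for d in decisions):
            raise ValueError(f"group {g!r} has no inclusion decisions")
    common = by_group.get(groups[0], set()) & by_group.get(groups[1], set())
    order = {d.protein_id: i for i, d in enumerate(decisions)}
    return sorted(common, key=order.get)


def psm_to_protein(psm: PSMTable, top_n: int = 3) -> IntensityMatrix:
    """Hi-3 protein quantitation from a PSM table.

    Per (protein, sample): sum PSM intensities per bare peptide
    sequence, then average the ``top_n`` most intense peptides (all of
    them when fewer exist).
    """
    per_pep = (psm.rows.groupby(["protein_id", "sample_id", "peptide"])
               ["intensity"].sum())

    def hi_n(s: pd.Series) -> float:
        return float(s.sort_values(ascending=False).head(top_n).mean())

    agg = per_pep.groupby(level=["protein_id", "sample_id"]).agg(hi_n)
    wide = agg.unstack("sample_id")
    return IntensityMatrix(wide)
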