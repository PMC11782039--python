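"""Signed fold changes, Mann–Whitney tests, BH adjustment, DEP selection.

The fold change between a test group and the control group is the
ratio of group medians expressed as a signed value of magnitude >= 1:

    fCh = +median_test / median_control   if median_test >= median_control
    fCh = -median_control / median_test   otherwise

so +2 means doubled in the test group and -2 means halved, and
fCh(a, b) = -fCh(b, a). Group differences are tested with the
two-sided Mann–Whitney U rank test and adjusted per comparison with
the Benjamini–Hochberg step-up procedure. A protein is called
differentially expressed (DEP) when |fCh| > 1.5 with adjusted
p < 0.05 in at least one comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GroupManifest, IntensityMatrix
from .qc import InclusionDecision, included_proteins

__all__ = [
    "DEPRecord",
    "signed_fold_change",
    "mwu_test",
    "bh_adjust",
    "run_comparison",
    "run_differential",
    "select_deps",
]

FC_CUT = 1.5
P_CUT = 0.05
MIN_N = 3
EXACT_MAX_N = 8


def signed_fold_change(median_test: float, median_control: float) -> float:
    """Signed ratio of medians; positive = elevated in the test group."""
    if median_test <= 0 or median_control <= 0:
        raise ValueError(
            f"medians must be positive, got ({median_test}, {median_control})"
        )
    if median_test >= median_control:
        return median_test / median_control
    return -median_control / median_test


def mwu_test(values_test, values_control, min_n: int = MIN_N) -> float:
    """Two-sided Mann–Whitney U p-value.

    Exact enumeration when min(n) <= 8 and the pooled sample is
    tie-free; otherwise the normal approximation with midranks, tie
    correction, and continuity correction. A side with fewer than
    ``min_n`` values is untestable: NaN is returned, not raised.
    """
    x = np.asarray([v for v in values_test if not math.isnan(v)], dtype=float)
    y = np.asarray([v for v in values_control if not math.isnan(v)],
                   dtype=float)
    if len(x) < min_n or len(y) < min_n:
        return float("nan")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if has_ties and np.ptp(pooled) == 0:
        return 1.0  # all values identical: no evidence of a shift
    method = "exact" if (min(len(x), len(y)) <= EXACT_MAX_N
                         and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        bad = p[finite][(p[finite] < 0) | (p[finite] > 1)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


@dataclass
class DEPRecord:
    """Differential expression of one protein in one comparison."""

    protein_id: str
    gene: str
    comparison: tuple[str, str]  # (test group, control group)
    fold_change: float
    median_test: float
    median_control: float
    p_raw: float
    p_adj: float
    n_obs_test: int
    n_obs_control: int
    n_imputed_test: int
    n_imputed_control: int


def run_comparison(
    matrix: IntensityMatrix,
    manifest: GroupManifest,
    test_group: str,
    control_group: str,
    decisions: list[InclusionDecision],
    genes: dict[str, str] | None = None,
) -> list[DEPRecord]:
    """All DEP records for one (test vs control) comparison.

    Only proteins included in both groups are tested. Medians and
    rank tests use observed plus imputed values, consistent with the
    inclusion rules counting imputed cells as present. BH adjustment
    runs across the proteins of this comparison.
    """
    genes = genes or {}
    proteins = included_proteins(decisions, (test_group, control_group))
    t_samples = [s for s in manifest.samples_in(test_group)
                 if s in set(matrix.sample_ids)]
    c_samples = [s for s in manifest.samples_in(control_group)
                 if s in set(matrix.sample_ids)]
    records = []
    p_raw_list = []
    for pid in proteins:
        tv = matrix.values.loc[pid, t_samples].dropna()
        cv = matrix.values.loc[pid, c_samples].dropna()
        fc = signed_fold_change(float(tv.median()), float(cv.median()))
        p = mwu_test(tv.to_numpy(), cv.to_numpy())
        imp = matrix.imputed.loc[pid]
        records.append(DEPRecord(
            protein_id=pid,
            gene=genes.get(pid, ""),
            comparison=(test_group, control_group),
            fold_change=fc,
            median_test=float(tv.median()),
            median_control=float(cv.median()),
            p_raw=p,
            p_adj=float("nan"),
            n_obs_test=int(tv.notna().sum() - imp[t_samples].sum()),
            n_obs_control=int(cv.notna().sum() - imp[c_samples].sum()),
            n_imputed_test=int(imp[t_samples].sum()),
            n_imputed_control=int(imp[c_samples].sum()),
        ))
        p_raw_list.append(p)
    adj = bh_adjust(p_raw_list)
    for rec, a in zip(records, adj):
        rec.p_adj = float(a)
    return records


def run_differential(
    matrix: IntensityMatrix,
    manifest: GroupManifest,
    decisions: list[InclusionDecision],
    comparisons: list[tuple[str, str]],
    genes: dict[str, str] | None = None,
) -> dict[tuple[str, str], list[DEPRecord]]:
    """Run every configured comparison; BH is applied within each."""
    return {
        (t, c): run_comparison(matrix, manifest, t, c, decisions, genes)
        for t, c in comparisons
    }


def select_deps(
    records_by_comparison: dict[tuple[str, str], list[DEPRecord]],
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
) -> pd.DataFrame:
    """DEP table across comparisons.

    A protein is selected when, in at least one comparison, it passes
    both |fold change| > ``fc_cut`` and adjusted p < ``p_cut``. The
    report carries every comparison's fold change and adjusted p for
    the selected proteins, including the non-significant companions.
    """
    per_protein: dict[str, dict] = {}
    selected: set[str] = set()
    for (test, ctrl), records in records_by_comparison.items():
        label = f"{test}_vs_{ctrl}"
        for rec in records:
            row = per_protein.setdefault(
                rec.protein_id, {"protein_id": rec.protein_id,
                                 "gene": rec.gene})
            row[f"fc_{label}"] = rec.fold_change
            row[f"p_adj_{label}"] = rec.p_adj
            if (abs(rec.fold_change) > fc_cut
                    and not math.isnan(rec.p_adj) and rec.p_adj < p_cut):
                selected.add(rec.protein_id)
    rows = [per_protein[pid] for pid in per_protein if pid in selected]
    cols = ["protein_id", "gene"]
    if rows:
        extra = sorted(k for k in rows[0] if k not in cols)
        cols += extra
    return pd.DataFrame(rows, columns=cols)


def records_to_frame(records: list[DEPRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "protein_id": r.protein_id, "gene": r.gene,
            "test_group": r.comparison[0], "control_group": r.comparison[1],
            "fold_change": r.fold_change,
            "median_test": r.median_test,
            "median_control": r.median_control,
            "p_raw": r.p_raw, "p_adj": r.p_adj,
            "n_obs_test": r.n_obs_test, "n_obs_control": r.n_obs_control,
            "n_imputed_test": r.n_imputed_test,
            "n_imputed_control": r.n_imputed_control,
        })
    return pd.DataFrame(rows)
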