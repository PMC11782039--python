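"""PCA and sparse PLS-DA segmentation of proteomic profiles.

Unsupervised structure is summarised by PCA of the standardized
log10-intensity matrix. Supervised segmentation uses sparse partial
least-squares discriminant analysis (sPLS-DA): classes are one-hot
coded and NIPALS-style weight updates are soft-thresholded so that at
most ``keepX`` proteins carry nonzero weight per component. This is a
reimplementation of the approach popularised by the MixOmics package;
performance is reported by stratified cross-validation and one-vs-rest
ROC AUC.

Feature selection mirrors the study's convention: a protein enters
the multivariate analysis only if it was *observed* (not imputed) in
at least ``min_samples_present`` samples overall (default 20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold

from .io_formats import GroupManifest, IntensityMatrix

__all__ = [
    "FeatureSelection",
    "SparseModel",
    "ClassificationReport",
    "EllipseParams",
    "select_features",
    "prepare_matrix",
    "pca",
    "PCAResult",
    "splsda_fit",
    "splsda_predict",
    "cross_validate_splsda",
    "tune_keepx",
    "confidence_ellipse",
    "roc_auc",
]

MIN_SAMPLES_PRESENT = 20
N_COMPONENTS = 2
KEEPX_GRID = (5, 10, 20, 50)
MAX_ITER = 500
TOL = 1e-6


# ---------------------------------------------------------------------------
# Feature selection and preparation
# ---------------------------------------------------------------------------

@dataclass
class FeatureSelection:
    min_samples_present: int
    selected_protein_ids: list[str]


def select_features(
    matrix: IntensityMatrix,
    min_samples_present: int = MIN_SAMPLES_PRESENT,
) -> FeatureSelection:
    """Proteins observed (non-imputed) in >= ``min_samples_present`` samples."""
    observed = matrix.observed_mask().sum(axis=1)
    keep = [pid for pid in matrix.protein_ids
            if observed[pid] >= min_samples_present]
    return FeatureSelection(min_samples_present, keep)


def prepare_matrix(
    matrix: IntensityMatrix,
    selection: FeatureSelection,
) -> pd.DataFrame:
    """Samples x proteins matrix: log10, unit-variance z-scores, NaN -> 0.

    Missing cells that survive imputation are set to the column mean,
    which is 0 after centering.
    """
    if not selection.selected_protein_ids:
        raise ValueError("feature selection is empty")
    sub = matrix.values.loc[selection.selected_protein_ids].T
    logged = np.log10(sub)
    mean = logged.mean(axis=0, skipna=True)
    sd = logged.std(axis=0, ddof=0, skipna=True)
    sd = sd.mask(sd == 0, 1.0)
    z = (logged - mean) / sd
    return z.fillna(0.0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # proteins x components
    explained_variance_pct: np.ndarray


def pca(prepared: pd.DataFrame, n_components: int = N_COMPONENTS) -> PCAResult:
    """PCA via SVD of the column-centered matrix.

    Component sign is fixed by making the largest-magnitude loading of
    each component positive. Explained-variance percentages are
    relative to the total variance, so they sum to at most 100.
    """
    X = prepared.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("degenerate (constant) matrix")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(S))
    total = float((S ** 2).sum())
    pct = 100.0 * (S[:k] ** 2) / total
    scores = U[:, :k] * S[:k]
    load = Vt[:k].T
    for j in range(k):
        top = np.argmax(np.abs(load[:, j]))
        if load[top, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=prepared.index, columns=comp_names),
        loadings=pd.DataFrame(load, index=prepared.columns,
                              columns=comp_names),
        explained_variance_pct=pct,
    )


# ---------------------------------------------------------------------------
# sPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class SparseModel:
    """Fitted sPLS-DA model."""

    classes: list[str]
    feature_ids: list[str]
    loadings: np.ndarray            # p x k sparse weight vectors (unit norm)
    x_rotations: np.ndarray         # p x k, projects new data onto scores
    scores: pd.DataFrame            # training samples x components
    keepX: list[int]
    explained_variance_pct: np.ndarray
    class_centroids: pd.DataFrame   # classes x components
    x_mean: np.ndarray
    converged: list[bool] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _soft_threshold(w: np.ndarray, keep: int) -> np.ndarray:
    if keep >= len(w):
        return w
    a = np.abs(w)
    lam = np.partition(a, len(w) - keep - 1)[len(w) - keep - 1]
    out = np.sign(w) * np.maximum(a - lam, 0.0)
    return out


def splsda_fit(
    prepared: pd.DataFrame,
    labels,
    keepX=None,
    n_components: int = N_COMPONENTS,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> SparseModel:
    """Fit sPLS-DA by NIPALS with per-component soft-thresholding.

    Classes are one-hot coded (centered); each component iterates
    weight updates, soft-thresholding the X-weight vector to its
    ``keepX`` largest magnitudes until relative change < 1e-6 (or 500
    iterations, in which case the component is flagged unconverged).
    X and Y are deflated between components. Deterministic given the
    input order.
    """
    y = pd.Series(list(labels), index=prepared.index)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for cls in classes:
        if (y == cls).sum() < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples")
    p = prepared.shape[1]
    if keepX is None:
        keepX = [p] * n_components
    if np.isscalar(keepX):
        keepX = [int(keepX)] * n_components
    keepX = [int(k) for k in keepX]
    for k in keepX:
        if k > p:
            raise ValueError(f"keepX {k} exceeds {p} proteins")

    X = prepared.to_numpy(dtype=float).copy()
    x_mean = X.mean(axis=0)
    X = X - x_mean
    X0_ss = float((X ** 2).sum())
    Y = pd.get_dummies(y)[classes].to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((X.shape[0], n_components))
    evar = np.zeros(n_components)
    converged = []
    for comp in range(n_components):
        u = Y[:, np.argmax(Y.var(axis=0))].copy()
        w_old = np.zeros(p)
        ok = False
        for _ in range(max_iter):
            w = X.T @ u
            w = _soft_threshold(w, keepX[comp])
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("all weights thresholded to zero")
            w /= norm
            t = X @ w
            c = Y.T @ t / (t @ t)
            u = Y @ c / (c @ c)
            if np.linalg.norm(w - w_old) < tol:
                ok = True
                break
            w_old = w
        converged.append(ok)
        t = X @ w
        p_load = X.T @ t / (t @ t)
        c = Y.T @ t / (t @ t)
        evar[comp] = 100.0 * float((np.outer(t, p_load) ** 2).sum()) / X0_ss
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, c)
        W[:, comp] = w
        P[:, comp] = p_load
        T[:, comp] = t

    rotations = W @ np.linalg.pinv(P.T @ W)
    scores = pd.DataFrame(T, index=prepared.index,
                          columns=[f"comp{j + 1}" for j in range(n_components)])
    centroids = scores.groupby(y).mean().loc[classes]
    return SparseModel(
        classes=classes,
        feature_ids=list(prepared.columns),
        loadings=W,
        x_rotations=rotations,
        scores=scores,
        keepX=keepX,
        explained_variance_pct=evar,
        class_centroids=centroids,
        x_mean=x_mean,
        converged=converged,
    )


def splsda_predict(model: SparseModel, new_samples: pd.DataFrame
                   ) -> tuple[pd.Series, pd.DataFrame]:
    """Assign new samples to the nearest class centroid in score space.

    Ties break deterministically to the lexicographically smaller
    label. Returns (labels, scores).
    """
    if list(new_samples.columns) != model.feature_ids:
        if set(new_samples.columns) != set(model.feature_ids):
            raise ValueError("feature set mismatch with fitted model")
        new_samples = new_samples[model.feature_ids]
    X = new_samples.to_numpy(dtype=float) - model.x_mean
    T = X @ model.x_rotations
    scores = pd.DataFrame(T, index=new_samples.index,
                          columns=model.scores.columns)
    cent = model.class_centroids.to_numpy()
    d = np.linalg.norm(T[:, None, :] - cent[None, :, :], axis=2)
    # classes are sorted, so argmin's first-hit rule is the lexicographic tie-break
    idx = np.argmin(np.round(d, 12), axis=1)
    labels = pd.Series([model.classes[i] for i in idx],
                       index=new_samples.index)
    return labels, scores


@dataclass
class ClassificationReport:
    roc_curves: dict          # class -> (fpr, tpr, thresholds)
    auc: dict                 # class -> float
    accuracy: float | None = None
    confusion: pd.DataFrame | None = None
    fold_assignments: pd.Series | None = None
    seed: int | None = None


def cross_validate_splsda(
    prepared: pd.DataFrame,
    labels,
    keepX=None,
    n_components: int = N_COMPONENTS,
    n_folds: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified M-fold cross-validated accuracy and per-class ROC AUC.

    The fold seed is part of the signature: the same seed reproduces
    the same fold assignment and therefore the same report.
    """
    y = pd.Series(list(labels), index=prepared.index)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = pd.Series(index=prepared.index, dtype=object)
    folds = pd.Series(index=prepared.index, dtype=int)
    classes = sorted(y.unique())
    score_frames = []
    for fold, (tr, te) in enumerate(skf.split(prepared, y)):
        model = splsda_fit(prepared.iloc[tr], y.iloc[tr], keepX=keepX,
                           n_components=n_components)
        lab, sc = splsda_predict(model, prepared.iloc[te])
        pred.iloc[te] = lab.to_numpy()
        folds.iloc[te] = fold
        cent = model.class_centroids.to_numpy()
        d = np.linalg.norm(sc.to_numpy()[:, None, :] - cent[None, :, :],
                           axis=2)
        score_frames.append(pd.DataFrame(-d, index=sc.index,
                                         columns=model.classes))
    class_scores = pd.concat(score_frames).loc[prepared.index]
    acc = float((pred == y).mean())
    conf = pd.DataFrame(
        confusion_matrix(y, pred, labels=classes),
        index=classes, columns=classes,
    )
    report = roc_auc(y, class_scores)
    report.accuracy = acc
    report.confusion = conf
    report.fold_assignments = folds
    report.seed = seed
    return report


def tune_keepx(
    prepared: pd.DataFrame,
    labels,
    grid=KEEPX_GRID,
    n_components: int = N_COMPONENTS,
    n_folds: int = 5,
    seed: int = 0,
) -> int:
    """Pick keepX from ``grid`` by CV balanced accuracy (ties -> smaller)."""
    y = pd.Series(list(labels), index=prepared.index)
    best, best_score = None, -np.inf
    for k in sorted(k for k in grid if k <= prepared.shape[1]):
        rep = cross_validate_splsda(prepared, y, keepX=k,
                                    n_components=n_components,
                                    n_folds=n_folds, seed=seed)
        conf = rep.confusion.to_numpy()
        with np.errstate(invalid="ignore"):
            recalls = np.diag(conf) / conf.sum(axis=1)
        bal = float(np.nanmean(recalls))
        if bal > best_score + 1e-12:
            best, best_score = k, bal
    if best is None:
        raise ValueError("keepX grid has no feasible entry")
    return best


# ---------------------------------------------------------------------------
# Confidence ellipses and ROC
# ---------------------------------------------------------------------------

@dataclass
class EllipseParams:
    center: np.ndarray
    semi_axes: np.ndarray   # descending
    angle_deg: float        # orientation of the major axis
    level: float
    degenerate: bool = False


def confidence_ellipse(scores_2d, level: float = 0.95) -> EllipseParams:
    """Normal-theory confidence ellipse of a 2-D score cloud.

    Semi-axes are sqrt(eigenvalue * chi2_2(level)); with level 0 the
    ellipse collapses to the class mean. A singular covariance flags
    the result degenerate rather than raising.
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be n x 2")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 samples for an ellipse")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = bool(evals[-1] <= 1e-12)
    q = stats.chi2.ppf(level, df=2) if level > 0 else 0.0
    semi = np.sqrt(np.maximum(evals, 0.0) * q)
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return EllipseParams(center=center, semi_axes=semi, angle_deg=angle,
                         level=level, degenerate=degenerate)


def roc_auc(y_true, class_scores: pd.DataFrame) -> ClassificationReport:
    """One-vs-rest ROC per class; AUC by the trapezoidal rule.

    ``class_scores`` has one column per class with higher = more
    class-like; score ties are handled by the averaged (midrank)
    convention of the underlying curve construction.
    """
    y = pd.Series(list(y_true))
    if y.nunique() < 2:
        raise ValueError("ROC needs at least 2 classes in y_true")
    curves, aucs = {}, {}
    for cls in class_scores.columns:
        truth = (y.to_numpy() == cls).astype(int)
        fpr, tpr, thr = roc_curve(truth, class_scores[cls].to_numpy())
        curves[cls] = (fpr, tpr, thr)
        aucs[cls] = float(_trapezoid_auc(fpr, tpr))
    return ClassificationReport(roc_curves=curves, auc=aucs)
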