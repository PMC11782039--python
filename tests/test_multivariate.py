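"""PCA/sPLS-DA against independent oracles; ellipse and ROC geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from plasmapipe.io_formats import GroupManifest, IntensityMatrix
from plasmapipe.multivariate import (
    confidence_ellipse,
    cross_validate_splsda,
    pca,
    prepare_matrix,
    roc_auc,
    select_features,
    splsda_fit,
    splsda_predict,
)


def _frame(arr, prefix="p"):
    return pd.DataFrame(np.asarray(arr, dtype=float),
                        columns=[f"{prefix}{i}" for i in
                                 range(np.asarray(arr).shape[1])])


class TestPrepareMatrix:
    @staticmethod
    def _matrix_with_presence(counts, n_samples=30):
        rng = np.random.default_rng(1)
        cols = [f"s{i}" for i in range(n_samples)]
        vals, imp = {}, {}
        for j, c in enumerate(counts):
            v = rng.lognormal(10, 1, n_samples)
            v[c:] = np.nan
            vals[f"P{j}"] = v
            imp[f"P{j}"] = np.zeros(n_samples, dtype=bool)
        return IntensityMatrix(pd.DataFrame(vals, index=cols).T)

    def test_presence_threshold_inclusive(self):
        m = self._matrix_with_presence([19, 20, 25, 30])
        sel = select_features(m, min_samples_present=20)
        assert sel.selected_protein_ids == ["P1", "P2", "P3"]

    def test_hand_counted_selection(self):
        counts = [5, 10, 19, 20, 21, 30] * 5
        m = self._matrix_with_presence(counts)
        sel = select_features(m, min_samples_present=20)
        assert len(sel.selected_protein_ids) == 3 * 5

    def test_columns_standardized(self):
        m = self._matrix_with_presence([30, 30, 25])
        sel = select_features(m, min_samples_present=20)
        X = prepare_matrix(m, sel)
        obs = ~m.values.loc[sel.selected_protein_ids].T.isna()
        for col in X.columns:
            vals = X.loc[obs[col], col]
            assert vals.mean() == pytest.approx(0.0, abs=1e-9)
            assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_missing_cells_become_zero(self):
        m = self._matrix_with_presence([30, 25])
        sel = select_features(m, min_samples_present=20)
        X = prepare_matrix(m, sel)
        assert (X.loc[m.values.loc["P1"].isna(), "P1"] == 0).all()

    def test_empty_selection_rejected(self):
        m = self._matrix_with_presence([5])
        sel = select_features(m, min_samples_present=20)
        with pytest.raises(ValueError):
            prepare_matrix(m, sel)


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(-1, 1, 10)
        X = _frame(np.column_stack([t, 2 * t, -t]))
        res = pca(X, n_components=2)
        assert res.explained_variance_pct[0] == pytest.approx(100.0)
        assert res.explained_variance_pct[1] == pytest.approx(0.0, abs=1e-9)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(2)
        X = _frame(rng.normal(size=(15, 6)))
        res = pca(X, n_components=4)
        g = res.scores.to_numpy().T @ res.scores.to_numpy()
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.normal(size=(10, 6)))
        res = pca(X, n_components=6)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        evals = np.linalg.eigvalsh(Xc.T @ Xc)[::-1]
        pct = 100 * evals / evals.sum()
        np.testing.assert_allclose(res.explained_variance_pct, pct[:6],
                                   atol=1e-8)
        # scores reproduce the projection onto the eigenvectors up to sign
        _, evecs = np.linalg.eigh(Xc.T @ Xc)
        evecs = evecs[:, ::-1]
        proj = Xc @ evecs
        for j in range(6):
            s = res.scores.to_numpy()[:, j]
            assert (np.abs(s - proj[:, j]).max() < 1e-8
                    or np.abs(s + proj[:, j]).max() < 1e-8)

    def test_constant_matrix_rejected(self):
        X = _frame(np.ones((5, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            pca(X)


class TestSPLSDA:
    def test_dense_limit_matches_unpenalized_oracles(self):
        rng = np.random.default_rng(4)
        X = _frame(rng.normal(size=(30, 12)))
        y = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        model = splsda_fit(X, y, keepX=12, n_components=2, tol=1e-12,
                           max_iter=20000)
        Y = pd.get_dummies(pd.Series(y)).to_numpy(float)
        Y = Y - Y.mean(axis=0)
        # exact oracle: dominant left singular vector of X'Y per
        # component, with standard PLS deflation in between
        Xd = X.to_numpy() - X.to_numpy().mean(axis=0)
        Yd = Y.copy()
        for c in range(2):
            ref = np.linalg.svd(Xd.T @ Yd, full_matrices=False)[0][:, 0]
            w = model.loadings[:, c]
            sign = np.sign(w @ ref)
            assert np.abs(w - sign * ref).max() < 1e-6
            t = Xd @ ref
            Yd = Yd - np.outer(t, Yd.T @ t / (t @ t))
            Xd = Xd - np.outer(t, Xd.T @ t / (t @ t))
        # second opinion: an independent NIPALS implementation
        pls = PLSRegression(n_components=2, scale=False, tol=1e-12,
                            max_iter=20000).fit(
            X.to_numpy() - X.to_numpy().mean(axis=0), Y)
        for c in range(2):
            w = model.loadings[:, c]
            ref = pls.x_weights_[:, c]
            ref = ref / np.linalg.norm(ref)
            sign = np.sign(w @ ref)
            assert np.abs(w - sign * ref).max() < 1e-4

    def test_keepx_bounds_support(self):
        rng = np.random.default_rng(5)
        X = _frame(rng.normal(size=(40, 50)))
        y = ["A"] * 20 + ["B"] * 20
        model = splsda_fit(X, y, keepX=7, n_components=2)
        for c in range(2):
            assert np.count_nonzero(model.loadings[:, c]) <= 7
            assert np.linalg.norm(model.loadings[:, c]) == pytest.approx(1.0)

    def test_informative_support_recovered(self):
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 100))
            y = np.array(["A"] * 30 + ["B"] * 30)
            X[y == "B", :10] += 1.2
            model = splsda_fit(_frame(X), y, keepX=10, n_components=1)
            sel = set(np.flatnonzero(model.loadings[:, 0]))
            hits.append(len(sel & set(range(10))))
        assert np.median(hits) >= 8

    def test_loadings_invariant_under_sample_reorder(self):
        rng = np.random.default_rng(6)
        X = _frame(rng.normal(size=(24, 15)))
        y = pd.Series(["A"] * 8 + ["B"] * 8 + ["C"] * 8, index=X.index)
        m1 = splsda_fit(X, y, keepX=5)
        perm = rng.permutation(len(X))
        m2 = splsda_fit(X.iloc[perm], y.iloc[perm], keepX=5)
        for c in range(2):
            a, b = m1.loadings[:, c], m2.loadings[:, c]
            sign = np.sign(a @ b) or 1.0
            assert np.abs(a - sign * b).max() < 1e-6

    def test_excessive_keepx_rejected(self):
        X = _frame(np.random.default_rng(7).normal(size=(12, 4)))
        y = ["A"] * 6 + ["B"] * 6
        with pytest.raises(ValueError, match="keepX"):
            splsda_fit(X, y, keepX=10)

    def test_separable_training_data_repredicted_perfectly(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 20))
        y = np.array(["A"] * 15 + ["B"] * 15)
        X[y == "B", :5] += 5.0
        Xdf = _frame(X)
        model = splsda_fit(Xdf, y, keepX=5)
        labels, _ = splsda_predict(model, Xdf)
        assert (labels.to_numpy() == y).all()

    def test_midpoint_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 10))
        y = np.array(["A"] * 10 + ["B"] * 10)
        X[y == "B", 0] += 4.0
        Xdf = _frame(X)
        model = splsda_fit(Xdf, y, keepX=10)
        mid = model.class_centroids.mean(axis=0).to_numpy()
        # craft a sample whose score lands exactly between the centroids
        rot = model.x_rotations
        sample, *_ = np.linalg.lstsq(rot.T, mid, rcond=None)
        probe = pd.DataFrame([sample + model.x_mean], columns=Xdf.columns)
        labels, scores = splsda_predict(model, probe)
        d = np.linalg.norm(scores.to_numpy()[0]
                           - model.class_centroids.to_numpy(), axis=1)
        assert d[0] == pytest.approx(d[1], abs=1e-9)
        assert labels.iloc[0] == "A"

    def test_permuted_labels_give_chance_accuracy(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(30 + seed)
            X = _frame(rng.normal(size=(60, 40)))
            y = pd.Series(["A", "B", "C"] * 20).sample(
                frac=1, random_state=seed).reset_index(drop=True)
            y.index = X.index
            rep = cross_validate_splsda(X, y, keepX=10, seed=seed)
            accs.append(rep.accuracy)
        assert abs(np.median(accs) - 1 / 3) <= 0.10


class TestConfidenceEllipse:
    def test_isotropic_radius_is_chi2_quantile(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(4000, 2))
        ell = confidence_ellipse(pts, level=0.95)
        expected = np.sqrt(stats.chi2.ppf(0.95, 2))  # ~2.448
        assert ell.semi_axes[0] == pytest.approx(expected, rel=0.05)
        assert ell.semi_axes[1] == pytest.approx(expected, rel=0.05)

    def test_level_zero_degenerates_to_point(self):
        pts = np.random.default_rng(11).normal(size=(50, 2))
        ell = confidence_ellipse(pts, level=0.0)
        assert np.allclose(ell.semi_axes, 0.0)

    def test_axes_align_with_principal_directions(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(500, 2)) * np.array([3.0, 0.5])
        theta = np.radians(30)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        pts = base @ rot.T
        ell = confidence_ellipse(pts)
        angle = ell.angle_deg % 180
        assert min(abs(angle - 30), abs(angle - 210 % 180)) < 5

    def test_singular_covariance_flagged(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        ell = confidence_ellipse(pts)
        assert ell.degenerate


class TestROCAUC:
    def test_perfect_ordering_auc_one(self):
        scores = pd.DataFrame({"pos": [0.9, 0.8, 0.2, 0.1]})
        rep = roc_auc(["pos", "pos", "neg", "neg"], scores)
        assert rep.auc["pos"] == pytest.approx(1.0)

    def test_hand_example_point_seven_five(self):
        scores = pd.DataFrame({"pos": [0.9, 0.8, 0.4, 0.2]})
        rep = roc_auc(["pos", "neg", "pos", "neg"], scores)
        assert rep.auc["pos"] == pytest.approx(0.75)

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(13)
        labels = rng.choice(["pos", "neg"], size=1000)
        scores = pd.DataFrame({"pos": rng.normal(size=1000)})
        rep = roc_auc(labels, scores)
        assert rep.auc["pos"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(["pos", "pos"], pd.DataFrame({"pos": [0.1, 0.2]}))
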