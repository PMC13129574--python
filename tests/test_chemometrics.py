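"""PCA, PLS, LOOCV and the pretreatment sweep, checked against independent oracles."""

import numpy as np
import pytest

from leafspec import preprocess
from leafspec.chemometrics import (
    factor_loading,
    loocv,
    pca,
    pls_fit,
    split_predict,
    sweep,
)
from leafspec.synth import (
    LeafDesign,
    gen_cluster_expression,
    gen_leaf_spectra,
    leaf_spectroscopy_design,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


class TestPCA:
    def test_collinear_points_explained_by_first_component(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([2 * t, -3 * t])
        res = pca(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_reconstruction_of_centered_matrix(self, rng):
        X = rng.normal(size=(15, 6))
        res = pca(X)
        np.testing.assert_allclose(
            res.scores @ res.loadings.T, X - X.mean(axis=0), atol=1e-10
        )

    def test_eigenvalues_match_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(20, 6))
        res = pca(X)
        ev = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(res.singular_values**2 / 19, ev, atol=1e-8)

    def test_autoscaled_pca_equals_correlation_eigendecomposition(self, rng):
        X = rng.normal(size=(25, 5)) * np.array([1, 10, 0.1, 5, 2])
        res = pca(X, scaling=True)
        ev = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(res.singular_values**2 / 24, ev, atol=1e-8)

    def test_matches_reference_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = rng.normal(size=(18, 7))
        res = pca(X)
        ref = sklearn.PCA().fit(X)
        np.testing.assert_allclose(
            res.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(res.loadings.T), np.abs(ref.components_), atol=1e-8
        )

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.normal(size=(12, 5))
        res = pca(X)
        for k in range(res.loadings.shape[1]):
            j = np.argmax(np.abs(res.loadings[:, k]))
            assert res.loadings[j, k] > 0

    def test_explained_ratios_nonincreasing_and_sum_to_one(self, rng):
        res = pca(rng.normal(size=(30, 8)))
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() == pytest.approx(1.0)


class TestFactorLoading:
    def test_rank_one_data_fully_correlated(self):
        t = np.linspace(-1, 1, 12)
        X = np.outer(t, [1.0, -2.0, 0.5])
        res = pca(X)
        corr, undef = factor_loading(X, res, 0)
        assert not undef.any()
        np.testing.assert_allclose(np.abs(corr), 1.0, atol=1e-10)

    def test_orthogonal_variable_uncorrelated(self):
        t = np.array([1.0, -1.0, 1.0, -1.0])
        u = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.column_stack([t, u])
        corr, _ = factor_loading(X, t[:, None] * np.array([1.0]), 0)
        assert corr[1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_variable_flagged_not_dropped(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 4.2
        corr, undef = factor_loading(X, pca(X[:, [0, 2]]), 0)
        assert undef.tolist() == [False, True, False]
        assert np.isnan(corr[1]) and np.isfinite(corr[[0, 2]]).all()

    def test_planted_window_variables_load_stronger(self, coarse_grid):
        """Variables inside the planted pigment/red-edge windows correlate
        more with PC1 than variables far outside them."""
        s, truth = gen_leaf_spectra(leaf_spectroscopy_design(), coarse_grid, seed=8)
        spec = preprocess.spec_by_name("SG1")
        X = preprocess.apply_rows(s.values, spec)
        Xc, _ = preprocess.center_scale(X, scaling=False)
        res = pca(Xc, pre_centered=True)
        corr, _ = factor_loading(Xc, res, 0)
        lam = s.grid.trim((spec.window - 1) // 2).values
        inside = (lam >= 675) & (lam <= 765)
        outside = (lam >= 2200) & (lam <= 2400)  # no planted effects there
        contrast = np.median(np.abs(corr[inside])) - np.median(np.abs(corr[outside]))
        assert contrast > 0.3


class TestPLS:
    def test_exact_recovery_when_y_in_column_space(self, rng):
        X = rng.normal(size=(20, 4))
        b = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ b
        model = pls_fit(X, y, n_components=4)
        resid = y - model.predict(X)
        assert np.abs(resid).max() < 1e-8

    def test_single_column_equals_ordinary_least_squares(self, rng):
        x = rng.normal(size=(15, 1))
        y = 2.0 + 3.0 * x[:, 0] + rng.normal(0, 0.1, 15)
        model = pls_fit(x, y, n_components=1)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        new = rng.normal(size=(5, 1))
        np.testing.assert_allclose(
            model.predict(new), slope * new[:, 0] + intercept, atol=1e-10
        )

    def test_scores_pairwise_orthogonal(self, rng):
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        model = pls_fit(X, y, n_components=5)
        gram = model.scores.T @ model.scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-10)

    def test_simpls_and_nipals_agree_for_univariate_response(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        a = pls_fit(X, y, 4, algorithm="simpls")
        b = pls_fit(X, y, 4, algorithm="nipals")
        new = rng.normal(size=(6, 8))
        for k in range(1, 5):
            np.testing.assert_allclose(
                a.predict(new, k), b.predict(new, k), atol=1e-8
            )

    def test_matches_reference_implementation(self, rng):
        cross = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 12))
        y = X[:, 0] - 2 * X[:, 5] + rng.normal(0, 0.2, 30)
        model = pls_fit(X, y, 3)
        ref = cross.PLSRegression(n_components=3, scale=False).fit(X, y)
        new = rng.normal(size=(7, 12))
        np.testing.assert_allclose(
            model.predict(new), ref.predict(new).ravel(), atol=1e-8
        )

    def test_full_rank_pls_equals_least_squares_fit(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = pls_fit(X, y, 5)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(model.coef, beta, atol=1e-8)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            pls_fit(rng.normal(size=(10, 3)), np.ones(10), 2)


class TestLOOCV:
    def test_predictions_equal_naive_per_fold_refits(self, rng):
        """Dual route: every fold refit independently with the reference PLS."""
        cross = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(20, 6))
        y = X[:, 1] + rng.normal(0, 0.3, 20)
        entry = loocv(X, y, spec=None, max_components=3)
        for a in range(1, 4):
            press = 0.0
            for i in range(20):
                keep = np.arange(20) != i
                ref = cross.PLSRegression(n_components=a, scale=False).fit(
                    X[keep], y[keep]
                )
                press += (y[i] - ref.predict(X[i : i + 1]).ravel()[0]) ** 2
            sst = ((y - y.mean()) ** 2).sum()
            assert entry.r2_by_ncomp[a - 1] == pytest.approx(1 - press / sst, abs=1e-8)

    def test_pure_noise_response_has_nonpositive_r2_on_average(self):
        r2s = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 10))
            y = rng.normal(size=30)
            entry = loocv(X, y, spec=None, max_components=2)
            r2s.append(entry.r2_by_ncomp[1])
        assert np.mean(r2s) < 0.05

    def test_noiseless_planted_signal_approaches_perfect_r2(self, coarse_grid):
        design = leaf_spectroscopy_design()
        s, truth = gen_leaf_spectra(design, coarse_grid, seed=3, noise_sd=0.0)
        y = truth.latent_growth
        entry = loocv(
            s, y + 0.0, spec=preprocess.spec_by_name("smoothing"), max_components=5
        )
        assert entry.best_r2 > 0.999

    def test_r2_invariant_to_affine_response_transform(self, rng):
        X = rng.normal(size=(18, 5))
        y = X[:, 0] + rng.normal(0, 0.5, 18)
        a = loocv(X, y, spec=None, max_components=3)
        b = loocv(X, 4.2 * y - 17.0, spec=None, max_components=3)
        np.testing.assert_allclose(a.r2_by_ncomp, b.r2_by_ncomp, atol=1e-10)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            loocv(rng.normal(size=(2, 4)), np.arange(2.0), spec=None)


class TestSplitPredict:
    @staticmethod
    def _datasets(seed=0, **expr_kw):
        design = leaf_spectroscopy_design()
        grid_kw = {}
        from leafspec.containers import WavelengthGrid

        grid = WavelengthGrid.spanning(400.0, 2499.5, 5.0)
        s, st_ = gen_leaf_spectra(design, grid, seed=seed)
        e, et = gen_cluster_expression(design, n_clusters=9, seed=seed + 1, **expr_kw)
        return s, e, et

    def test_study_split_row_counts(self):
        s, e, _ = self._datasets()
        is_test = (
            (s.meta["field"] == "alluvial") & s.meta["dat"].isin((21, 35, 49, 63, 77))
        ).to_numpy()
        assert is_test.sum() == 20  # 4 cultivars x 5 held-out DATs
        assert (~is_test).sum() == 52  # 36 andosol + 16 alluvial training rows
        spec = preprocess.spec_by_name("SG2 + scaling")
        pred = split_predict(s.select(~is_test), e.select(~is_test), s.select(is_test), spec)
        assert len(pred) == 20 * 9

    def test_overlapping_sample_ids_rejected(self):
        s, e, _ = self._datasets()
        spec = preprocess.spec_by_name("smoothing")
        with pytest.raises(ValueError, match="overlap"):
            split_predict(s, e, s, spec)

    def test_memorisation_sanity_check(self):
        """Test rows copied from training rows reproduce the fitted values."""
        s, e, _ = self._datasets()
        half = np.arange(s.n_samples) < 36
        train_s, train_e = s.select(half), e.select(half)
        clone = train_s.select(np.ones(36, dtype=bool))
        clone.meta["sample_id"] = [f"T{i}" for i in range(36)]
        spec = preprocess.spec_by_name("SG2 + scaling")
        pred = split_predict(train_s, train_e, clone, spec, n_components=3)
        Xr = preprocess.apply_rows(train_s.values, spec)
        Xc, stats = preprocess.center_scale(Xr, scaling=True)
        for j, cluster in enumerate(train_e.clusters):
            model = pls_fit(Xc, train_e.values[:, j], 3)
            fitted = model.predict(Xc)
            got = pred.query("cluster == @cluster")["predicted"].to_numpy()
            np.testing.assert_allclose(got, fitted, atol=1e-10)

    def test_subspecies_difference_sign_reproduced(self):
        """Clusters with a planted indica-vs-japonica offset keep its sign in
        the held-out predictions for most seeds."""
        hits = 0
        for seed in range(10):
            s, e, et = self._datasets(seed=10 + seed, subspecies_every=1)
            is_test = (
                (s.meta["field"] == "alluvial")
                & s.meta["dat"].isin((21, 35, 49, 63, 77))
            ).to_numpy()
            spec = preprocess.spec_by_name("SG2 + scaling")
            pred = split_predict(
                s.select(~is_test), e.select(~is_test), s.select(is_test), spec
            )
            test_meta = s.select(is_test).meta
            indica = dict(
                zip(test_meta["sample_id"], test_meta["subspecies"] == "indica")
            )
            pred["indica"] = pred["sample_id"].map(indica)
            cluster = et.cluster_truth.query("subspecies_offset > 0").cluster.iloc[0]
            sub = pred.query("cluster == @cluster")
            diff = (
                sub[sub.indica]["predicted"].mean()
                - sub[~sub.indica]["predicted"].mean()
            )
            hits += diff > 0
        assert hits >= 9


class TestSweep:
    @staticmethod
    def _small(seed=0):
        from leafspec.containers import WavelengthGrid

        design = leaf_spectroscopy_design()
        grid = WavelengthGrid.spanning(400.0, 2499.5, 10.0)
        s, _ = gen_leaf_spectra(design, grid, seed=seed)
        e, et = gen_cluster_expression(design, n_clusters=6, seed=seed + 1)
        return preprocess.to_absorbance(s), e, et

    def test_report_covers_full_grid(self):
        a, e, _ = self._small()
        specs = preprocess.registry()[:4]
        report = sweep(a, e, specs, max_components=4)
        assert len(report) == 4 * 6
        assert set(report["pretreatment"]) == {s.name for s in specs}

    def test_flat_noisy_clusters_predict_much_worse_than_monotone(self):
        a, e, et = self._small(seed=5)
        specs = [preprocess.spec_by_name("SG2 + scaling")]
        report = sweep(a, e, specs, max_components=6)
        merged = report.merge(
            et.cluster_truth, left_on="cluster", right_on="cluster"
        )
        flat = merged.query("archetype == 'flat_noisy'")["r2"].median()
        mono = merged.query("archetype != 'flat_noisy'")["r2"].median()
        assert mono - flat > 0.3

    def test_duplicate_spec_gives_identical_rows(self):
        a, e, _ = self._small()
        spec = preprocess.spec_by_name("SG1")
        report = sweep(a, e, [spec, spec], max_components=3)
        first = report.iloc[:6]["r2"].to_numpy()
        second = report.iloc[6:]["r2"].to_numpy()
        np.testing.assert_array_equal(first, second)
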