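import numpy as np
import pytest

from aqualeaf import (
    correlation_spectrum,
    fit_pls,
    grouped_cv,
    important_bands,
    leave_one_group_out,
    predict,
)


class TestFitPls:
    def test_single_latent_direction_recovered_with_one_factor(self, rng):
        t = rng.standard_normal(30)
        p = rng.standard_normal(8)
        X = np.outer(t, p)
        y = X @ rng.standard_normal(8)
        m = fit_pls(X, y, 1)
        np.testing.assert_allclose(predict(m, X), y, atol=1e-10)

    def test_full_factor_model_matches_ols(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        m = fit_pls(X, y, 5)
        Xc = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(predict(m, X), Xc @ beta, atol=1e-8)

    def test_matches_sklearn_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((40, 12))
        y = X @ rng.standard_normal(12) + 0.1 * rng.standard_normal(40)
        m = fit_pls(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(
            m.regression_vector, ref.coef_.ravel(), atol=1e-8
        )

    def test_constant_y_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="variance"):
            fit_pls(X, np.ones(10), 2)

    def test_too_many_factors_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        y = rng.standard_normal(6)
        with pytest.raises(ValueError, match="n_factors"):
            fit_pls(X, y, 4)


class TestPredict:
    def test_mean_input_predicts_mean_response(self, rng):
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        m = fit_pls(X, y, 2)
        assert predict(m, X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean(), abs=1e-12
        )

    def test_duplicated_row_duplicated_prediction(self, rng):
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        m = fit_pls(X, y, 3)
        two = predict(m, np.vstack([X[0], X[0]]))
        assert two[0] == two[1]

    def test_scores_based_reconstruction(self, rng):
        X = rng.standard_normal((25, 7))
        y = X @ rng.standard_normal(7) + 0.05 * rng.standard_normal(25)
        m = fit_pls(X, y, 4)
        # recompute predictions through the sequential score decomposition
        Xd = X - m.x_mean
        yhat = np.full(25, m.y_mean)
        for a in range(m.n_factors):
            t = Xd @ m.weights[:, a]
            yhat += m.y_loadings[a] * t
            Xd = Xd - np.outer(t, m.x_loadings[:, a])
        np.testing.assert_allclose(predict(m, X), yhat, atol=1e-10)

    def test_band_count_mismatch_raises(self, rng):
        X = rng.standard_normal((10, 5))
        m = fit_pls(X, rng.standard_normal(10), 2)
        with pytest.raises(ValueError, match="bands"):
            predict(m, rng.standard_normal((3, 4)))


class TestGroupedCv:
    def test_partition_never_splits_a_group(self):
        groups = np.array(["a", "b", "a", "c", "b", "c", "c"])
        folds = leave_one_group_out(groups)
        assert len(folds) == 3
        for train, test in folds:
            assert set(groups[test]) .isdisjoint(set(groups[train]))
            assert len(np.intersect1d(train, test)) == 0
        covered = np.sort(np.concatenate([t for _, t in folds]))
        np.testing.assert_array_equal(covered, np.arange(7))

    def test_loo_on_noiseless_linear_data_is_exact(self, rng):
        X = rng.standard_normal((12, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 4.0
        rep = grouped_cv(X, y, np.arange(12), max_factors=3)
        assert rep.n_factors == 3
        assert rep.secv < 1e-6
        assert rep.r2cv > 1.0 - 1e-9

    def test_row_order_invariance(self, rng):
        X = rng.standard_normal((30, 6))
        y = X @ rng.standard_normal(6) + 0.2 * rng.standard_normal(30)
        groups = np.repeat(np.arange(10), 3)
        rep1 = grouped_cv(X, y, groups, max_factors=4)
        perm = rng.permutation(30)
        rep2 = grouped_cv(X[perm], y[perm], groups[perm], max_factors=4)
        np.testing.assert_allclose(rep2.secv_curve, rep1.secv_curve, atol=1e-10)
        assert rep2.n_factors == rep1.n_factors

    def test_single_group_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError):
            grouped_cv(X, rng.standard_normal(5), np.zeros(5), 2)

    def test_secv_within_band_of_generator_irreducible_error(
        self, default_experiments
    ):
        from aqualeaf import SgConfig, select_wavelength_range, sg_derivative, subset
        from aqualeaf.synthetic import irreducible_day_rmse

        ratios = []
        for seed, (sset, truth) in default_experiments.items():
            for line in ("tolerant", "sensitive"):
                stress = subset(
                    sset, f"line_label == '{line}' and treatment == 'stress'"
                )
                d = select_wavelength_range(
                    sg_derivative(stress, SgConfig()), 1300, 1600
                )
                y = d.meta["day"].to_numpy(float)
                gid = (
                    d.meta["plant_id"].astype(str)
                    + "|" + d.meta["leaf_index"].astype(str)
                    + "|" + d.meta["day"].astype(str)
                ).to_numpy()
                rep = grouped_cv(d.absorbance, y, gid, max_factors=10)
                ratios.append(rep.secv / irreducible_day_rmse(truth.config, line))
        assert all(0.8 <= r <= 1.5 for r in ratios)


class TestCorrelationSpectrum:
    def test_band_equal_to_y_has_unit_correlation(self, rng):
        X = rng.standard_normal((50, 4))
        y = X[:, 2].copy()
        r = correlation_spectrum(X, y)
        assert r[2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_band_loop(self, rng):
        X = rng.standard_normal((40, 10))
        y = rng.standard_normal(40)
        r = correlation_spectrum(X, y)
        loop = np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(10)])
        np.testing.assert_allclose(r, loop, atol=1e-12)

    def test_independent_noise_is_uncorrelated(self, rng):
        X = rng.standard_normal((1000, 20))
        y = rng.standard_normal(1000)
        assert np.max(np.abs(correlation_spectrum(X, y))) < 0.1

    def test_zero_variance_band_warns_and_returns_zero(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 1] = 2.5
        with pytest.warns(UserWarning, match="zero-variance"):
            r = correlation_spectrum(X, rng.standard_normal(30))
        assert r[1] == 0.0


class TestImportantBands:
    def test_dominant_coefficient_ranks_first(self, rng):
        X = rng.standard_normal((40, 5))
        y = 10.0 * X[:, 3] + 0.01 * rng.standard_normal(40)
        m = fit_pls(X, y, 2, wavelengths=np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        top = important_bands(m, 1)
        assert top[0][0] == 4.0

    def test_top_k_clipped_with_warning(self, rng):
        X = rng.standard_normal((20, 3))
        m = fit_pls(X, X @ np.ones(3), 2)
        with pytest.warns(UserWarning, match="clip"):
            assert len(important_bands(m, 10)) == 3

    def test_all_zero_vector_warns_empty(self):
        from aqualeaf.chemometrics import PlsModel

        m = PlsModel(1, np.zeros(4), 0.0, np.zeros((4, 1)), np.zeros((4, 1)),
                     np.zeros(1), np.zeros(4))
        with pytest.warns(UserWarning, match="zero"):
            assert important_bands(m, 2) == []
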