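import numpy as np
import pandas as pd
import pytest

from soyspec import (
    fit_pls1, predict, loo_cv, diagnostics, explained_variance, train_pls,
    PLSModel,
)
from soyspec.errors import DataError, DegenerateInputError, ParameterError
from soyspec.preprocess import regression_recipe
from soyspec.regression import first_local_minimum, predict_matrix
from soyspec.spectra_io import ReferenceTable

from conftest import make_spectra


def _random_problem(n=12, p=9, seed=0, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    beta = rng.normal(0, 1, p)
    y = X @ beta + rng.normal(0, noise, n)
    return X, y


class TestFitPLS1:
    def test_rank_one_relation_needs_one_factor(self):
        # orthogonal columns, y a multiple of one of them: the first PLS
        # weight is exactly that column's axis, so one factor is exact
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(0, 1, (10, 6)))
        X = Q - Q.mean(axis=0)
        X, _ = np.linalg.qr(X)
        y = 3.0 * X[:, 2]
        model = fit_pls1(X, y, 1)
        np.testing.assert_allclose(predict_matrix(model, X), y, atol=1e-9)

    def test_full_rank_equals_least_squares(self):
        """At n_factors = rank(X), PLS1 calibration predictions coincide
        with the ordinary least-squares fit (centered problem)."""
        X, y = _random_problem(n=8, p=5, seed=2)
        model = fit_pls1(X, y, 5)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        np.testing.assert_allclose(predict_matrix(model, X),
                                   y.mean() + Xc @ beta, atol=1e-8)

    def test_constant_y_is_degenerate(self):
        X, _ = _random_problem()
        with pytest.raises(DegenerateInputError):
            fit_pls1(X, np.full(12, 5.0), 2)

    def test_too_many_factors_rejected(self):
        X, y = _random_problem(n=6, p=4)
        with pytest.raises(ParameterError):
            fit_pls1(X, y, 6)

    def test_scores_are_orthogonal(self):
        X, y = _random_problem(n=20, p=15, seed=3)
        model = fit_pls1(X, y, 6)
        G = model.x_scores.T @ model.x_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-6 * np.abs(np.diag(G)).max()

    def test_matches_sklearn_nipals(self):
        """Independent-algorithm cross-check: scikit-learn's PLSRegression
        (used as oracle only) must give the same predictions."""
        from sklearn.cross_decomposition import PLSRegression
        X, y = _random_problem(n=25, p=12, seed=4)
        Xnew = np.random.default_rng(5).normal(0, 1, (7, 12))
        for k in (1, 3, 5):
            model = fit_pls1(X, y, k)
            sk = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(
                predict_matrix(model, Xnew), sk.predict(Xnew).ravel(),
                atol=1e-8)


class TestExplainedVariance:
    def test_full_rank_reaches_100(self):
        X, y = _random_problem(n=8, p=5, seed=6)
        model = fit_pls1(X, y, 5)
        ev = explained_variance(model)
        assert np.all(np.diff(ev) >= -1e-9)
        np.testing.assert_allclose(ev[-1], 100.0, atol=1e-6)

    def test_matches_deflation_oracle(self):
        X, y = _random_problem(n=15, p=10, seed=7)
        model = fit_pls1(X, y, 4)
        Xc = X - X.mean(axis=0)
        ss0 = np.sum(Xc ** 2)
        # brute force: re-deflate using the fitted scores/loadings
        Xd = Xc.copy()
        for a in range(4):
            Xd = Xd - np.outer(model.x_scores[:, a], model.x_loadings[:, a])
            expected = 100.0 * (1 - np.sum(Xd ** 2) / ss0)
            np.testing.assert_allclose(model.explained_x_variance[a],
                                       expected, atol=1e-9)


class TestFirstLocalMinimum:
    @pytest.mark.parametrize("curve,expected", [
        ((5, 3, 4), 2),            # first local minimum
        ((5, 4, 3, 2), 4),         # strictly decreasing -> max_factors
        ((3, 3, 2), 1),            # tie resolves to smaller k
        ((1, 2, 3), 1),
    ])
    def test_rule(self, curve, expected):
        assert first_local_minimum(curve) == expected


class TestLooCV:
    def test_matches_explicit_refit_loop(self):
        """RMSECV curve must equal an explicit loop that refits PLS on
        every leave-one-out subset."""
        X, y = _random_problem(n=12, p=8, seed=8, noise=0.5)
        res = loo_cv(X, y, 6)
        expected = np.zeros(6)
        for k in range(1, 7):
            errs = []
            for i in range(12):
                mask = np.arange(12) != i
                model = fit_pls1(X[mask], y[mask], k)
                errs.append(predict_matrix(model, X[i][None, :])[0] - y[i])
            expected[k - 1] = np.sqrt(np.mean(np.square(errs)))
        np.testing.assert_allclose(res.rmsecv_by_factor, expected, atol=1e-9)

    def test_noise_free_rank_one_chooses_one_factor(self):
        rng = np.random.default_rng(9)
        t = rng.normal(0, 1, 10)
        X = np.outer(t, rng.normal(0, 1, 6))
        y = 2.0 * t
        res = loo_cv(X, y, 3)
        assert res.chosen_factors == 1
        assert res.rmsecv_by_factor[0] < 1e-8

    def test_replicates_held_out_together(self):
        """A fold must remove every replicate scan of the held-out sample:
        duplicating each row (perfect pseudo-replicates) must not shrink
        RMSECV the way leaking replicates into training would."""
        X, y = _random_problem(n=10, p=6, seed=10, noise=0.5)
        base = loo_cv(X, y, 3)
        X2 = np.repeat(X, 2, axis=0)
        y2 = np.repeat(y, 2)
        groups = np.repeat(np.arange(10), 2)
        grouped = loo_cv(X2, y2, 3, groups=groups)
        np.testing.assert_allclose(grouped.rmsecv_by_factor,
                                   base.rmsecv_by_factor, atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(DataError):
            loo_cv(np.zeros((2, 4)), np.array([1.0, 2.0]), 1)


class TestDiagnostics:
    def test_leverages_sum_to_n_factors(self):
        X, y = _random_problem(n=20, p=10, seed=11)
        model = fit_pls1(X, y, 4)
        rep = diagnostics(model, y)
        np.testing.assert_allclose(rep.leverage.sum(), 4.0, atol=1e-6)
        assert (rep.leverage >= 0).all()

    def test_constructed_outlier_flagged_by_residual_rule(self):
        X, y = _random_problem(n=30, p=10, seed=12, noise=0.2)
        model = fit_pls1(X, y, 3)
        rmsec = np.sqrt(np.mean(
            (y - (model.y_mean + model.x_scores @ model.y_loadings)) ** 2))
        y_bad = y.copy()
        y_bad[17] += 10 * rmsec
        model_bad = fit_pls1(X, y_bad, 3)
        rep = diagnostics(model_bad, y_bad)
        assert 17 in rep.flagged_ids


class TestPredict:
    @staticmethod
    def _trained(seed=0):
        spectra = make_spectra(n_samples=15, n_wavelengths=80,
                               replicates=2, seed=seed)
        rng = np.random.default_rng(seed + 100)
        y = pd.Series(rng.uniform(30, 40, 15),
                      index=[f"s{i}" for i in range(15)])
        refs = ReferenceTable(pd.DataFrame({"total_protein": y}).rename_axis(
            "sample_id"))
        recipe = regression_recipe(1450.0, 1900.0, window=11)
        model, cv = train_pls(spectra, refs, "total_protein", recipe, 4)
        return spectra, refs, model, cv

    def test_replicate_scans_average_into_sample_prediction(self):
        spectra, refs, model, _ = self._trained()
        scan_pred = predict(model, spectra)
        sample_pred = predict(model, spectra, per_sample=True)
        manual = pd.Series(scan_pred,
                           index=spectra.scan_meta["sample_id"].to_numpy()
                           ).groupby(level=0, sort=False).mean()
        pd.testing.assert_series_equal(sample_pred, manual)

    def test_identical_scans_identical_predictions(self):
        from soyspec.spectra_io import SpectraSet
        spectra, refs, model, _ = self._trained(seed=1)
        row = spectra.absorbance[0]
        meta = pd.DataFrame({"sample_id": ["s0", "s0"],
                             "replicate_id": [1, 2],
                             "class_label": [None, None]})
        dup = SpectraSet(spectra.grid, np.vstack([row, row]), meta)
        pred = predict(model, dup)
        assert pred[0] == pred[1]
        per_sample = predict(model, dup, per_sample=True)
        assert per_sample["s0"] == pred[0]

    def test_save_load_round_trip_reproduces_predictions(self, tmp_path):
        spectra, refs, model, _ = self._trained(seed=2)
        path = tmp_path / "model.json"
        model.save(path)
        back = PLSModel.load(path)
        np.testing.assert_allclose(predict(back, spectra),
                                   predict(model, spectra), atol=1e-12)

    def test_cv_matches_grouped_oracle_on_fixture_subset(self, study_fixture):
        """End-to-end: train_pls's RMSECV equals a hand-rolled grouped LOO
        on the same preprocessed matrix."""
        spectra, refs, _ = study_fixture
        ids = refs.samples_with("total_protein")[:12]
        sub = spectra.subset_samples(ids)
        recipe = regression_recipe(1876.0, 2294.0)
        model, cv = train_pls(sub, refs, "total_protein", recipe, 4)
        from soyspec.preprocess import PreprocessRecipe
        stateless = PreprocessRecipe(
            [s for s in recipe.steps if s["step"] != "mean_center"])
        X = stateless.apply(sub).absorbance
        groups = sub.scan_meta["sample_id"].to_numpy()
        y = refs.trait_values("total_protein").loc[groups].to_numpy()
        oracle = loo_cv(X, y, 4, groups=groups)
        np.testing.assert_allclose(cv.rmsecv_by_factor,
                                   oracle.rmsecv_by_factor, atol=1e-9)
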