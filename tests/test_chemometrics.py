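import numpy as np
import pytest

from laverspec import chemometrics as chem
from laverspec.synthetic import (
    DEFAULT_BANDS,
    INDEX_BAND_RANGES,
    QualityRecord,
    make_spectrum,
    wavelength_axis,
)


def _random_problem(rng, n=18, p=8, q=2):
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    return X, Y


def _ols_fitted(X, Y):
    """Least-squares oracle on centered data."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return Xc @ B + Y.mean(axis=0)


class TestFitPLS:
    def test_full_rank_matches_least_squares(self, rng):
        for _ in range(10):
            X, Y = _random_problem(rng)
            model = chem.fit_pls(X, Y, n_components=X.shape[1])
            _, Yhat = chem.predict_classes(model, X)
            np.testing.assert_allclose(Yhat, _ols_fitted(X, Y), atol=1e-8)

    def test_exact_linear_response_r2_one(self, rng):
        X = rng.standard_normal((15, 6))
        B = rng.standard_normal((6, 2))
        Y = X @ B + 3.0
        model = chem.fit_pls(X, Y, n_components=6)
        _, Yhat = chem.predict_classes(model, X)
        resid = Y - Yhat
        assert np.sum(resid**2) / np.sum((Y - Y.mean(0)) ** 2) < 1e-12

    def test_matches_sklearn_nipals(self, rng):
        """Independent cross-check against sklearn's PLSRegression."""
        from sklearn.cross_decomposition import PLSRegression

        X, Y = _random_problem(rng, n=25, p=12, q=3)
        for F in (2, 5):
            model = chem.fit_pls(X, Y, n_components=F)
            _, Yhat = chem.predict_classes(model, X)
            ref = PLSRegression(n_components=F, scale=False, tol=1e-12, max_iter=5000).fit(X, Y)
            np.testing.assert_allclose(Yhat, ref.predict(X), atol=2e-5)

    def test_duplicated_rows_equal_fit(self, rng):
        X, Y = _random_problem(rng, n=10, p=5)
        X2, Y2 = np.vstack([X, X]), np.vstack([Y, Y])
        m1 = chem.fit_pls(X, Y, 3)
        m2 = chem.fit_pls(X2, Y2, 3)
        probe = rng.standard_normal((4, 5))
        np.testing.assert_allclose(
            chem.predict_classes(m1, probe)[1], chem.predict_classes(m2, probe)[1], atol=1e-8
        )

    def test_scores_orthogonal(self, rng):
        X, Y = _random_problem(rng, n=20, p=10)
        model = chem.fit_pls(X, Y, 6)
        G = model.T.T @ model.T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_rank_exhaustion_truncates_with_warning(self, rng):
        X = rng.standard_normal((8, 3))
        Y = rng.standard_normal((8, 2))
        with pytest.warns(UserWarning, match="rank"):
            model = chem.fit_pls(X, Y, n_components=7)
        assert model.n_components <= 3

    def test_constant_column_autoscale_guarded(self, rng):
        X, Y = _random_problem(rng, n=12, p=4)
        X[:, 2] = 5.0
        model = chem.fit_pls(X, Y, 2, autoscale=True)
        assert np.all(np.isfinite(model.W))


class TestPredictClasses:
    def test_separable_training_labels_recovered(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 4)), rng.normal(3, 0.1, (10, 4))])
        y = np.array([0] * 10 + [1] * 10)
        model = chem.fit_pls(X, y, 2)
        labels, _ = chem.predict_classes(model, X)
        np.testing.assert_array_equal(labels, y)

    def test_tie_goes_to_lowest_class(self):
        model = chem.fit_pls(np.eye(4), np.array([0, 0, 1, 1]), 1)
        # force exactly equal indicator columns
        model.C[:] = 0.0
        model.y_mean[:] = 0.5
        labels, Yhat = chem.predict_classes(model, np.eye(4))
        assert np.allclose(Yhat, 0.5)
        assert np.all(labels == model.classes[0])

    def test_permuting_samples_permutes_outputs(self, rng):
        X, Y = _random_problem(rng, n=12, p=5)
        model = chem.fit_pls(X, Y, 3)
        perm = rng.permutation(12)
        l1, y1 = chem.predict_classes(model, X)
        l2, y2 = chem.predict_classes(model, X[perm])
        np.testing.assert_allclose(y1[perm], y2, atol=1e-12)

    def test_band_mismatch_is_error(self, rng):
        X, Y = _random_problem(rng)
        model = chem.fit_pls(X, Y, 2)
        with pytest.raises(ValueError, match="band count"):
            chem.predict_classes(model, X[:, :4])


class TestVIP:
    def test_mean_vip_squared_is_one(self, rng):
        """Normalization identity holds for any fit."""
        for n, p, F in [(15, 10, 3), (20, 30, 5), (12, 6, 2)]:
            X = rng.standard_normal((n, p))
            y = rng.integers(0, 2, n)
            model = chem.fit_pls(X, y, F)
            res = chem.vip(model)
            assert abs(np.mean(res.vip**2) - 1.0) < 1e-8

    def test_single_component_uniform_weights_gives_unit_vip(self):
        model = chem.fit_pls(np.eye(4), np.array([0, 0, 1, 1]), 1)
        p = 4
        model.W = np.full((p, 1), 1 / np.sqrt(p))
        res = chem.vip(model)
        np.testing.assert_allclose(res.vip, 1.0, atol=1e-12)

    def test_informative_band_scores_highest(self, rng):
        X = rng.standard_normal((40, 20))
        y = (X[:, 7] > 0).astype(int)
        model = chem.fit_pls(X, y, 2)
        res = chem.vip(model)
        assert np.argmax(res.vip) == 7
        assert res.selected[7]

    def test_selected_ranges_reported_in_nm(self, rng):
        wl = np.linspace(1000, 1100, 11)
        sel = np.array([0, 1, 1, 0, 0, 1, 0, 0, 0, 1, 1], dtype=bool)
        ranges = chem.selected_ranges(sel, wl)
        assert ranges == [(1010.0, 1020.0), (1050.0, 1050.0), (1090.0, 1100.0)]

    def test_zero_variance_vip_undefined(self):
        model = chem.fit_pls(np.eye(4), np.array([0, 0, 1, 1]), 1)
        model.C[:] = 0.0
        with pytest.raises(ValueError, match="VIP undefined"):
            chem.vip(model)


def _single_index_task(index, n=60, seed=0):
    """Spectra varying only in one quality index; labels are its grade levels."""
    rng = np.random.default_rng(seed)
    axis = wavelength_axis()
    base = {"moisture": 9.0, "protein": 38.0, "cutting_stress": 0.45}
    levels = {
        "moisture": [6.5, 9.0, 12.4],
        "protein": [29.0, 32.5, 38.5],
        "cutting_stress": [0.28, 0.39, 0.50],
    }[index]
    X, y = [], []
    for i in range(n):
        cls = i % 3
        vals = dict(base)
        vals[index] = levels[cls] * rng.normal(1.0, 0.02)
        rec = QualityRecord(f"S{i}", **vals)
        X.append(make_spectrum(rec, DEFAULT_BANDS, axis, rng=rng, noise_sd=0.002))
        y.append(cls)
    return np.array(X), np.array(y), axis


class TestVIPBandRecovery:
    @pytest.mark.parametrize("index", ["moisture", "protein", "cutting_stress"])
    def test_selected_bands_cover_planted_ranges(self, index):
        X, y, axis = _single_index_task(index)
        model = chem.fit_pls(X, y, 3)
        res = chem.vip(model, wavelengths=axis)
        sel = res.selected
        for lo, hi in INDEX_BAND_RANGES[index]:
            in_range = (axis >= lo) & (axis <= hi)
            coverage = sel[in_range].mean()
            assert coverage >= 0.5, (index, (lo, hi), coverage)


class TestRefitOnSelected:
    def test_all_bands_selection_identical_to_full_fit(self, rng):
        X, Y = _random_problem(rng, n=20, p=8)
        full = chem.fit_pls(X, Y, 3)
        res = chem.VIPResult(vip=np.ones(8), selected=np.ones(8, bool))
        refit = chem.refit_on_selected(X, Y, res, 3)
        probe = rng.standard_normal((5, 8))
        np.testing.assert_allclose(
            chem.predict_classes(full, probe)[1], chem.predict_classes(refit, probe)[1], atol=1e-10
        )

    def test_vip_plsda_within_ten_points_of_full(self):
        X, y, _ = _single_index_task("moisture", n=60)
        plan = chem.CVPlan(n_splits=10)
        full = chem.venetian_cv(X, y, chem.plsda_model_fn(3), plan)
        vipf = chem.venetian_cv(X, y, chem.vip_plsda_model_fn(3), plan)
        assert abs(full.fraction_correct - vipf.fraction_correct) <= 0.10

    def test_excluding_informative_bands_drops_to_chance(self):
        X, y, axis = _single_index_task("moisture", n=60)
        model = chem.fit_pls(X, y, 3)
        res = chem.vip(model)
        anti = chem.VIPResult(vip=res.vip, selected=~res.selected)
        rep = chem.venetian_cv(
            X, y,
            lambda Xtr, ytr: (
                lambda Xte: chem.predict_classes(
                    chem.refit_on_selected(Xtr, ytr, anti, 3), Xte
                )
            ),
        )
        assert rep.fraction_correct <= 1 / 3 + 0.15

    def test_too_few_selected_bands_rejected(self, rng):
        X, Y = _random_problem(rng, n=10, p=6)
        res = chem.VIPResult(vip=np.ones(6), selected=np.zeros(6, bool))
        with pytest.raises(ValueError, match="at least 2"):
            chem.refit_on_selected(X, Y, res, 2)


class TestANN:
    def test_linearly_separable_perfect_training(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = chem.fit_ann(X, y, seed=0)
        labels, proba = chem.predict_ann(model, X)
        assert np.mean(labels == y) == 1.0
        assert proba.shape == (40, 2)

    def test_xor_solved_by_hidden_layer(self, rng):
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]])
        X = np.vstack([c + rng.normal(0, 0.08, (25, 2)) for c in centers])
        y = np.array([0] * 50 + [1] * 50)
        model = chem.fit_ann(X, y, seed=1)
        labels, _ = chem.predict_ann(model, X)
        assert np.mean(labels == y) > 0.9

    def test_same_seed_identical_weights(self, rng):
        X, _ = _random_problem(rng, n=30, p=4)
        y = rng.integers(0, 2, 30)
        m1 = chem.fit_ann(X, y, seed=7)
        m2 = chem.fit_ann(X, y, seed=7)
        for a, b in zip(m1.net.coefs_, m2.net.coefs_):
            np.testing.assert_array_equal(a, b)

    def test_pls_ann_trains_on_scores(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (15, 30)), rng.normal(1, 0.2, (15, 30))])
        y = np.array([0] * 15 + [1] * 15)
        base = chem.fit_pls(X, y, 3)
        model = chem.fit_ann(X, y, seed=0, pls_model=base)
        assert model.net.coefs_[0].shape[0] == 3  # input layer sees 3 scores
        labels, _ = chem.predict_ann(model, X)
        assert np.mean(labels == y) == 1.0


class TestVenetianCV:
    def test_fold_definition_interleaved(self):
        plan = chem.CVPlan(n_splits=10)
        folds = plan.folds(20)
        assert all(len(f) == 2 for f in folds)
        np.testing.assert_array_equal(folds[3], [3, 13])

    def test_separable_data_perfect_pooled_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 5)), rng.normal(4, 0.1, (20, 5))])
        y = np.array([0] * 20 + [1] * 20)
        order = rng.permutation(40)
        rep = chem.venetian_cv(X[order], y[order], chem.plsda_model_fn(2))
        assert rep.fraction_correct == 1.0
        assert rep.accuracy == 1.0

    def test_label_permutation_at_chance(self, rng):
        """Held-out accuracy on permuted labels stays in the chance band."""
        X = rng.standard_normal((90, 30))
        y = np.tile([0, 1, 2], 30)
        y_perm = rng.permutation(y)
        rep = chem.venetian_cv(X, y_perm, chem.plsda_model_fn(3))
        p = 1 / 3
        band = 1.96 * np.sqrt(p * (1 - p) / 90)
        assert abs(rep.fraction_correct - p) <= band + 0.05

    def test_missing_class_in_training_warns_but_scores(self, rng):
        X = rng.standard_normal((12, 4))
        y = np.array([0] * 11 + [1])
        with pytest.warns(UserWarning, match="misses a class"):
            rep = chem.venetian_cv(X, y, chem.plsda_model_fn(1), chem.CVPlan(n_splits=6))
        assert rep.confusion.sum() == 12


class TestSelectComponents:
    def test_picks_informative_dimension(self, rng):
        X, y, _ = _single_index_task("moisture", n=40)
        F = chem.select_components(X, y, max_components=5)
        assert 1 <= F <= 5


class TestScoreReport:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = chem.score_report(y, y)
        assert rep.accuracy == 1.0 and rep.error_rate == 0.0
        np.testing.assert_allclose(rep.sensitivity, 1.0)

    def test_formula_arithmetic_two_class(self):
        """TP=3 FN=1 TN=4 FP=2 for the positive class."""
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
        rep = chem.score_report(y_true, y_pred)
        i = list(rep.classes).index(1)
        assert rep.tp[i] == 3 and rep.fn[i] == 1 and rep.tn[i] == 4 and rep.fp[i] == 2
        assert rep.sensitivity[i] == pytest.approx(0.75)
        assert rep.specificity[i] == pytest.approx(2 / 3, abs=1e-3)
        assert rep.per_class_accuracy[i] == pytest.approx(0.7)

    def test_accuracy_error_complementary(self, rng):
        y_true = rng.integers(0, 3, 50)
        y_pred = rng.integers(0, 3, 50)
        rep = chem.score_report(y_true, y_pred)
        assert rep.accuracy + rep.error_rate == 1.0
        assert np.all(rep.tp + rep.tn + rep.fp + rep.fn == 50)

    def test_relabeling_invariance(self, rng):
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        rep1 = chem.score_report(y_true, y_pred)
        relabel = {0: 2, 1: 0, 2: 1}
        y_true2 = np.array([relabel[v] for v in y_true])
        y_pred2 = np.array([relabel[v] for v in y_pred])
        rep2 = chem.score_report(y_true2, y_pred2)
        assert rep1.accuracy == pytest.approx(rep2.accuracy)
        assert sorted(rep1.sensitivity) == pytest.approx(sorted(rep2.sensitivity))

    def test_absent_class_reported_missing(self):
        rep = chem.score_report(
            np.array([0, 0, 1]), np.array([0, 1, 1]), classes=np.array([0, 1, 2])
        )
        assert 2 in rep.missing_classes
        assert np.isnan(rep.sensitivity[2])

    def test_constant_continuous_prediction_r2_nonpositive(self):
        y = np.array([0, 1, 0, 1])
        cont = np.full((4, 2), 0.3)
        rep = chem.score_report(y, y, cont)
        assert np.all(rep.r2_per_class <= 0 + 1e-12)
        # RMSE against the indicator of a constant predictor
        Y, _ = chem.one_hot(y)
        np.testing.assert_allclose(
            rep.rmse_per_class, np.sqrt(np.mean((Y - 0.3) ** 2, axis=0)), atol=1e-12
        )


class TestHoldoutSplit:
    def test_stratified_80_20(self):
        X = np.arange(100).reshape(100, 1).astype(float)
        y = np.tile([0, 1], 50)
        X_tr, X_te, y_tr, y_te = chem.holdout_split(X, y)
        assert len(y_te) == 20 and len(y_tr) == 80
        assert np.sum(y_te == 0) == 10  # stratification preserved
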