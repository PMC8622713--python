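"""PLSDA: NIPALS correctness against independent references, LV selection,
feature-band extraction, and the comparator contract."""

import numpy as np
import pytest

import oralftir as of
from oralftir.comparators import ComparatorSpec, fit_comparator
from oralftir.dataset import WavenumberGrid
from oralftir.evaluation import venetian_blinds
from oralftir.plsda import (
    PLSDAModel,
    extract_feature_bands,
    fit_plsda,
    predict,
    select_n_lv,
)


def separable_fixture(make_set, rng, n_per_class=10, p=25, gap=3.0):
    """Two spectral classes separated along a random direction."""
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    base = rng.normal(size=(2 * n_per_class, p))
    y = np.array(["H"] * n_per_class + ["C"] * n_per_class)
    base[y == "C"] += gap * direction
    sample_ids = [f"S-{i:02d}" for i in range(2 * n_per_class)]
    return make_set(base, sample_ids=sample_ids, classes=list(y)), y


def reference_pls1(X, y, n_lv):
    """Independent PLS1 recursion: no response deflation (the weight
    sequence is unchanged because X-deflation orthogonalizes the scores),
    regression vector assembled from the rotation matrix."""
    x_mean, y_mean = X.mean(axis=0), y.mean()
    Xk = X - x_mean
    yc = y - y_mean
    W, P, Q = [], [], []
    for _ in range(n_lv):
        w = Xk.T @ yc
        w /= np.linalg.norm(w)
        t = Xk @ w
        tt = t @ t
        P.append(Xk.T @ t / tt)
        Q.append(yc @ t / tt)
        W.append(w)
        Xk = Xk - np.outer(t, P[-1])
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    return W @ np.linalg.solve(P.T @ W, Q)


class TestFit:
    def test_single_informative_column_dominates(self, make_set, rng):
        """y perfectly correlated with one column: that column carries the
        regression vector and the training response is reproduced exactly."""
        X = np.zeros((20, 10))
        y = np.array(["H"] * 10 + ["C"] * 10)
        X[:, 4] = (y == "C") * 1.0
        X[:, 7] = 0.3  # constant column, vanishes after centering
        s = make_set(X, classes=list(y))
        model = fit_plsda(s, n_lv=1)
        assert np.argmax(np.abs(model.coef)) == 4
        scores = model.predict_scores(s)
        assert np.allclose(scores, (y == "C").astype(float), atol=1e-8)

    @pytest.mark.parametrize("n_lv", [1, 2, 4])
    def test_regression_vector_matches_independent_recursion(self, make_set, rng, n_lv):
        s, y = separable_fixture(make_set, rng, gap=1.0)
        model = fit_plsda(s, n_lv=n_lv)
        b_ref = reference_pls1(s.intensities, (y == "C").astype(float), n_lv)
        assert np.allclose(model.coef, b_ref, atol=1e-8)

    def test_matches_sklearn_pls_regression(self, make_set, rng):
        """Cross-check against an established PLS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        s, y = separable_fixture(make_set, rng, gap=1.0)
        model = fit_plsda(s, n_lv=3)
        sk = PLSRegression(n_components=3, scale=False).fit(
            s.intensities, (y == "C").astype(float)
        )
        assert np.allclose(model.coef, sk.coef_.ravel(), atol=1e-8)

    def test_scores_are_mutually_orthogonal(self, make_set, rng):
        s, _ = separable_fixture(make_set, rng, gap=1.0)
        model = fit_plsda(s, n_lv=4)
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_saturates_to_least_squares_fit(self, make_set, rng):
        """With the maximal LV count on full-rank X the training response is
        reproduced exactly."""
        X = rng.normal(size=(12, 30))
        y = np.array(["H"] * 6 + ["C"] * 6)
        s = make_set(X, classes=list(y))
        model = fit_plsda(s, n_lv=11)
        assert np.allclose(model.predict_scores(s), (y == "C").astype(float), atol=1e-6)

    def test_single_class_training_rejected(self, make_set, rng):
        s = make_set(rng.normal(size=(6, 8)), classes=["H"] * 6)
        with pytest.raises(ValueError, match="both classes"):
            fit_plsda(s, n_lv=1)


class TestPredict:
    def test_training_rows_classified_correctly(self, make_set, rng):
        s, y = separable_fixture(make_set, rng)
        model = fit_plsda(s, n_lv=2)
        frame = predict(model, s)
        assert (frame["predicted_class"].to_numpy() == y).all()

    def test_tie_at_threshold_goes_to_positive_class(self, make_set, rng):
        s, _ = separable_fixture(make_set, rng)
        model = fit_plsda(s, n_lv=1)
        assert model.predict_classes(np.array([0.5]))[0] == "C"

    def test_grid_mismatch_detected(self, make_set, rng):
        s, _ = separable_fixture(make_set, rng)
        model = fit_plsda(s, n_lv=1)
        permuted = make_set(
            s.intensities, grid=WavenumberGrid(s.grid.values * 1.1), classes=list(s.classes)
        )
        with pytest.raises(ValueError, match="grid"):
            model.predict_scores(permuted)


class TestLvSelection:
    def test_separable_one_dimensional_signal_needs_one_lv(self, make_set, rng):
        n_samples, p = 10, 15
        direction = rng.normal(size=p)
        y_sample = np.array(["H", "C"] * (n_samples // 2))
        X = rng.normal(size=(2 * n_samples, p)) * 0.1
        yy = np.repeat(y_sample, 2)
        X[yy == "C"] += 5.0 * direction / np.linalg.norm(direction)
        ids = [f"S-{i:02d}" for i in range(n_samples) for _ in (0, 1)]
        s = make_set(X, sample_ids=ids, classes=list(yy))
        folds = venetian_blinds(ids, k=5)
        n_lv, cal, cv = select_n_lv(s, yy, folds.folds, max_lv=4)
        assert n_lv == 1
        assert len(cal) == len(cv) == 4

    def test_choice_is_deterministic(self, default_run):
        mi = default_run.model_input
        train = mi.select_rows(np.isin(mi.classes, ("H", "C")))
        folds = venetian_blinds(train, k=10)
        a = select_n_lv(train, train.classes, folds.folds, max_lv=6)
        b = select_n_lv(train, train.classes, folds.folds, max_lv=6)
        assert a[0] == b[0]
        assert np.array_equal(a[2], b[2])


class TestExplainedVariance:
    def test_rank_one_x_fully_explained_by_lv1(self, make_set, rng):
        direction = rng.normal(size=20)
        t = np.linspace(-1, 1, 12)
        X = np.outer(t, direction)
        y = np.array(["H"] * 6 + ["C"] * 6)
        model = fit_plsda(make_set(X, classes=list(y)), n_lv=1)
        assert model.explained_x_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_matches_reconstruction_norm_oracle_and_sums_below_100(self, make_set, rng):
        s, _ = separable_fixture(make_set, rng, gap=1.0)
        model = fit_plsda(s, n_lv=4)
        Xc = s.intensities - s.intensities.mean(axis=0)
        total = (Xc**2).sum()
        for k in range(4):
            rank_one = np.outer(model.x_scores[:, k], model.x_loadings[k])
            assert model.explained_x_variance[k] == pytest.approx(
                100.0 * (rank_one**2).sum() / total, abs=1e-8
            )
        assert model.explained_x_variance.sum() <= 100.0 + 1e-9


def _stub_model(grid_values, loadings):
    k, p = loadings.shape
    return PLSDAModel(
        wavenumbers=grid_values,
        n_lv=k,
        x_mean=np.zeros(p),
        y_mean=0.5,
        weights=loadings,
        x_loadings=loadings,
        x_scores=np.zeros((2, k)),
        y_loadings=np.zeros(k),
        y_scores=np.zeros((2, k)),
        coef=np.zeros(p),
        explained_x_variance=np.zeros(k),
    )


class TestFeatureBands:
    def test_single_positive_gaussian_loading(self, grid):
        loading = np.exp(-0.5 * ((grid.values - 1650.0) / 15.0) ** 2)
        model = _stub_model(grid.values, loading[None, :])
        bands = extract_feature_bands(model, lv_indices=(1,))
        assert len(bands) == 1
        assert bands[0].wavenumber == pytest.approx(1650.0, abs=2.0)
        assert bands[0].sign == "+"

    def test_opposite_sign_gaussians_get_correct_signs(self, grid):
        loading = np.exp(-0.5 * ((grid.values - 1548.0) / 12.0) ** 2) - np.exp(
            -0.5 * ((grid.values - 1482.0) / 12.0) ** 2
        )
        model = _stub_model(grid.values, loading[None, :])
        bands = extract_feature_bands(model, lv_indices=(1,), prominence_fraction=0.5)
        found = {(round(b.wavenumber), b.sign) for b in bands}
        assert (1548, "+") in found
        assert (1482, "-") in found

    def test_zero_loading_yields_no_bands(self, grid):
        model = _stub_model(grid.values, np.zeros((1, len(grid.values))))
        assert extract_feature_bands(model, lv_indices=(1,)) == []


class TestComparators:
    def test_separable_fixture_gives_perfect_cv(self, make_set, rng):
        from oralftir.evaluation import cross_validate

        n = 10
        X = np.repeat(rng.normal(size=(n, 15)), 2, axis=0) + rng.normal(size=(2 * n, 15)) * 0.05
        y = np.repeat(np.array(["H"] * (n // 2) + ["C"] * (n // 2)), 2)
        X[y == "C"] += 4.0
        sample_ids = [f"S-{i:02d}" for i in range(n) for _ in (0, 1)]
        s = make_set(X, sample_ids=sample_ids, classes=list(y))
        folds = venetian_blinds(s, k=5)

        model = fit_comparator(ComparatorSpec("svm_rbf"), s, y, folds.folds, seed=0)
        report = cross_validate(
            lambda tr, lab: fit_comparator(
                ComparatorSpec("svm_rbf", model.hyperparameters), tr, lab,
                np.zeros(tr.n_spectra, dtype=int), seed=0,
            ),
            s, y, folds, calibration=False,
        )
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0

    def test_hyperparameter_tuning_is_deterministic(self, make_set, rng):
        s, y = separable_fixture(make_set, rng, n_per_class=8)
        # duplicate rows so the grouped-CV contract holds
        X = np.vstack([s.intensities, s.intensities])
        yy = np.concatenate([y, y])
        ids = list(s.sample_ids) + list(s.sample_ids)
        s2 = make_set(X, sample_ids=ids, classes=list(yy))
        folds = venetian_blinds(s2, k=4)
        m1 = fit_comparator(ComparatorSpec("svm_rbf"), s2, yy, folds.folds, seed=3)
        m2 = fit_comparator(ComparatorSpec("svm_rbf"), s2, yy, folds.folds, seed=3)
        assert m1.hyperparameters == m2.hyperparameters

    def test_unknown_comparator_rejected(self):
        with pytest.raises(ValueError, match="unknown comparator"):
            ComparatorSpec("random_forest")
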