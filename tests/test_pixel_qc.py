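"""Pixel QC: PCA/T2/Q against closed-form oracles, clustering, selection."""

import numpy as np
import pytest
from scipy.stats import f as f_dist
from scipy.stats import norm

import oralftir as of
from oralftir.pixel_qc import (
    class_average,
    fit_pca,
    hca,
    remove_outliers,
    representative_spectrum,
    select_epithelium,
    select_two_per_sample,
    t2_q,
)
from oralftir.preprocessing import preprocess_general
from oralftir.synthetic import CohortScenario, DistortionConfig, generate_area


def eigendecomposition_oracle(X):
    """PCA via explicit eigendecomposition of the covariance matrix."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestPca:
    def test_rank_one_matrix_is_fully_explained_by_pc1(self, make_set, rng):
        X = np.outer(rng.normal(size=30), rng.normal(size=40))
        model = fit_pca(make_set(X), n_components=3)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition_oracle(self, make_set, rng):
        X = rng.normal(size=(50, 20))
        model = fit_pca(make_set(X), n_components=5)
        evals, evecs = eigendecomposition_oracle(X)
        assert np.allclose(model.eigenvalues, evals[:5], atol=1e-8)
        for k in range(5):
            # loadings match up to sign
            dot = abs(model.components[k] @ evecs[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_full_reconstruction(self, make_set, rng):
        X = rng.normal(size=(15, 10))
        model = fit_pca(make_set(X), n_components=10)
        assert np.allclose(model.reconstruct(model.scores), X, atol=1e-10)

    def test_too_many_components_rejected(self, make_set, rng):
        with pytest.raises(ValueError):
            fit_pca(make_set(rng.normal(size=(5, 10))), n_components=8)


class TestT2Q:
    def test_row_at_training_mean_has_zero_t2(self, make_set, rng):
        X = rng.normal(size=(40, 12))
        s = make_set(X)
        model = fit_pca(s, n_components=3)
        mean_row = make_set(X.mean(axis=0, keepdims=True), grid=s.grid)
        report = t2_q(model, mean_row)
        assert report.reduced_t2[0] == pytest.approx(0.0, abs=1e-12)

    def test_row_in_loading_span_has_zero_q(self, make_set, rng):
        X = rng.normal(size=(40, 12))
        s = make_set(X)
        model = fit_pca(s, n_components=3)
        row = X.mean(axis=0) + 2.0 * model.components[0] - 1.0 * model.components[2]
        report = t2_q(model, make_set(row[None, :], grid=s.grid))
        assert report.reduced_q[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_formulas(self, make_set, rng):
        """Reduced T2 and Q match the direct formulas computed from the
        eigendecomposition oracle, including the F and Jackson-Mudholkar
        confidence limits."""
        X = rng.normal(size=(60, 15))
        k = 4
        model = fit_pca(make_set(X), n_components=k)
        report = t2_q(model, make_set(X))

        evals, evecs = eigendecomposition_oracle(X)
        Xc = X - X.mean(axis=0)
        scores = Xc @ evecs[:, :k]
        t2 = (scores**2 / evals[:k]).sum(axis=1)
        resid = Xc - scores @ evecs[:, :k].T
        q = (resid**2).sum(axis=1)

        n = X.shape[0]
        t2_lim = k * (n - 1) / (n - k) * f_dist.ppf(0.95, k, n - k)
        th1, th2, th3 = (evals[k:].sum(), (evals[k:] ** 2).sum(), (evals[k:] ** 3).sum())
        h0 = 1 - 2 * th1 * th3 / (3 * th2**2)
        c = norm.ppf(0.95)
        q_lim = th1 * (c * np.sqrt(2 * th2 * h0**2) / th1 + 1 + th2 * h0 * (h0 - 1) / th1**2) ** (1 / h0)

        assert np.allclose(report.reduced_t2, t2 / t2_lim, atol=1e-8)
        assert np.allclose(report.reduced_q, q / q_lim, atol=1e-8)


class TestOutlierRemoval:
    def test_infinite_threshold_is_identity(self, make_set, rng):
        s = make_set(rng.normal(size=(30, 10)))
        cleaned, report = remove_outliers(s, tau_t=np.inf, tau_q=np.inf)
        assert cleaned.n_spectra == 30
        assert not report.is_outlier.any()

    def test_injected_outliers_flagged_with_low_false_positive_rate(self):
        """A preprocessed area with 5% injected extreme pixels: most are
        flagged, few clean pixels are."""
        rng = np.random.default_rng(17)
        cfg = DistortionConfig(outlier_pixel_fraction=0.05)
        area = generate_area("H-01", "HK", CohortScenario(seed=17), cfg, rng)
        pre = preprocess_general(area)
        _, report = remove_outliers(pre)
        truth = (pre.meta["tissue"] == "outlier").to_numpy()
        assert truth.sum() > 0
        recall = (report.is_outlier & truth).sum() / truth.sum()
        fpr = (report.is_outlier & ~truth).sum() / (~truth).sum()
        assert recall >= 0.8
        assert fpr <= 0.05

    def test_nonpositive_threshold_rejected(self, make_set, rng):
        with pytest.raises(ValueError):
            remove_outliers(make_set(rng.normal(size=(10, 5))), tau_t=0.0)


class TestHca:
    def test_tree_has_n_minus_one_merges(self, make_set, rng):
        s = make_set(rng.normal(size=(12, 6)))
        assert hca(s).linkage_matrix.shape[0] == 11

    def test_identical_rows_merge_at_zero_height(self, make_set):
        s = make_set(np.ones((6, 8)))
        assert np.allclose(hca(s).merge_heights, 0.0)

    def test_two_tissue_profiles_separate_at_two_cluster_cut(self):
        rng = np.random.default_rng(23)
        scen = CohortScenario(seed=23, stroma_fraction=0.3)
        cfg = DistortionConfig(outlier_pixel_fraction=0.0)
        area = generate_area("H-01", "HK", scen, cfg, rng)
        pre = preprocess_general(area)
        labels = hca(pre).cut_k(2)
        truth = (pre.meta["tissue"] == "stroma").to_numpy().astype(int)
        agreement = max((labels == truth).mean(), (labels != truth).mean())
        assert agreement >= 0.95


class TestSelectEpithelium:
    def _area(self, stroma_fraction, seed=31):
        rng = np.random.default_rng(seed)
        scen = CohortScenario(seed=seed, stroma_fraction=stroma_fraction)
        cfg = DistortionConfig(outlier_pixel_fraction=0.0)
        return preprocess_general(generate_area("H-01", "HK", scen, cfg, rng))

    def test_majority_cluster_is_epithelium(self):
        pre = self._area(0.3)
        selected = select_epithelium(pre)
        frac = selected.n_spectra / pre.n_spectra
        assert 0.6 <= frac <= 0.8
        assert (selected.meta["tissue"] == "epithelium").mean() >= 0.95

    def test_single_tissue_area_returned_whole(self):
        pre = self._area(0.0)
        assert select_epithelium(pre).n_spectra == pre.n_spectra

    def test_minority_override(self):
        pre = self._area(0.3)
        minority = select_epithelium(pre, designate="minority")
        majority = select_epithelium(pre, designate="majority")
        assert minority.n_spectra + majority.n_spectra == pre.n_spectra
        assert minority.n_spectra < majority.n_spectra


class TestRepresentatives:
    def test_single_row_is_its_own_representative(self, make_set, rng):
        s = make_set(rng.random((1, 10)))
        rep = representative_spectrum(s)
        assert np.array_equal(rep.intensities[0], s.intensities[0])
        assert rep.meta["role"].iloc[0] == "representative"

    def test_two_rows_average(self, make_set, rng):
        a, b = rng.random(10), rng.random(10)
        rep = representative_spectrum(make_set(np.vstack([a, b]), sample_ids=["S", "S"], area_ids=["A", "A"]))
        assert np.allclose(rep.intensities[0], (a + b) / 2, atol=1e-15)

    def test_full_area_matches_brute_force_mean(self):
        rng = np.random.default_rng(41)
        area = generate_area("H-01", "HK", CohortScenario(seed=41), DistortionConfig(), rng)
        rep = representative_spectrum(area)
        assert np.allclose(rep.intensities[0], area.intensities.mean(axis=0), atol=1e-12)


class TestTwoPerSample:
    def test_exactly_two_areas_both_kept(self, make_set, rng):
        s = make_set(rng.random((2, 8)), sample_ids=["S1", "S1"], area_ids=["a1", "a2"])
        assert select_two_per_sample(s).n_spectra == 2

    def test_farthest_pair_of_three_selected(self, make_set):
        # three 1-D-like rows at positions 0, 1, 3: pairwise distances 1, 2, 3
        rows = np.zeros((3, 8))
        rows[:, 0] = [0.0, 1.0, 3.0]
        s = make_set(rows, sample_ids=["S1"] * 3, area_ids=["a1", "a2", "a3"])
        kept = select_two_per_sample(s)
        assert sorted(kept.meta["area_id"]) == ["a1", "a3"]

    def test_single_area_sample_is_an_error(self, make_set, rng):
        s = make_set(rng.random((1, 8)), sample_ids=["S1"], area_ids=["a1"])
        with pytest.raises(ValueError, match="at least two"):
            select_two_per_sample(s)

    def test_output_always_two_rows_per_sample(self, default_run):
        reps = default_run.representatives
        counts = reps.meta.groupby("sample_id").size()
        assert (counts == 2).all()


class TestClassAverage:
    def test_representative_counts_per_class(self, default_run):
        """24 HK, 22 OED and 22 OSCC representative spectra feed the class
        averages of the default cohort."""
        reps = default_run.representatives
        for label, expected in [("H", 24), ("D", 22), ("C", 22)]:
            avg = class_average(reps, label)
            assert avg.meta["n_spectra"].iloc[0] == expected

    def test_single_row_class_is_identity(self, make_set, rng):
        s = make_set(rng.random((1, 8)), classes=["C"])
        assert np.array_equal(class_average(s, "C").intensities, s.intensities)

    def test_unknown_class_rejected(self, make_set, rng):
        with pytest.raises(ValueError):
            class_average(make_set(rng.random((2, 8))), "X")

    @pytest.mark.parametrize(
        "center, order",
        [(1650.0, "HDC"), (1548.0, "HDC"), (1310.0, "HDC"),
         (1240.0, "CDH"), (1154.0, "CDH"), (1080.0, "CDH"), (1030.0, "CDH")],
    )
    def test_class_averages_reproduce_band_orderings(self, zero_distortion_run, center, order):
        """Class-average representatives keep the generator's band-intensity
        orderings on the artifact-free cohort."""
        reps = zero_distortion_run.representatives
        vals = [class_average(reps, c).band_mean(center)[0] for c in order]
        assert vals[0] > vals[1] > vals[2]
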