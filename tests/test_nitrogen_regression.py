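import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cross_decomposition import PLSRegression

import hyperleaf as hl
from hyperleaf import ZeroVarianceError
from hyperleaf.nitrogen_regression import pls1_coefficient_paths


def record(sid, weight=250.0, n_percent=3.0, flag="none"):
    return hl.SampleRecord(sid, "V1", 100.0, 1, weight, n_percent,
                           exclusion_flag=flag)


class TestClean:
    def test_underweight_leaf_excluded(self):
        assert hl.clean([record("A", weight=99.0, n_percent=None)]) == []

    def test_boundaries_are_strict(self):
        kept = hl.clean([record("A", n_percent=0.9),
                         record("B", n_percent=7.0),
                         record("C", n_percent=1.0),
                         record("D", n_percent=7.1)])
        assert [r.sample_id for r in kept] == ["B", "C"]

    def test_study_scale_counts(self):
        records = hl.generate_ledger_for_cleaning(600, 42, 8, 7, seed=0)
        assert len(hl.clean(records)) == 543

    def test_flag_records_labels_every_category(self):
        flagged = hl.flag_records([
            record("A", weight=50.0, n_percent=None),
            record("B", n_percent=0.5),
            record("C", n_percent=None, flag="acquisition_error"),
            record("D"),
        ])
        assert [r.exclusion_flag for r in flagged] == [
            "too_small", "n_outlier", "acquisition_error", "none"]


class TestMetrics:
    def test_hand_computed_three_point_example(self):
        m = hl.metrics(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        assert m.r2 == pytest.approx(0.5, abs=1e-12)
        assert m.rmse == pytest.approx(np.sqrt(1.0 / 3.0), abs=1e-12)
        assert m.bias == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert m.mean_abs == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert m.median_abs == pytest.approx(0.0, abs=1e-12)

    def test_perfect_prediction(self):
        y = np.array([1.0, 2.5, 4.0])
        m = hl.metrics(y, y)
        assert (m.r2, m.rmse, m.bias, m.mean_abs, m.median_abs) == (1, 0, 0, 0, 0)

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        assert hl.metrics(y, np.full(4, y.mean())).r2 == pytest.approx(0.0)

    def test_r2_can_be_negative(self):
        y = np.array([1.0, 2.0, 3.0])
        assert hl.metrics(y, y[::-1] + 5.0).r2 < 0

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ZeroVarianceError):
            hl.metrics(np.array([2.0, 2.0]), np.array([1.0, 3.0]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_rmse_dominates_bias(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(3, 1, 20)
        yhat = y + rng.normal(0, 0.5, 20)
        m = hl.metrics(y, yhat)
        assert m.rmse >= abs(m.bias) - 1e-12
        assert m.rmse >= 0 and m.mean_abs >= 0


class TestPLS1:
    def test_coefficient_paths_match_sklearn(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 25))
        y = X[:, :5] @ rng.normal(size=5) + 0.1 * rng.normal(size=40)
        B, b0 = pls1_coefficient_paths(X, y, 8)
        for k in (1, 4, 8):
            oracle = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(B[:, k - 1], oracle.coef_.ravel(),
                                       atol=1e-10)
            np.testing.assert_allclose(X @ B[:, k - 1] + b0[k - 1],
                                       oracle.predict(X).ravel(), atol=1e-10)

    def test_constant_response_gives_zero_coefficients(self):
        X = np.random.default_rng(1).normal(size=(10, 4))
        B, b0 = pls1_coefficient_paths(X, np.full(10, 2.0), 3)
        np.testing.assert_allclose(B, 0.0, atol=1e-12)
        assert b0[0] == pytest.approx(2.0)


def dataset_from_matrix(X, y, wavelengths=None):
    lam = (np.arange(400.0, 400.0 + X.shape[1]) if wavelengths is None
           else wavelengths)
    spectra, records = {}, []
    for i in range(X.shape[0]):
        sid = f"S{i:04d}"
        spectra[sid] = hl.Spectrum(sid, lam, X[i], 1.0)
        records.append(record(sid, n_percent=float(y[i])))
    return hl.Dataset(spectra, records)


class TestFitPlsrCv:
    def test_noiseless_linear_relationship_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 0.9, size=(60, 3))
        y = 1.0 + X @ np.array([2.0, -1.0, 0.5])
        fit = hl.fit_plsr_cv(dataset_from_matrix(X, y), seed=0)
        assert fit.mean_metrics.r2 >= 0.999
        # ordinary least squares is the oracle for the full-data refit
        beta = np.linalg.lstsq(np.column_stack([X, np.ones(60)]), y, rcond=None)[0]
        np.testing.assert_allclose(fit.full_coefficients, beta[:3], atol=1e-6)

    def test_permuted_response_has_no_skill(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 0.9, size=(80, 12))
        y = X @ rng.normal(size=12)
        fit = hl.fit_plsr_cv(dataset_from_matrix(X, rng.permutation(y)), seed=1)
        assert fit.mean_metrics.r2 <= 0.1

    def test_fold_exclusivity(self, default_fit):
        folds = default_fit.fold_assignments
        n = folds.size
        union = set()
        for f in range(5):
            idx = set(np.flatnonzero(folds == f))
            assert not union & idx
            union |= idx
        assert union == set(range(n))
        assert default_fit.predictions["sample_id"].is_unique

    def test_latent_variable_counts_in_range(self, default_fit):
        assert all(1 <= lv <= 20 for lv in default_fit.fold_lv)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.1, 0.9, size=(40, 6))
        y = X @ rng.normal(size=6) + 0.05 * rng.normal(size=40)
        data = dataset_from_matrix(X, y)
        a = hl.fit_plsr_cv(data, seed=7)
        b = hl.fit_plsr_cv(data, seed=7)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.fold_coefficients, b.fold_coefficients)
        assert a.mean_metrics == b.mean_metrics

    def test_duplicated_samples_leave_coefficients_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.1, 0.9, size=(30, 5))
        y = X @ rng.normal(size=5) + 0.02 * rng.normal(size=30)
        base = dataset_from_matrix(X, y)
        folds = hl.assign_folds(30, 5, seed=4)
        # latent-variable count pinned so the comparison isolates the fit
        fit1 = hl.fit_plsr_cv(base, seed=4, fold_assignments=folds,
                              lv_range=(3, 3))
        dup = dataset_from_matrix(np.repeat(X, 2, axis=0), np.repeat(y, 2))
        fit2 = hl.fit_plsr_cv(dup, seed=4, lv_range=(3, 3),
                              fold_assignments=np.repeat(folds, 2))
        np.testing.assert_allclose(fit1.fold_coefficients,
                                   fit2.fold_coefficients, atol=1e-8)

    def test_grouped_folds_keep_groups_together(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0.1, 0.9, size=(60, 4))
        y = X @ rng.normal(size=4)
        groups = np.repeat(np.arange(20), 3)  # 3 time-points per plant
        folds = hl.assign_folds(60, 5, seed=0, groups=groups)
        for g in range(20):
            assert np.unique(folds[groups == g]).size == 1


class TestKeyWavelengths:
    def make_fit(self, lam, avg):
        return hl.FitResult(
            sample_ids=[], wavelengths=lam,
            fold_assignments=np.array([]),
            fold_coefficients=np.tile(avg, (5, 1)),
            fold_intercepts=np.zeros(5), fold_lv=[1] * 5, fold_metrics=[],
            predictions=pd.DataFrame(), mean_metrics=None)

    def test_planted_sine_extrema_recovered(self):
        lam = np.arange(400.0, 1001.0)
        fit = self.make_fit(lam, np.sin(2 * np.pi * lam / 200.0))
        keys = hl.key_wavelengths(fit, 6)
        # analytic critical points of sin(2*pi*lam/200): lam = 450, 550, ...
        expected = np.arange(450.0, 1000.0, 100.0)
        assert len(keys) == 6
        for w in keys.wavelengths:
            assert np.min(np.abs(expected - w)) <= 1.0

    def test_monotone_curve_has_no_keys(self):
        lam = np.arange(400.0, 500.0)
        fit = self.make_fit(lam, np.linspace(0, 1, lam.size))
        with pytest.warns(UserWarning, match="extrema"):
            keys = hl.key_wavelengths(fit, 3)
        assert len(keys) == 0

    def test_plateau_counts_once_at_its_centre(self):
        lam = np.arange(400.0, 411.0)
        avg = np.array([0.0, 1.0, 2.0, 3.0, 3.0, 3.0, 3.0, 3.0, 2.0, 1.0, 0.0])
        keys = hl.key_wavelengths(self.make_fit(lam, avg), 1)
        assert keys.wavelengths[0] == pytest.approx(405.0)

    def test_ranked_by_absolute_coefficient(self, default_fit):
        keys = hl.key_wavelengths(default_fit, 10)
        mags = [e[2] for e in keys.entries]
        assert mags == sorted(mags, reverse=True)
        assert len(set(keys.wavelengths)) == len(keys)


class TestCrossSensor:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0.1, 0.9, size=(50, 8))
        y = 2.0 + X @ rng.normal(size=8) + 0.01 * rng.normal(size=50)
        data = dataset_from_matrix(X, y)
        return hl.fit_plsr_cv(data, seed=6), data, y

    def test_in_sample_predictions_reproduced_exactly(self, model):
        fit, data, _ = model
        spectra = [data.spectra[sid] for sid in data.sample_ids]
        X = np.vstack([s.values for s in spectra])
        expected = X @ fit.full_coefficients + fit.full_intercept
        np.testing.assert_allclose(hl.apply_cross_sensor(fit, spectra),
                                   expected, atol=1e-12)

    def test_constant_band_offset_shifts_predictions_linearly(self, model):
        fit, data, _ = model
        c = 0.05
        shifted = [s.with_values(s.values + c)
                   for s in (data.spectra[sid] for sid in data.sample_ids)]
        base = [data.spectra[sid] for sid in data.sample_ids]
        delta = (hl.apply_cross_sensor(fit, shifted)
                 - hl.apply_cross_sensor(fit, base))
        np.testing.assert_allclose(delta, c * fit.full_coefficients.sum(),
                                   atol=1e-10)

    def test_shared_generative_model_slope_near_one_and_planted_gain_bias(self):
        # two sensors on the same grid observing the same samples
        cfg = hl.GeneratorConfig(seed=9, n_samples=80)
        a = hl.generate_cohort(cfg, ("asd",))
        data = hl.Dataset(
            {sid: hl.preprocess_signature(s)
             for sid, s in a.datasets["asd"].spectra.items()}, a.records)
        fit = hl.fit_plsr_cv(data, seed=9)
        spectra = [data.spectra[sid] for sid in data.sample_ids]
        _, y, _ = data.design_matrix()
        yhat, rep = hl.evaluate_cross_sensor(fit, spectra, y)
        assert np.polyfit(y, yhat, 1)[0] == pytest.approx(1.0, abs=0.05)
        # planted additive distortion shows up as bias
        distorted = [s.with_values(s.values + 0.05) for s in spectra]
        _, rep2 = hl.evaluate_cross_sensor(fit, distorted, y)
        assert abs(rep2.bias - 0.05 * fit.full_coefficients.sum()) < 1e-8
        assert abs(rep2.bias) > 0.0

    def test_grid_mismatch_rejected(self, model):
        fit, _, _ = model
        other = hl.Spectrum("X", np.arange(500.0, 508.0), np.full(8, 0.3), 1.0)
        with pytest.raises(hl.GridMismatchError):
            hl.apply_cross_sensor(fit, [other])


class TestNoiseMonotonicity:
    def test_validation_r2_degrades_with_noise(self):
        r2 = []
        for sigma in (0.002, 0.01, 0.05):
            cfg = hl.GeneratorConfig(seed=2, n_samples=150, noise_sigma=sigma)
            bundle = hl.generate_cohort(cfg)
            data = hl.Dataset(
                {sid: hl.preprocess_signature(s)
                 for sid, s in bundle.datasets["asd"].spectra.items()},
                bundle.records)
            r2.append(hl.fit_plsr_cv(data, seed=2).mean_metrics.r2)
        assert r2[0] >= r2[1] - 0.02
        assert r2[1] >= r2[2] - 0.02
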