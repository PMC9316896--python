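"""Window restriction, baseline correction, and PLS calibration."""

import numpy as np
import pytest

from rcvkit import chemometrics as chem
from rcvkit import synthetic as syn
from rcvkit.chemometrics import (
    CalibrationSet,
    CoverageError,
    DegenerateDataError,
    PreprocessSpec,
    SpectralWindowSet,
    baseline_correct,
    build_calibration_set,
    choose_components_cv,
    cross_val_rmse,
    fit_pls,
    model_from_json,
    model_to_json,
    predict,
    restrict_to_windows,
)


def spectrum(wn, ab, **kw):
    return syn.Spectrum(np.asarray(wn, float), np.asarray(ab, float), **kw)


class TestWindows:
    def test_full_range_window_is_identity(self):
        s = spectrum([1000, 1100, 1200], [1.0, 2.0, 3.0])
        out = restrict_to_windows(s, SpectralWindowSet(((1000, 1200),)))
        np.testing.assert_array_equal(out.values, s.absorbance)
        assert out.segments == (3,)

    def test_single_band_window_retains_interior_channel(self):
        # the one-band model window keeps only the grid point inside it
        s = spectrum([1000, 1200, 1250, 1300], [0.0, 1.0, 2.0, 3.0])
        out = restrict_to_windows(s, SpectralWindowSet(((1200.20, 1259.84),)))
        np.testing.assert_array_equal(out.wavenumbers, [1250])
        np.testing.assert_array_equal(out.values, [2.0])

    def test_closed_interval_endpoints_included(self):
        s = spectrum([1200, 1250, 1260], [1.0, 2.0, 3.0])
        out = restrict_to_windows(s, SpectralWindowSet(((1200, 1260),)))
        assert out.segments == (3,)

    def test_two_windows_concatenate(self):
        s = spectrum(np.arange(650, 4000, 2.0), np.zeros(1675))
        ws = SpectralWindowSet(((1187.15, 1289.65), (2884.96, 2993.05)))
        out = restrict_to_windows(s, ws)
        assert len(out.values) == sum(out.segments)
        assert len(out.segments) == 2

    def test_window_outside_grid_raises(self):
        s = spectrum([1000, 1100], [0.0, 0.0])
        with pytest.raises(CoverageError):
            restrict_to_windows(s, SpectralWindowSet(((900, 950),)))

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            SpectralWindowSet(((1000, 1200), (1100, 1300)))


class TestBaseline:
    def make(self, values):
        wn = np.linspace(1200, 1260, len(values))
        return chem.WindowedChannels(wn, np.asarray(values, float), (len(values),))

    def test_constant_offset_removed(self):
        out = baseline_correct(self.make([3.0] * 7))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-14)

    def test_linear_tilt_removed(self):
        wn = np.linspace(1200, 1260, 9)
        out = baseline_correct(chem.WindowedChannels(wn, 0.01 * wn - 2.0, (9,)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_peak_on_tilt_reduces_to_peak(self):
        # closed-form oracle: endpoints of a symmetric window see equal
        # Gaussian tails, so subtracting the endpoint line leaves
        # peak - tail at interior channels and zero at the ends
        wn = np.linspace(1200, 1260, 31)
        peak = 0.5 * np.exp(-0.5 * ((wn - 1230) / 8) ** 2)
        tilt = 0.002 * wn + 1.3
        out = baseline_correct(chem.WindowedChannels(wn, peak + tilt, (31,)))
        expected = peak - peak[0]  # symmetric tails: line through tails is flat
        np.testing.assert_allclose(out.values, expected, atol=1e-12)
        assert out.values[0] == pytest.approx(0.0, abs=1e-14)
        assert out.values[-1] == pytest.approx(0.0, abs=1e-14)

    def test_too_few_channels_raises(self):
        with pytest.raises(DegenerateDataError):
            baseline_correct(self.make([1.0, 2.0]))

    def test_none_mode_is_identity(self):
        ch = self.make([1.0, 2.0, 3.0])
        assert baseline_correct(ch, "none") is ch


def toy_calibration(X, y):
    return CalibrationSet(
        X=X, y=y, spec=PreprocessSpec(baseline_mode="none"),
        wavenumbers=np.arange(X.shape[1], dtype=float), segments=(X.shape[1],),
    )


class TestFitPls:
    def test_rank_one_single_component_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        X = np.column_stack([x, np.zeros(12), np.zeros(12)])
        y = 2.5 * x + 1.0
        model = fit_pls(toy_calibration(X, y), 1)
        fitted = (X - model.x_mean) @ model.coef + model.y_mean
        np.testing.assert_allclose(fitted, y, atol=1e-10)

    def test_full_rank_equals_least_squares(self):
        # normal-equations oracle on a full-rank 8x5 problem
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        model = fit_pls(toy_calibration(X, y), 5)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        np.testing.assert_allclose(model.coef, beta, atol=1e-8)

    def test_agrees_with_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        for k in (1, 2, 3):
            ours = fit_pls(toy_calibration(X, y), k)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(ours.coef, ref.coef_.ravel(), atol=1e-8)

    def test_training_mean_spectrum_predicts_mean_response(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        model = fit_pls(toy_calibration(X, y), 2)
        pred = (X.mean(axis=0) - model.x_mean) @ model.coef + model.y_mean
        assert pred == pytest.approx(y.mean(), abs=1e-12)

    def test_response_scale_equivariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        m1 = fit_pls(toy_calibration(X, y), 2)
        m2 = fit_pls(toy_calibration(X, 3.0 * y), 2)
        np.testing.assert_allclose(3.0 * m1.coef, m2.coef, atol=1e-10)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(5).normal(size=(6, 3))
        with pytest.raises(DegenerateDataError):
            fit_pls(toy_calibration(X, np.ones(6)), 1)

    def test_zero_variance_predictors_rejected(self):
        X = np.ones((6, 3))
        with pytest.raises(DegenerateDataError):
            fit_pls(toy_calibration(X, np.arange(6.0)), 1)

    def test_component_bounds_enforced(self):
        X = np.random.default_rng(6).normal(size=(6, 3))
        with pytest.raises(ValueError):
            fit_pls(toy_calibration(X, np.arange(6.0)), 4)


@pytest.fixture(scope="module")
def trained(signature, instrument):
    spectra = syn.generate_calibration_set(
        [0.6, 1.2, 1.8, 2.4, 3.0], 5, signature, instrument, seed=10
    )
    cal = build_calibration_set(spectra)
    return cal, fit_pls(cal, 2)


class TestPredict:
    def test_simulator_round_trip_noise_free(self, trained, signature, quiet_instrument):
        _, model = trained
        s = syn.simulate_measurement(1.5, signature, quiet_instrument, seed=0)
        assert predict(model, s).value == pytest.approx(1.5, abs=0.02)

    def test_offset_invariance_with_linear_baseline(self, trained, signature, quiet_instrument):
        _, model = trained
        s = syn.simulate_measurement(1.5, signature, quiet_instrument, seed=0)
        shifted = syn.Spectrum(s.wavenumbers, s.absorbance + 0.37)
        assert predict(model, shifted).value == pytest.approx(predict(model, s).value, abs=1e-9)

    def test_below_floor_flagged_but_returned(self, trained, signature, quiet_instrument):
        _, model = trained
        floored = chem.set_calibration_floor(model, 1.0)
        s = syn.simulate_measurement(0.7, signature, quiet_instrument, seed=0)
        p = predict(floored, s)
        assert p.below_floor
        assert p.value == pytest.approx(0.7, abs=0.05)

    def test_extrapolation_flagged(self, trained, signature, quiet_instrument):
        _, model = trained
        s = syn.simulate_measurement(5.0, signature, quiet_instrument, seed=0)
        assert predict(model, s).extrapolated

    def test_grid_mismatch_raises(self, trained):
        _, model = trained
        s = spectrum([1000, 1100], [0.0, 0.0])
        with pytest.raises(CoverageError):
            predict(model, s)


class TestComponentSelection:
    def test_rank_one_data_selects_one(self):
        rng = np.random.default_rng(0)
        x = np.repeat(np.linspace(1, 2, 6), 2)
        X = np.column_stack([x, 2 * x, -x])
        y = 3 * x
        assert choose_components_cv(toy_calibration(X, y), 3, folds=3) == 1

    def test_rank_two_signal_selects_two(self):
        # analyte plus an overlapping interferent: a single latent
        # variable cannot separate them, so the known rank is 2
        rng = np.random.default_rng(1)
        levels = np.repeat(np.linspace(0.5, 3.0, 6), 3)
        interferent = np.tile([0.0, 1.0, 2.0], 6)
        f1 = np.array([1.0, 0.8, 0.3, 0.1])
        f2 = np.array([0.1, 0.4, 0.9, 1.0])
        X = np.outer(levels, f1) + np.outer(interferent, f2)
        X += rng.normal(0, 1e-4, X.shape)
        assert choose_components_cv(toy_calibration(X, levels), 3, folds=3) == 2

    def test_cv_rmse_small_for_clean_synthetic_data(self, signature, instrument):
        spectra = syn.generate_calibration_set(
            [0.6, 1.2, 1.8, 2.4, 3.0], 5, signature, instrument, seed=11
        )
        cal = build_calibration_set(spectra)
        assert cross_val_rmse(cal, 2) < 0.05


class TestSerialization:
    def test_round_trip_lossless(self, signature, instrument):
        spectra = syn.generate_calibration_set([0.6, 1.8, 3.0], 3, signature, instrument, seed=1)
        cal = build_calibration_set(spectra)
        model = chem.set_calibration_floor(fit_pls(cal, 2), 0.56)
        back = model_from_json(model_to_json(model))
        np.testing.assert_array_equal(back.coef, model.coef)
        np.testing.assert_array_equal(back.x_mean, model.x_mean)
        assert back.y_mean == model.y_mean
        assert back.y_range == model.y_range
        assert back.calibration_floor == model.calibration_floor
        assert back.spec == model.spec

    def test_rejects_foreign_document(self):
        with pytest.raises(ValueError):
            model_from_json('{"format": "something-else"}')
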