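"""Unit and property tests for the FCS models, correlator and fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphograd import fcs_core as fcs
from conftest import direct_autocorrelation


class TestModelG:
    def test_closed_form_value_at_dwell_time(self):
        # 1 component, N=1, T=0, S=5, tau=tau_D:
        # G = 0.5 * (1 + 1/25)^(-1/2)
        m = fcs.FcsModel.one_component(n_particles=1.0, dwell_time=1e-3,
                                       triplet_fraction=0.0,
                                       structural_parameter=5.0)
        g = fcs.model_g(m, [1e-3])[0]
        assert g == pytest.approx(0.5 / np.sqrt(1 + 1 / 25), rel=1e-12)
        assert g == pytest.approx(0.4903, abs=1e-4)

    def test_amplitude_equals_inverse_particle_number(self):
        m = fcs.FcsModel.one_component(n_particles=2.0, dwell_time=1e-3,
                                       triplet_fraction=0.0)
        assert fcs.model_g(m, [1e-9])[0] == pytest.approx(0.5, rel=1e-5)

    def test_correlation_vanishes_at_long_lags(self):
        m = fcs.FcsModel.one_component(n_particles=1.0, dwell_time=1e-4,
                                       triplet_fraction=0.0)
        assert fcs.model_g(m, [1e-4 * 1e6])[0] < 1e-4

    def test_rejects_nonpositive_lags(self):
        m = fcs.FcsModel.one_component()
        with pytest.raises(ValueError):
            fcs.model_g(m, [0.0, 1e-3])

    @settings(deadline=None, max_examples=25)
    @given(n=st.floats(0.1, 100), tau=st.floats(1e-5, 1e-2),
           frac=st.floats(0.0, 1.0), tau2=st.floats(1e-5, 1e-2))
    def test_two_component_with_empty_slow_equals_one_component(
            self, n, tau, frac, tau2):
        lags = np.logspace(-6, 0, 40)
        one = fcs.FcsModel.one_component(n_particles=n, dwell_time=tau)
        two = fcs.FcsModel(
            [fcs.DiffusionComponent(1.0, tau),
             fcs.DiffusionComponent(0.0, tau2)], n_particles=n)
        np.testing.assert_allclose(fcs.model_g(one, lags),
                                   fcs.model_g(two, lags), rtol=1e-12)

    def test_triplet_factor_raises_amplitude_at_short_lags(self):
        base = fcs.FcsModel.one_component(triplet_fraction=0.0)
        trip = fcs.FcsModel.one_component(triplet_fraction=0.10)
        lags = np.array([1e-6])
        ratio = fcs.model_g(trip, lags) / fcs.model_g(base, lags)
        assert ratio[0] == pytest.approx(1 + 0.1 / 0.9 * np.exp(-1e-6 / 30e-6),
                                         rel=1e-9)


class TestAutocorrelate:
    def test_constant_trace_gives_zero_correlation(self):
        tr = fcs.PhotonTrace(1e-5, np.full(4096, 7))
        curve = fcs.autocorrelate(tr)
        np.testing.assert_allclose(curve.g, 0.0, atol=1e-12)

    def test_zero_trace_raises_degenerate(self):
        tr = fcs.PhotonTrace(1e-5, np.zeros(64, dtype=int))
        with pytest.raises(fcs.DegenerateTraceError):
            fcs.autocorrelate(tr)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(42)
        counts = rng.poisson(3.0, size=3000)
        # correlated signal so g is nontrivial
        counts[1:] += counts[:-1] // 2
        tr = fcs.PhotonTrace(1e-5, counts)
        curve = fcs.autocorrelate(tr)
        grid = fcs.multi_tau_lag_grid(len(counts), 1e-5)
        # base-resolution channels: direct correlation of the raw trace
        ks = [k for (lag, level, k) in grid if level == 0]
        oracle = direct_autocorrelation(counts.astype(float), ks)
        np.testing.assert_allclose(curve.g[:len(ks)], oracle, rtol=1e-10,
                                   atol=1e-12)
        # one rebinned cascade: direct correlation of the rebinned trace
        ks1 = [k for (lag, level, k) in grid if level == 1]
        reb = tr.rebin(2).counts.astype(float)
        oracle1 = direct_autocorrelation(reb, ks1)
        np.testing.assert_allclose(curve.g[len(ks):len(ks) + len(ks1)],
                                   oracle1, rtol=1e-10, atol=1e-12)

    def test_independent_poisson_counts_are_delta_correlated(self):
        rng = np.random.default_rng(3)
        n = 20000
        tr = fcs.PhotonTrace(1e-5, rng.poisson(5.0, size=n))
        curve = fcs.autocorrelate(tr)
        assert np.all(np.abs(curve.g) < 3 / np.sqrt(n))

    def test_lag_grid_spans_half_millisecond_to_fifty(self):
        tr = fcs.PhotonTrace(2e-5, np.random.default_rng(0).poisson(
            2.0, size=500_000))
        curve = fcs.autocorrelate(tr)
        assert curve.lags[0] <= 0.5e-3
        assert curve.lags[-1] >= 50e-3


class TestAverageCurves:
    def _curve(self, g):
        return fcs.CorrelationCurve(np.array([1e-5, 2e-5, 4e-5]),
                                    np.asarray(g, dtype=float))

    def test_single_curve_is_identity(self):
        c = self._curve([1.0, 0.5, 0.2])
        avg = fcs.average_curves([c])
        np.testing.assert_array_equal(avg.g, c.g)

    def test_opposite_curves_cancel(self):
        g = np.array([1.0, 0.5, 0.2])
        avg = fcs.average_curves([self._curve(g), self._curve(-g)])
        np.testing.assert_allclose(avg.g, 0.0, atol=1e-15)

    def test_mismatched_grids_rejected(self):
        a = self._curve([1, 2, 3])
        b = fcs.CorrelationCurve(np.array([1e-5, 3e-5, 4e-5]),
                                 np.ones(3))
        with pytest.raises(fcs.GridMismatchError):
            fcs.average_curves([a, b])

    def test_averaging_reduces_variance(self):
        rng = np.random.default_rng(11)
        lags = np.array([1e-5, 2e-5, 4e-5, 8e-5])
        reps = [[fcs.CorrelationCurve(lags, rng.normal(0.5, 0.1, 4))
                 for _ in range(5)] for _ in range(40)]
        avg_var = np.var([fcs.average_curves(r).g for r in reps], axis=0)
        single_var = np.var([r[0].g for r in reps], axis=0)
        assert np.all(avg_var <= single_var)


class TestFitCurve:
    def test_exact_recovery_one_component(self, multi_tau_lags):
        truth = fcs.FcsModel.one_component(n_particles=1.7, dwell_time=3e-4)
        curve = fcs.CorrelationCurve(multi_tau_lags,
                                     fcs.model_g(truth, multi_tau_lags))
        spec = fcs.FcsModel.one_component(n_particles=1.0, dwell_time=1e-4)
        fit = fcs.fit_curve(curve, spec)
        assert fit.converged
        assert fit.model.n_particles == pytest.approx(1.7, rel=1e-6)
        assert fit.model.components[0].dwell_time == pytest.approx(3e-4,
                                                                   rel=1e-6)

    def test_exact_recovery_two_component(self, exact_2c_curve):
        curve, truth = exact_2c_curve
        spec = fcs.FcsModel.two_component(1.0, 1e-4, 1e-3, 0.8)
        fit = fcs.fit_curve(curve, spec)
        assert fit.model.n_particles == pytest.approx(0.8, rel=1e-5)
        assert fit.model.components[0].dwell_time == pytest.approx(1.8e-4,
                                                                   rel=1e-4)
        assert fit.model.components[0].fraction == pytest.approx(0.93,
                                                                 abs=1e-4)

    def test_components_sorted_fast_to_slow(self, exact_2c_curve):
        curve, _ = exact_2c_curve
        spec = fcs.FcsModel.two_component(1.0, 5e-3, 1e-2, 0.3)
        fit = fcs.fit_curve(curve, spec)
        assert (fit.model.components[0].dwell_time
                < fit.model.components[1].dwell_time)

    def test_one_component_fit_worse_on_two_component_data(
            self, exact_2c_curve):
        curve, _ = exact_2c_curve
        noisy = fcs.CorrelationCurve(
            curve.lags,
            curve.g + np.random.default_rng(5).normal(0, 1e-3,
                                                      len(curve.lags)))
        fit1 = fcs.fit_curve(noisy, fcs.FcsModel.one_component())
        fit2 = fcs.fit_curve(noisy, fcs.FcsModel.two_component())
        assert fit2.reduced_chi2 < fit1.reduced_chi2 * (1 + 1e-9)

    def test_needs_enough_lags(self):
        lags = np.logspace(-5, -3, 5)
        curve = fcs.CorrelationCurve(lags, np.ones(5))
        with pytest.raises(ValueError):
            fcs.fit_curve(curve, fcs.FcsModel.one_component())

    def test_derived_quantities_attached_with_calibration(self,
                                                          exact_2c_curve):
        curve, _ = exact_2c_curve
        cal = fcs.CalibrationResult(0.2, 1.0, 435.0)
        fit = fcs.fit_curve(curve, fcs.FcsModel.two_component(),
                            calibration=cal)
        d_fast = 0.2 ** 2 / (4 * fit.model.components[0].dwell_time)
        assert fit.derived_d[0] == pytest.approx(d_fast, rel=1e-12)
        assert fit.concentration_nm == pytest.approx(
            fcs.concentration(fit.model.n_particles, cal), rel=1e-12)


class TestCalibrate:
    def _reference_curve(self, tau_d, s=5.0, n=0.3):
        lags = np.array([lag for lag, _, _ in
                         fcs.multi_tau_lag_grid(2_000_000, 4e-6,
                                                max_lag=0.5)])
        model = fcs.FcsModel.one_component(
            n_particles=n, dwell_time=tau_d, structural_parameter=s)
        return fcs.CorrelationCurve(lags, fcs.model_g(model, lags))

    def test_closed_form_lateral_radius(self):
        curve = self._reference_curve(2.0e-5)
        cal = fcs.calibrate(curve, reference_d=500.0)
        assert cal.omega_o == pytest.approx(np.sqrt(4 * 500 * 2e-5),
                                            rel=1e-4)
        assert cal.omega_o == pytest.approx(0.2, rel=1e-4)
        assert cal.structural_parameter == pytest.approx(5.0, rel=1e-3)

    def test_effective_volume_formula(self):
        cal = fcs.CalibrationResult(0.2, 1.0, 435.0)
        assert cal.v_eff_fl == pytest.approx(np.pi ** 1.5 * 0.04 * 1.0,
                                             rel=1e-12)
        assert cal.v_eff_fl == pytest.approx(0.2227, abs=2e-4)

    def test_radius_scales_with_sqrt_of_reference_d(self):
        curve = self._reference_curve(2.0e-5)
        a = fcs.calibrate(curve, reference_d=400.0)
        b = fcs.calibrate(curve, reference_d=800.0)
        assert b.omega_o / a.omega_o == pytest.approx(np.sqrt(2), rel=1e-6)

    def test_warns_on_odd_structural_parameter(self):
        curve = self._reference_curve(2.0e-5, s=15.0)
        with pytest.warns(fcs.CalibrationQualityWarning):
            fcs.calibrate(curve, reference_d=500.0)


class TestSelectModel:
    def _noisy(self, model, lags, sigma, seed):
        rng = np.random.default_rng(seed)
        g = fcs.model_g(model, lags) + rng.normal(0, sigma, len(lags))
        return fcs.CorrelationCurve(lags, g,
                                    weights=np.full(len(lags), sigma))

    def test_one_component_data_selects_one_component(self, multi_tau_lags):
        truth = fcs.FcsModel.one_component(n_particles=1.0, dwell_time=3e-4,
                                           triplet_fraction=0.0)
        curve = self._noisy(truth, multi_tau_lags, 0.01, 0)
        f1 = fcs.fit_curve(curve, fcs.FcsModel.one_component())
        f2 = fcs.fit_curve(curve, fcs.FcsModel.two_component())
        sel = fcs.select_model(curve, f1, f2)
        assert sel.choice == 1

    def test_separated_two_component_data_selects_two(self, multi_tau_lags):
        truth = fcs.FcsModel.two_component(1.0, 2e-4, 5e-3, 0.85,
                                           triplet_fraction=0.0)
        curve = self._noisy(truth, multi_tau_lags, 0.005, 1)
        f1 = fcs.fit_curve(curve, fcs.FcsModel.one_component())
        f2 = fcs.fit_curve(curve, fcs.FcsModel.two_component())
        sel = fcs.select_model(curve, f1, f2)
        assert sel.choice == 2

    def test_narrow_window_rejected(self, exact_2c_curve):
        curve, _ = exact_2c_curve
        f1 = fcs.fit_curve(curve, fcs.FcsModel.one_component())
        f2 = fcs.fit_curve(curve, fcs.FcsModel.two_component())
        with pytest.raises(ValueError):
            fcs.select_model(curve, f1, f2, window=(1e-3, 1.1e-3))


class TestDerivedQuantities:
    def test_concentration_of_single_particle(self):
        cal = fcs.CalibrationResult(0.2, 1.0, 435.0)
        assert fcs.concentration(1.0, cal) == pytest.approx(7.46, abs=0.01)

    def test_concentration_linear_in_particle_number(self):
        cal = fcs.CalibrationResult(0.2, 1.0, 435.0)
        assert fcs.concentration(0.5, cal) == pytest.approx(
            fcs.concentration(1.0, cal) / 2, rel=1e-12)
        assert fcs.concentration(0.5, cal) == pytest.approx(3.73, abs=0.01)

    def test_concentration_inverse_in_volume(self):
        a = fcs.CalibrationResult(0.2, 1.0, 435.0)
        b = fcs.CalibrationResult(0.2 * 2 ** (1 / 3), 1.0 * 2 ** (1 / 3),
                                  435.0)
        assert fcs.concentration(1.0, b) == pytest.approx(
            fcs.concentration(1.0, a) / 2, rel=1e-9)

    def test_count_rate_definition_and_subtraction(self):
        tr = fcs.PhotonTrace(1e-3, np.full(10_000, 1))  # 10k counts / 10 s
        assert fcs.count_rate(tr) == pytest.approx(1.0)
        assert fcs.count_rate(tr, background_khz=0.4) == pytest.approx(0.6)

    def test_count_rate_clips_at_zero_with_warning(self):
        tr = fcs.PhotonTrace(1e-3, np.full(1000, 1))
        with pytest.warns(UserWarning):
            assert fcs.count_rate(tr, background_khz=5.0) == 0.0
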