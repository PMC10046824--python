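"""Convolution-model fitting, chi-square-doubling intervals, PS-term dose."""

import numpy as np
import pytest

import calodose as cd
from conftest import CT_SETTINGS


def ct_run(schedule, params, *, sigma=0.002, seed=0, drift=cd.DriftParams(0.003, 0.2),
           settings=(100.0,)):
    return cd.simulate_ct_series(
        list(settings), params, schedule, drift, cd.NoiseSpec(sigma, seed)
    )


class TestFitTransient:
    def test_noiseless_self_consistency(self, ct_schedule, table_params):
        wfs = ct_run(ct_schedule, table_params, sigma=0.0)
        fit = cd.fit_transient(wfs, ct_schedule, init=table_params)
        assert fit.converged
        for name in ("k1", "k2", "tau1", "tau2"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(table_params, name), rel=1e-3
            )
        assert fit.chi2_min < 1e-20
        assert fit.per_run_drifts[0].slope == pytest.approx(0.003, rel=1e-6)
        assert fit.per_run_drifts[0].offset == pytest.approx(0.2, rel=1e-6)

    def test_fast_time_constant_within_published_band(self, ct_schedule, table_params):
        wfs = ct_run(ct_schedule, table_params, seed=7)
        fit = cd.fit_transient(wfs, ct_schedule)  # cold start through the grid
        assert fit.converged
        assert 1.4 - 0.7 <= fit.params.tau1 <= 1.4 + 0.6

    def test_amplitude_ratio_matches_published_value(self, table_params):
        assert table_params.k1 / table_params.k2 == pytest.approx(16.9, abs=0.05)
        assert round(table_params.k1 / table_params.k2) == 17

    def test_amplitudes_scale_with_waveform_rescaling(self, ct_schedule, table_params):
        wfs = ct_run(ct_schedule, table_params, seed=3)
        doubled = [w.with_samples(2.0 * w.samples) for w in wfs]
        f1 = cd.fit_transient(wfs, ct_schedule, init=table_params)
        f2 = cd.fit_transient(doubled, ct_schedule, init=table_params)
        assert f2.params.k1 == pytest.approx(2 * f1.params.k1, rel=1e-6)
        assert f2.params.k2 == pytest.approx(2 * f1.params.k2, rel=1e-6)
        assert f2.params.tau1 == pytest.approx(f1.params.tau1, rel=1e-6)

    def test_median_parameter_recovery_over_seeds(self, ct_schedule, table_params):
        errs = {n: [] for n in ("k1", "k2", "tau1", "tau2")}
        for seed in range(24):
            wfs = ct_run(ct_schedule, table_params, seed=seed)
            fit = cd.fit_transient(wfs, ct_schedule, init=table_params)
            for n in errs:
                rel = getattr(fit.params, n) / getattr(table_params, n) - 1.0
                errs[n].append(abs(rel))
        for n, e in errs.items():
            assert np.median(e) < 0.05, f"median recovery error of {n}: {np.median(e):.3f}"

    def test_shared_parameters_across_dose_rates(self, ct_schedule, table_params):
        settings = [150.0, 350.0, 650.0]
        wfs = cd.simulate_ct_series(
            settings, table_params, ct_schedule,
            [cd.DriftParams(0.001, 0.0), cd.DriftParams(-0.002, 0.3),
             cd.DriftParams(0.004, -0.1)],
            cd.NoiseSpec(0.002, 21),
        )
        fit = cd.fit_transient(wfs, ct_schedule, init=table_params, settings_mAs=settings)
        assert fit.converged
        assert len(fit.per_run_drifts) == 3
        # amplitudes come back per 100 mA*s despite the per-run scaling
        assert fit.params.k1 == pytest.approx(table_params.k1, rel=0.05)
        assert fit.params.k2 == pytest.approx(table_params.k2, rel=0.05)

    def test_init_outside_bounds_rejected(self, ct_schedule, table_params):
        wfs = ct_run(ct_schedule, table_params, sigma=0.0)
        bad = cd.TransientParams(0.27, 0.016, 1.4, 628.0)
        with pytest.raises(ValueError, match="bounds"):
            cd.fit_transient(wfs, ct_schedule, bad, tau_bounds=((0.05, 1.0), (10, 1e5)))

    def test_fit_pressed_to_bound_flagged_not_converged(self, ct_schedule, table_params):
        wfs = ct_run(ct_schedule, table_params, sigma=0.0)
        init = cd.TransientParams(0.27, 0.016, 4.0, 628.0)
        fit = cd.fit_transient(
            wfs, ct_schedule, init, tau_bounds=((3.999999, 50.0), (10, 1e5))
        )
        assert not fit.converged
        with pytest.raises(ValueError, match="non-converged"):
            cd.param_uncertainty(fit, "tau1", wfs, ct_schedule)

    def test_empty_input_rejected(self, ct_schedule):
        with pytest.raises(ValueError):
            cd.fit_transient([], ct_schedule)


class TestChiSquareDoubling:
    def test_quadratic_closed_form(self):
        # chi2 = 1 + (theta-2)^2 doubles at theta = 1, 3: interval (-1, +1)
        lo, hi, lo_open, hi_open = cd.chi_square_doubling_interval(
            lambda t: 1.0 + (t - 2.0) ** 2, best=2.0, chi2_min=1.0
        )
        assert lo == pytest.approx(-1.0, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-9)
        assert not (lo_open or hi_open)

    def test_asymmetric_piecewise_branches(self):
        def chi2(t):
            d = t - 2.0
            return 1.0 + (d * d if d > 0 else 4.0 * d * d)

        lo, hi, *_ = cd.chi_square_doubling_interval(chi2, best=2.0, chi2_min=1.0)
        assert lo == pytest.approx(-0.5, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-9)

    def test_flat_objective_flagged_open(self):
        lo, hi, lo_open, hi_open = cd.chi_square_doubling_interval(
            lambda t: 1.0, best=0.0, chi2_min=1.0, max_expand=10
        )
        assert lo_open and hi_open

    def test_zero_minimum_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cd.chi_square_doubling_interval(lambda t: (t - 1.0) ** 2, best=1.0)

    def test_profile_interval_on_noisy_series_same_decade_as_published(
        self, ct_schedule, table_params
    ):
        # eleven-setting series, as in the experiment; published tau2 band (-50, +86)
        wfs = cd.simulate_ct_series(
            CT_SETTINGS, table_params, ct_schedule,
            cd.DriftParams(0.003, 0.2), cd.NoiseSpec(0.002, 3),
        )
        fit = cd.fit_transient(wfs, ct_schedule, init=table_params,
                               settings_mAs=CT_SETTINGS)
        iv = cd.param_uncertainty(fit, "tau2", wfs, ct_schedule, settings_mAs=CT_SETTINGS)
        assert not (iv.lower_open or iv.upper_open)
        assert 0.1 <= iv.upper_dev / 86.0 <= 10.0
        assert 0.1 <= -iv.lower_dev / 50.0 <= 10.0

    def test_profile_widens_or_equals_strict_slice(self, ct_schedule, table_params):
        wfs = ct_run(ct_schedule, table_params, seed=7)
        fit = cd.fit_transient(wfs, ct_schedule, init=table_params)
        prof = cd.param_uncertainty(fit, "tau1", wfs, ct_schedule, profile_drifts=True)
        strict = cd.param_uncertainty(fit, "tau1", wfs, ct_schedule, profile_drifts=False)
        assert prof.upper_dev >= strict.upper_dev - 1e-9
        assert prof.lower_dev <= strict.lower_dev + 1e-9

    def test_unknown_parameter_rejected(self, ct_schedule, table_params):
        wfs = ct_run(ct_schedule, table_params, sigma=0.0)
        fit = cd.fit_transient(wfs, ct_schedule, init=table_params)
        with pytest.raises(ValueError, match="unknown parameter"):
            cd.param_uncertainty(fit, "tau3", wfs, ct_schedule)


class TestPsComponentDose:
    def test_staircase_term_dose_near_published_value(self, ct_schedule, table_params):
        wfs = ct_run(ct_schedule, table_params, sigma=0.0)
        fit = cd.fit_transient(wfs, ct_schedule, init=table_params)
        ps = cd.ps_component_dose(fit, ct_schedule, 1208.0)
        # published chain: ~0.030 mK/cycle -> ~36 mGy per cycle per 100 mA*s;
        # midpoint extrapolation returns the loss-corrected step (k2*t_open), a
        # few percent above the net per-cycle rise, hence the loose tolerance
        assert ps.mean_delta_T_mK == pytest.approx(0.030, rel=0.10)
        assert ps.dose_mGy == pytest.approx(36.0, rel=0.10)

    def test_zero_slow_amplitude_gives_zero_dose(self, ct_schedule):
        fit = cd.FitResult(
            params=cd.TransientParams(0.27, 0.0, 1.4, 628.0),
            per_run_drifts=(cd.DriftParams(),),
            chi2_min=0.0, n_points=100, mode="analytic", converged=True,
        )
        ps = cd.ps_component_dose(fit, ct_schedule, 1208.0)
        assert ps.dose_mGy == pytest.approx(0.0, abs=1e-12)

    def test_factor_versus_chamber_dose(self):
        ps = cd.PSComponentDose(mean_delta_T_mK=0.030, dose_mGy=36.24,
                                cp_used=1208.0, n_cycles=10)
        assert ps.factor_vs_ic(2.46) == pytest.approx(14.7, abs=0.05)
        assert ps.factor_vs_ic(2.46, rounded=True) == 15
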