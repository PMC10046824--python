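"""Timing function, closed-form convolution, discrete mode, CSV round trip."""

import numpy as np
import pytest

import calodose as cd
from calodose.waveform import DISCRETE_COMPENSATION


class TestTimingFunction:
    def test_on_and_off_instants(self, ct_schedule):
        s = ct_schedule
        assert cd.timing_function(s.t_start + 0.5, s) == 1.0
        assert cd.timing_function(s.t_start + 5.0, s) == 0.0
        # half-open convention: on at the leading edge, off at the trailing edge
        assert cd.timing_function(s.t_start, s) == 1.0
        assert cd.timing_function(s.t_start + s.t_open, s) == 0.0
        # off before the first pulse and after the last cycle
        assert cd.timing_function(s.t_start - 0.1, s) == 0.0
        assert cd.timing_function(s.t_end + 0.1, s) == 0.0

    def test_mean_over_period_is_duty_cycle(self, ct_schedule):
        s = ct_schedule
        t = s.t_start + s.dt * np.arange(int(s.period / s.dt))
        mean = cd.timing_function(t, s).mean()
        assert abs(mean - s.duty_cycle) <= s.dt / s.period


class TestForwardWaveform:
    def test_single_pulse_closed_form(self):
        # boxcar * exponential evaluated at the end of the pulse: k*tau*(1 - exp(-w/tau))
        s = cd.IrradiationSchedule(t_open=2.0, period=10.0, n_cycles=1, t_start=0.0, dt=0.25)
        wf = cd.forward_waveform(
            cd.TransientParams(k1=1.0, k2=0.0, tau1=1.4, tau2=100.0), cd.DriftParams(), s
        )
        i = int(round(s.t_open / s.dt))
        assert wf.samples[i] == pytest.approx(1.4 * (1 - np.exp(-2 / 1.4)), rel=1e-12)
        assert wf.samples[i] == pytest.approx(1.064, abs=1e-3)

    def test_slow_term_limit_is_pure_staircase(self, ct_schedule, staircase_params):
        wf = cd.forward_waveform(staircase_params, cd.DriftParams(), ct_schedule, t0=0.0)
        k2, w = staircase_params.k2, ct_schedule.t_open
        total_on = ct_schedule.n_cycles * w
        assert wf.samples[-1] == pytest.approx(k2 * total_on, rel=1e-6)

    def test_per_cycle_increase_of_slow_term(self, ct_schedule, staircase_params):
        # over one full cycle the staircase grows by k2 * t_open (tau2 >> period)
        wf = cd.forward_waveform(staircase_params, cd.DriftParams(), ct_schedule, t0=0.0)
        per = int(round(ct_schedule.period / ct_schedule.dt))
        i = int(round((ct_schedule.t_start - wf.t0) / ct_schedule.dt))
        step = wf.samples[i + 2 * per] - wf.samples[i + per]
        assert step == pytest.approx(staircase_params.k2 * ct_schedule.t_open, rel=5e-3)

    def test_linear_in_amplitudes_and_drift(self, ct_schedule, table_params):
        d = cd.DriftParams(slope=0.01, offset=-0.3)
        wf = cd.forward_waveform(table_params, d, ct_schedule)
        wf2 = cd.forward_waveform(table_params.scaled(2.0), d, ct_schedule)
        base = cd.forward_waveform(table_params, cd.DriftParams(), ct_schedule)
        np.testing.assert_allclose(wf2.samples - d.line(wf2.times), 2 * base.samples, atol=1e-12)
        np.testing.assert_allclose(wf.samples - base.samples, d.line(wf.times), atol=1e-12)

    def test_zero_amplitudes_give_exact_drift_line(self, ct_schedule):
        d = cd.DriftParams(slope=0.002, offset=1.5)
        wf = cd.forward_waveform(
            cd.TransientParams(0.0, 0.0, 1.4, 628.0), d, ct_schedule, t0=0.0
        )
        np.testing.assert_array_equal(wf.samples, d.line(wf.times))

    def test_fast_and_slow_terms_sum_to_both(self, ct_schedule, table_params):
        kw = dict(drift=cd.DriftParams(), schedule=ct_schedule, t0=0.0)
        both = cd.forward_waveform(table_params, **kw)
        fast = cd.forward_waveform(table_params, terms="fast", **kw)
        slow = cd.forward_waveform(table_params, terms="slow", **kw)
        np.testing.assert_allclose(fast.samples + slow.samples, both.samples, atol=1e-12)

    def test_unresolved_pulse_rejected(self):
        s = cd.IrradiationSchedule(t_open=2.0, period=10.0, n_cycles=2, dt=2.5)
        with pytest.raises(ValueError, match="resolve"):
            cd.forward_waveform(cd.TransientParams(1, 0.1, 1.4, 628), cd.DriftParams(), s)


class TestDiscreteMode:
    def test_coarse_step_underestimates_exact_convolution(self, ct_schedule, table_params):
        a = cd.forward_waveform(table_params, cd.DriftParams(), ct_schedule, "analytic", t0=0.0)
        d = cd.forward_waveform(table_params, cd.DriftParams(), ct_schedule, "discrete", t0=0.0)
        assert np.all(d.samples <= a.samples + 1e-12)
        # the deficit is a few percent of the peak at the 0.25 s step
        assert np.max(a.samples - d.samples) / np.max(a.samples) > 0.01

    def test_compensation_raises_both_amplitudes(self, ct_schedule, table_params):
        d = cd.forward_waveform(table_params, cd.DriftParams(), ct_schedule, "discrete")
        dc = cd.forward_waveform(
            table_params, cd.DriftParams(), ct_schedule, "discrete", compensate=True
        )
        np.testing.assert_allclose(dc.samples, DISCRETE_COMPENSATION * d.samples, rtol=1e-12)

    def test_modes_converge_as_dt_shrinks(self, table_params):
        s = cd.IrradiationSchedule(t_open=2.0, period=10.0, n_cycles=10, t_start=10.0, dt=0.001)
        a = cd.forward_waveform(table_params, cd.DriftParams(), s, "analytic", t0=0.0)
        d = cd.forward_waveform(table_params, cd.DriftParams(), s, "discrete", t0=0.0)
        rel = np.max(np.abs(a.samples - d.samples)) / np.max(np.abs(a.samples))
        assert rel < 1e-3


class TestTemperatureWaveform:
    def test_csv_round_trip(self, tmp_path, ct_schedule, table_params):
        wf = cd.forward_waveform(table_params, cd.DriftParams(0.01, 0.2), ct_schedule)
        path = tmp_path / "wf.csv"
        wf.to_csv(path)
        assert path.read_text().splitlines()[0] == "time_s,temp_mK"
        back = cd.TemperatureWaveform.from_csv(path)
        assert back.t0 == pytest.approx(wf.t0)
        assert back.dt == pytest.approx(wf.dt)
        np.testing.assert_allclose(back.samples, wf.samples, rtol=1e-12)

    def test_rejects_nonuniform_sampling(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,temp_mK\n0.0,1.0\n1.0,2.0\n3.0,4.0\n")
        with pytest.raises(ValueError, match="uniform"):
            cd.TemperatureWaveform.from_csv(path)

    def test_rejects_degenerate_records(self):
        with pytest.raises(ValueError):
            cd.TemperatureWaveform(0.0, 1.0, np.array([1.0]))
        with pytest.raises(ValueError):
            cd.TemperatureWaveform(0.0, -1.0, np.array([1.0, 2.0]))


class TestScheduleValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t_open=10.0, period=10.0, n_cycles=1),
            dict(t_open=0.0, period=10.0, n_cycles=1),
            dict(t_open=2.0, period=10.0, n_cycles=0),
            dict(t_open=2.0, period=10.0, n_cycles=1, dt=0.0),
        ],
    )
    def test_invalid_schedules_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cd.IrradiationSchedule(**kwargs)
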