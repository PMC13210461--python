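"""Structural model: clearance power law and the event-stepped infusion
solution, cross-checked against closed forms and a stiff ODE oracle."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from linzpk import (
    IndividualParameters,
    PopulationParameters,
    RegimenSpec,
    Subject,
    auc_window,
    clearance_at,
    simulate_concentrations,
    simulate_regimen,
    steady_state_trough,
    trough_on_day,
)
from linzpk.dataset_io import CovariateSeries, DoseEvent
from linzpk import _engine
from linzpk.structural_pk import clearance_segments


def _constant_cl_params(cl=4.25, v=25.6):
    """Zero out covariate exponents so clearance is time-constant."""
    return PopulationParameters(cl_pop=cl, v_pop=v).with_(
        beta_egfr=0.0, beta_day=0.0, beta_age=0.0
    )


class TestClearance:
    def test_reference_covariates_return_typical_value(self):
        assert clearance_at(59.6, 3.5, 78.0) == pytest.approx(4.25, abs=1e-12)

    def test_eta_scales_exponentially(self):
        assert clearance_at(59.6, 3.5, 78.0, eta=math.log(2)) == pytest.approx(8.50)

    def test_printed_power_model_low_renal_function(self):
        # independent evaluation of 4.25*(25/59.6)^0.29*(10/3.5)^-0.18
        expected = 4.25 * (25 / 59.6) ** 0.29 * (10 / 3.5) ** -0.18
        assert clearance_at(25.0, 10.0, 78.0) == pytest.approx(expected)
        assert expected == pytest.approx(2.73, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            clearance_at(-5.0, 3.0, 78.0)
        with pytest.raises(ValueError):
            clearance_at(50.0, 0.5, 78.0)


def _subject(doses, egfr=59.6, age=78.0):
    return Subject(
        id="S",
        doses=tuple(doses),
        observations=(),
        covariates=CovariateSeries(age=age, egfr=((0.0, egfr),)),
    )


class TestSimulation:
    def test_no_doses_design_gives_zero_profile(self, params):
        # engine-level: a design without doses yields identically zero
        d = _engine.build_design([], [0.0, 5.0, 20.0], age=78, egfr_series=((0.0, 50.0),))
        conc = _engine.propagate(d, np.full(d.n_segments, 4.25), 25.6)
        assert np.all(conc == 0.0)

    def test_single_dose_end_of_infusion_closed_form(self):
        p = _constant_cl_params()
        s = _subject([DoseEvent(0.0, 600.0, 1.0)])
        prof = simulate_concentrations(s, p, query_times=[1.0])
        k = 4.25 / 25.6
        expected = (600 / 4.25) * (1 - math.exp(-k))
        assert prof.concentrations[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(21.6, abs=0.01)

    def test_zero_before_first_dose(self, params):
        s = _subject([DoseEvent(5.0, 600.0, 1.0)])
        prof = simulate_concentrations(s, params, query_times=[0.0, 2.0, 4.9, 6.0])
        assert np.all(prof.concentrations[:3] == 0.0)
        assert prof.concentrations[3] > 0

    def test_washout_monotone_to_zero(self):
        p = _constant_cl_params()
        s = _subject([DoseEvent(0.0, 600.0, 1.0)])
        t = np.linspace(1.0, 200.0, 80)
        prof = simulate_concentrations(s, p, query_times=t)
        assert np.all(np.diff(prof.concentrations) < 0)
        assert prof.concentrations[-1] < 1e-8

    def test_linearity_in_dose(self, params):
        s1 = _subject([DoseEvent(i * 12.0, 300.0) for i in range(6)])
        s2 = _subject([DoseEvent(i * 12.0, 600.0) for i in range(6)])
        t = np.linspace(1, 70, 40)
        c1 = simulate_concentrations(s1, params, query_times=t).concentrations
        c2 = simulate_concentrations(s2, params, query_times=t).concentrations
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-10)

    def test_individual_eta_scales_clearance(self, params):
        s = _subject([DoseEvent(0.0, 600.0)])
        hi = simulate_concentrations(
            s, params, IndividualParameters(eta_cl=0.5), query_times=[12.0]
        )
        lo = simulate_concentrations(
            s, params, IndividualParameters(eta_cl=-0.5), query_times=[12.0]
        )
        assert hi.concentrations[0] < lo.concentrations[0]

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_ode_oracle_random_regimens(self, seed, params):
        """Event-stepped analytic solution vs a stiff ODE integrator on random
        regimens with time-varying clearance: < 0.01 mg/L everywhere."""
        rng = np.random.default_rng(seed)
        n_doses = rng.integers(2, 8)
        interval = rng.uniform(6, 24)
        dose = rng.uniform(200, 900)
        dur = rng.uniform(0.5, 2.0)
        egfr = rng.uniform(15, 120)
        age = rng.uniform(65, 87)
        eta = rng.normal(0, 0.3)
        doses = [DoseEvent(i * interval, dose, dur) for i in range(n_doses)]
        t_end = n_doses * interval + 12
        t = np.linspace(0.0, t_end, 97)
        s = _subject(doses, egfr=egfr, age=age)
        prof = simulate_concentrations(
            s, params, IndividualParameters(eta_cl=eta), query_times=t
        )

        v = params.v_pop

        def rate_in(tt):
            return sum(d.rate for d in doses if d.time < tt < d.time + d.infusion_duration)

        def cl_t(tt):
            day = math.floor(tt / 24.0) + 1
            return clearance_at(egfr, day, age, eta, params)

        def rhs(tt, y):
            return [rate_in(tt) / v - (cl_t(tt) / v) * y[0]]

        # integrate piecewise so discontinuities land on interval ends
        breaks = sorted(
            {0.0, t_end}
            | {d.time for d in doses}
            | {d.time + d.infusion_duration for d in doses}
            | {24.0 * k for k in range(int(t_end // 24) + 1)}
            | set(t)
        )
        y = 0.0
        oracle = {0.0: 0.0}
        for a, b in zip(breaks[:-1], breaks[1:]):
            sol = solve_ivp(
                rhs, (a, b), [y], method="LSODA", rtol=1e-10, atol=1e-12
            )
            y = sol.y[0, -1]
            oracle[b] = y
        ode_vals = np.array([oracle[tt] for tt in t])
        assert np.max(np.abs(prof.concentrations - ode_vals)) < 0.01


class TestTroughs:
    def test_steady_state_matches_closed_form(self):
        p = _constant_cl_params()
        reg = RegimenSpec(n_doses=60)  # 30 days >> 10 half-lives (t1/2 ~ 4.2 h)
        sim = trough_on_day(reg, 28, p, egfr=59.6, age=78.0)
        ss = steady_state_trough(600, 12, 1, 4.25, 25.6)
        assert sim == pytest.approx(ss, rel=5e-3)

    def test_typical_elderly_day3_inside_band(self, params):
        tr = trough_on_day(RegimenSpec(n_doses=10), 3, params, egfr=75.0, age=78.0)
        assert 2.0 <= tr <= 7.0

    def test_trough_linear_in_dose(self):
        p = _constant_cl_params()
        r1 = RegimenSpec(dose=600, n_doses=10)
        r2 = RegimenSpec(dose=60, n_doses=10)
        t1 = trough_on_day(r1, 4, p, 59.6, 78.0)
        t2 = trough_on_day(r2, 4, p, 59.6, 78.0)
        assert t2 == pytest.approx(t1 / 10, rel=1e-10)

    def test_day_outside_regimen_rejected(self, params):
        with pytest.raises(ValueError):
            trough_on_day(RegimenSpec(n_doses=4), 10, params, 50.0, 78.0)

    def test_accumulation_under_negative_day_exponent(self, params):
        """With beta_day < 0, clearance declines over days, so troughs under
        fixed covariates are non-decreasing day over day."""
        reg = RegimenSpec(n_doses=30)
        troughs = [
            trough_on_day(reg, d, params, egfr=45.0, age=78.0) for d in range(1, 13)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(troughs, troughs[1:]))


class TestAUC:
    def test_single_dose_total_auc_is_dose_over_cl(self):
        p = _constant_cl_params()
        a = auc_window(RegimenSpec(n_doses=1), 0, 400, p, 59.6, 78.0, method="analytic")
        assert a == pytest.approx(600 / 4.25, rel=1e-3)

    def test_trapezoid_vs_analytic_below_point1_percent(self, params):
        reg = RegimenSpec(n_doses=8)
        at = auc_window(reg, 48, 72, params, 45.0, 78.0, grid_step=0.1)
        aa = auc_window(reg, 48, 72, params, 45.0, 78.0, method="analytic")
        assert abs(at - aa) / aa < 1e-3

    def test_zero_concentration_window(self, params):
        a = auc_window(RegimenSpec(n_doses=1), 30, 31, _constant_cl_params(cl=400.0), 59.6, 78.0)
        assert a == pytest.approx(0.0, abs=1e-6)

    def test_invalid_window_rejected(self, params):
        with pytest.raises(ValueError):
            auc_window(RegimenSpec(), 10, 5, params, 50.0, 78.0)
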