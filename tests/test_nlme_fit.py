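"""FOCE-I estimator: Laplace objective vs exact quadrature, limiting cases,
empirical Bayes, and stepwise covariate selection."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from linzpk import (
    IndividualParameters,
    PopulationParameters,
    StudyDataset,
    Subject,
    empirical_bayes,
    eta_shrinkage,
    fit_population,
    individual_neg2ll,
    ofv,
    simulate_concentrations,
)
from linzpk.dataset_io import ConcentrationRecord, CovariateSeries, DoseEvent
from linzpk.nlme_fit import DEFAULT_TERMS, CovariateTerm, covariate_search


def _toy_subject(rng, params, ident, n_obs):
    """A q12h course with noisy observations at random times."""
    egfr = rng.uniform(25, 100)
    age = rng.uniform(66, 86)
    doses = tuple(DoseEvent(12.0 * k, 600.0, 1.0) for k in range(8))
    times = np.sort(rng.uniform(2, 90, n_obs))
    eta = rng.normal(0, params.omega_cl)
    shell = Subject(
        id=ident,
        doses=doses,
        observations=(),
        covariates=CovariateSeries(age=age, egfr=((0.0, egfr),)),
    )
    f = simulate_concentrations(
        shell, params, IndividualParameters(eta_cl=eta), query_times=times
    ).concentrations
    obs = []
    for t, fj in zip(times, f):
        y = fj * (1 + params.sigma_prop * rng.standard_normal())
        while y <= 0.8:
            y = fj * (1 + params.sigma_prop * rng.standard_normal())
        obs.append(ConcentrationRecord(time=float(t), value=float(y)))
    return Subject(
        id=ident, doses=doses, observations=tuple(obs), covariates=shell.covariates
    )


@pytest.fixture(scope="module")
def toy_data(params):
    rng = np.random.default_rng(42)
    subs = tuple(_toy_subject(rng, params, f"T{i}", n) for i, n in enumerate([2, 3, 4]))
    return StudyDataset(subjects=subs)


def _exact_minus2ll(subject, params, half_width=6.0):
    """Adaptive quadrature of the marginal likelihood over eta."""

    def integrand(eta):
        return math.exp(-0.5 * individual_neg2ll(eta, subject, params))

    lim = half_width * params.omega_cl
    val, _ = quad(integrand, -lim, lim, limit=200, epsabs=1e-14, epsrel=1e-12)
    return -2.0 * math.log(val)


class TestObjective:
    def test_laplace_close_to_quadrature_oracle(self, toy_data, params):
        """The Laplace (FOCE-I) OFV tracks the exactly integrated -2LL to
        well under one OFV unit on a 9-observation toy set."""
        exact = sum(_exact_minus2ll(s, params) for s in toy_data.subjects)
        assert abs(ofv(params, toy_data) - exact) < 0.5

    def test_laplace_close_to_oracle_off_mode(self, toy_data, params):
        shifted = params.with_(cl_pop=5.0, omega_cl=0.45)
        exact = sum(_exact_minus2ll(s, shifted) for s in toy_data.subjects)
        assert abs(ofv(shifted, toy_data) - exact) < 0.5

    def test_zero_iiv_limit_is_fixed_effects_loglik(self, toy_data, params):
        """As omega -> 0 the Laplace OFV reduces exactly to the fixed-effects
        -2LL at eta = 0 (prior and curvature terms cancel)."""
        tiny = params.with_(omega_cl=1e-7)
        expected = 0.0
        for s in toy_data.subjects:
            times = [o.time for o in s.observations]
            f = simulate_concentrations(s, params, query_times=times).concentrations
            y = np.array([o.value for o in s.observations])
            sd = params.sigma_prop * f
            expected += np.sum(np.log(2 * np.pi * sd**2) + (y - f) ** 2 / sd**2)
        assert ofv(tiny, toy_data) == pytest.approx(expected, abs=1e-6)

    def test_additive_over_subjects(self, toy_data, params):
        a = StudyDataset(subjects=toy_data.subjects[:1])
        b = StudyDataset(subjects=toy_data.subjects[1:])
        assert ofv(params, toy_data) == pytest.approx(
            ofv(params, a) + ofv(params, b), abs=1e-8
        )

    def test_individual_neg2ll_hand_formula(self, toy_data, params):
        """-2 log joint = residual term + prior term, assembled by hand."""
        s = toy_data.subjects[0]
        eta = 0.3
        times = [o.time for o in s.observations]
        f = simulate_concentrations(
            s, params, IndividualParameters(eta_cl=eta), query_times=times
        ).concentrations
        y = np.array([o.value for o in s.observations])
        sd = params.sigma_prop * f
        expected = float(
            np.sum(np.log(2 * np.pi * sd**2) + (y - f) ** 2 / sd**2)
            + math.log(2 * np.pi * params.omega_cl**2)
            + eta**2 / params.omega_cl**2
        )
        assert individual_neg2ll(eta, s, params) == pytest.approx(expected, rel=1e-10)


class TestEmpiricalBayes:
    def test_recovers_eta_when_residual_noise_is_tiny(self, params):
        low_noise = params.with_(sigma_prop=0.02)
        true_eta = 0.4
        doses = tuple(DoseEvent(12.0 * k, 600.0, 1.0) for k in range(8))
        times = [11.5, 35.5, 59.5, 83.5]
        shell = Subject(
            id="E",
            doses=doses,
            observations=(),
            covariates=CovariateSeries(age=78.0, egfr=((0.0, 50.0),)),
        )
        f = simulate_concentrations(
            shell, low_noise, IndividualParameters(eta_cl=true_eta), query_times=times
        ).concentrations
        obs = tuple(
            ConcentrationRecord(time=t, value=float(v)) for t, v in zip(times, f)
        )
        s = Subject(id="E", doses=doses, observations=obs, covariates=shell.covariates)
        eta_hat, se, fallback = empirical_bayes(s, low_noise)
        assert not fallback
        assert eta_hat == pytest.approx(true_eta, abs=0.01)
        assert 0 < se < 0.05  # four near-noiseless observations pin eta down

    def test_no_observations_falls_back_to_prior(self, params):
        s = Subject(
            id="N",
            doses=(DoseEvent(0.0, 600.0),),
            observations=(),
            covariates=CovariateSeries(age=78.0, egfr=((0.0, 50.0),)),
        )
        eta_hat, se, fallback = empirical_bayes(s, params)
        assert fallback and eta_hat == 0.0 and se == params.omega_cl

    def test_shrinkage_endpoints(self, params):
        w = params.omega_cl
        assert eta_shrinkage(np.full(10, 0.17), w) == pytest.approx(100.0)
        spread = np.array([-1.0, 1.0]) * w / math.sqrt(2.0)  # SD(ddof=1) == omega
        assert eta_shrinkage(spread, w) == pytest.approx(0.0, abs=1e-10)
        with pytest.raises(ValueError):
            eta_shrinkage(np.array([0.1]), w)


class TestFit:
    def test_all_fixed_returns_initial_values(self, toy_data, params):
        names = ["cl_pop", "v_pop", "omega_cl", "sigma_prop"] + [
            f"beta_{t.name}" for t in DEFAULT_TERMS
        ]
        res = fit_population(toy_data, init=params, fixed=names)
        assert res.params.cl_pop == params.cl_pop
        assert res.params.v_pop == params.v_pop
        assert res.ofv == pytest.approx(ofv(params, toy_data), abs=1e-8)

    def test_unknown_fixed_name_rejected(self, toy_data):
        with pytest.raises(ValueError, match="unknown fixed"):
            fit_population(toy_data, fixed=["banana"])

    def test_fit_beats_generating_values(self, small_cohort, params):
        """The ML estimate cannot have a higher OFV than the true generating
        parameters (up to optimizer tolerance)."""
        ds, _ = small_cohort
        res = fit_population(ds, compute_rse=False)
        assert res.converged
        assert res.ofv <= ofv(params, ds) + 1e-6

    def test_fixed_parameters_are_respected(self, small_cohort, params):
        ds, _ = small_cohort
        res = fit_population(
            ds, init=params, fixed=["v_pop", "beta_day", "beta_age"], compute_rse=False
        )
        assert res.params.v_pop == pytest.approx(params.v_pop)
        assert res.betas["day"] == pytest.approx(params.beta_day)
        assert res.betas["age"] == pytest.approx(params.beta_age)
        assert res.params.cl_pop != params.cl_pop  # the free ones moved

    def test_rse_and_parameter_table(self, small_cohort):
        ds, _ = small_cohort
        res = fit_population(ds, compute_rse=True)
        for name in ("cl_pop", "v_pop", "omega_cl", "sigma_prop"):
            assert name in res.rse
            assert np.isfinite(res.rse[name]) and res.rse[name] > 0
        table = res.parameter_table()
        assert len(table) == 4 + len(DEFAULT_TERMS)
        assert "estimate" in table.columns
        assert -50.0 < table.attrs["eta_shrinkage_percent"] < 100.0

    def test_ebes_match_standalone_empirical_bayes(self, small_cohort):
        ds, _ = small_cohort
        res = fit_population(ds, compute_rse=False)
        sid = ds.subjects[0].id
        eta_hat, _, _ = empirical_bayes(ds.subjects[0], res.params)
        assert res.ebes[sid] == pytest.approx(eta_hat, abs=1e-6)


class TestCovariateSearch:
    def test_selects_real_covariate_rejects_inert(self, study_cohort):
        """On a 103-subject cohort generated with an eGFR effect on CL, the
        stepwise search keeps eGFR and drops an inert weight covariate."""
        ds, _ = study_cohort
        trace = covariate_search(
            ds,
            [CovariateTerm("egfr", 59.6), CovariateTerm("weight", 70.0)],
            maxfev=1500,
        )
        assert trace.selected == ("egfr",)
        forward_egfr = [s for s in trace.steps if s[0] == "forward" and s[1] == "egfr"]
        assert forward_egfr[0][2] > 3.84  # significant OFV drop
        assert trace.final_fit is not None and "egfr" in trace.final_fit.betas

    def test_infinite_threshold_selects_nothing(self, small_cohort):
        ds, _ = small_cohort
        trace = covariate_search(
            ds,
            [CovariateTerm("egfr", 59.6)],
            forward_threshold=math.inf,
            maxfev=800,
        )
        assert trace.selected == ()
        assert all(s[3] == "excluded" for s in trace.steps)
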