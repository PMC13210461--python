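"""Nonlinear mixed-effects estimation (FOCE with interaction) for the
covariate-driven clearance model.

One scalar random effect acts on log-clearance.  For each subject the
conditional objective

    g_i(eta) = sum_j [ log(2 pi sigma_j^2) + (y_j - f_j)^2 / sigma_j^2 ]
               + log(2 pi omega^2) + eta^2 / omega^2,
    sigma_j = sigma_prop * f_j(eta)          (interaction),

is minimized over eta, and the marginal -2 log-likelihood is approximated by
the Laplace expansion at the conditional mode:

    OFV_i = g_i(eta_hat) + log( g_i''(eta_hat) / (4 pi) ).

The population objective (OFV) is the sum over subjects; fixed effects and
variance components are estimated by minimizing it on a transformed scale
(log for CL_pop, V, omega, sigma; identity for covariate exponents).
Standard errors come from the central finite-difference Hessian with
delta-method back-transformation; empirical Bayes estimates and eta-shrinkage
are computed at the optimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from . import _engine
from .dataset_io import StudyDataset, Subject
from .structural_pk import PopulationParameters

__all__ = [
    "CovariateTerm",
    "FitResult",
    "CovariateSearchTrace",
    "individual_neg2ll",
    "ofv",
    "fit_population",
    "empirical_bayes",
    "eta_shrinkage",
    "covariate_search",
    "DEFAULT_TERMS",
]

logger = logging.getLogger(__name__)

_LOG_4PI = math.log(4.0 * math.pi)
#: transformed-scale lower bound treated as a boundary estimate for variances
_VARIANCE_FLOOR = math.log(1e-3)


@dataclass(frozen=True)
class CovariateTerm:
    """A centered power term on clearance: (value/ref)^beta."""

    name: str
    ref: float

    def __post_init__(self) -> None:
        if not (self.ref > 0):
            raise ValueError("reference value must be positive")


DEFAULT_TERMS: tuple[CovariateTerm, ...] = (
    CovariateTerm("egfr", 59.6),
    CovariateTerm("day", 3.5),
    CovariateTerm("age", 78.0),
)


def _betas_from_params(params: PopulationParameters, terms) -> np.ndarray:
    mapping = {"egfr": params.beta_egfr, "day": params.beta_day, "age": params.beta_age}
    return np.array([mapping.get(t.name, 0.0) for t in terms], dtype=float)


def _params_with_betas(
    params: PopulationParameters, terms, betas: np.ndarray
) -> PopulationParameters:
    updates: dict = {"beta_egfr": 0.0, "beta_day": 0.0, "beta_age": 0.0}
    refs: dict = {}
    for t, b in zip(terms, betas):
        if t.name in ("egfr", "day", "age"):
            updates[f"beta_{t.name}"] = float(b)
            refs[f"{t.name}_ref"] = t.ref
    return replace(params, **updates, **refs)


class _SubjectData:
    """Cached design and log-covariate matrix for one subject."""

    __slots__ = ("subject", "design", "y", "logratio", "eta_warm")

    def __init__(self, subject: Subject, terms: Sequence[CovariateTerm]):
        obs = subject.analysis_observations
        times = np.array([o.time for o in obs], dtype=float)
        order = np.argsort(times, kind="stable")
        self.subject = subject
        self.y = np.array([o.value for o in obs], dtype=float)[order]
        self.design = _engine.design_for_subject(subject, times[order])
        cols = [
            np.log(self.design.covariate_values(t.name) / t.ref) for t in terms
        ]
        self.logratio = (
            np.column_stack(cols) if cols else np.zeros((self.design.n_segments, 0))
        )
        self.eta_warm = 0.0

    def base_cl(self, log_cl_pop: float, betas: np.ndarray) -> np.ndarray:
        return np.exp(log_cl_pop + self.logratio @ betas)


def _prepare(data: StudyDataset, terms) -> list[_SubjectData]:
    out = []
    for s in data.subjects:
        if not s.analysis_observations:
            raise ValueError(f"subject {s.id} has no quantifiable observations")
        out.append(_SubjectData(s, terms))
    return out


def _subject_inner(
    sd: _SubjectData,
    log_cl_pop: float,
    betas: np.ndarray,
    v: float,
    omega: float,
    sigma: float,
):
    base_cl = sd.base_cl(log_cl_pop, betas)
    return _engine._inner_minimize_kernel(
        sd.design.dt,
        sd.design.rate,
        base_cl,
        v,
        sd.design.query_idx,
        sd.y,
        omega * omega,
        sigma,
        sd.eta_warm,
    )


def individual_neg2ll(
    eta: float, subject: Subject, params: PopulationParameters, terms=DEFAULT_TERMS
) -> float:
    """-2 log joint density of a subject's quantifiable observations and eta."""
    sd = _SubjectData(subject, terms)
    base_cl = sd.base_cl(math.log(params.cl_pop), _betas_from_params(params, terms))
    val = _engine._neg2ll_kernel(
        float(eta),
        sd.design.dt,
        sd.design.rate,
        base_cl,
        params.v_pop,
        sd.design.query_idx,
        sd.y,
        params.omega_cl**2,
        params.sigma_prop,
    )
    if not np.isfinite(val):
        raise FloatingPointError(
            "model prediction non-positive at a quantifiable observation"
        )
    return float(val)


def _ofv_cached(
    cache: list[_SubjectData],
    log_cl_pop: float,
    betas: np.ndarray,
    v: float,
    omega: float,
    sigma: float,
) -> float:
    total = 0.0
    for sd in cache:
        eta_hat, g_hat, g2 = _subject_inner(sd, log_cl_pop, betas, v, omega, sigma)
        if not np.isfinite(g_hat):
            return np.inf
        sd.eta_warm = eta_hat
        g2 = max(g2, 1e-10)
        total += g_hat + math.log(g2) - _LOG_4PI
    return total


def ofv(
    params: PopulationParameters, data: StudyDataset, terms=DEFAULT_TERMS
) -> float:
    """FOCE-I objective function value (-2 log-likelihood approximation)."""
    cache = _prepare(data, terms)
    return _ofv_cached(
        cache,
        math.log(params.cl_pop),
        _betas_from_params(params, terms),
        params.v_pop,
        params.omega_cl,
        params.sigma_prop,
    )


@dataclass
class FitResult:
    """Population fit output: estimates, precision, EBEs, convergence."""

    params: PopulationParameters
    terms: tuple[CovariateTerm, ...]
    betas: dict
    ofv: float
    rse: dict
    covariance: np.ndarray | None
    ebes: dict
    eta_shrinkage: float
    converged: bool
    n_function_evals: int
    boundary: bool = False
    message: str = ""

    def parameter_table(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        p = self.params
        rows = [
            ("CL_pop (L/h)", p.cl_pop, self.rse.get("cl_pop")),
            ("V_pop (L)", p.v_pop, self.rse.get("v_pop")),
        ]
        for t in self.terms:
            rows.append((f"beta_{t.name}", self.betas[t.name], self.rse.get(f"beta_{t.name}")))
        rows.append(("IIV CL (CV%)", p.iiv_cv_percent, self.rse.get("omega_cl")))
        rows.append(("RUV prop (CV%)", p.ruv_cv_percent, self.rse.get("sigma_prop")))
        df = pd.DataFrame(rows, columns=["parameter", "estimate", "rse_percent"])
        df.attrs["eta_shrinkage_percent"] = self.eta_shrinkage
        return df


_FIXED_NAMES = ("cl_pop", "v_pop", "omega_cl", "sigma_prop")


def _pack(params: PopulationParameters, betas: np.ndarray) -> np.ndarray:
    return np.concatenate(
        (
            [math.log(params.cl_pop), math.log(params.v_pop)],
            betas,
            [math.log(params.omega_cl), math.log(params.sigma_prop)],
        )
    )


def _names(terms) -> list[str]:
    return (
        ["cl_pop", "v_pop"]
        + [f"beta_{t.name}" for t in terms]
        + ["omega_cl", "sigma_prop"]
    )


def fit_population(
    data: StudyDataset,
    init: PopulationParameters | None = None,
    fixed: Iterable[str] = (),
    terms: Sequence[CovariateTerm] = DEFAULT_TERMS,
    compute_rse: bool = True,
    maxfev: int = 4000,
    xatol: float = 1e-4,
    fatol: float = 1e-5,
) -> FitResult:
    """Estimate population parameters by minimizing the FOCE-I objective.

    ``fixed`` names parameters held at their initial values (``cl_pop``,
    ``v_pop``, ``beta_<covariate>``, ``omega_cl``, ``sigma_prop``).
    CL_pop, V, omega and sigma are estimated on the log scale.  A Nelder–Mead
    search is used (the objective contains an inner optimization, so exact
    gradients are unavailable); convergence is declared on simplex size and
    relative-OFV tolerances.  Variance estimates at the transform floor are
    flagged as boundary solutions.
    """
    init = init or PopulationParameters()
    terms = tuple(terms)
    cache = _prepare(data, terms)
    names = _names(terms)
    fixed = set(fixed)
    unknown = fixed - set(names)
    if unknown:
        raise ValueError(f"unknown fixed parameter names: {sorted(unknown)}")
    x_full = _pack(init, _betas_from_params(init, terms))
    free_idx = np.array([i for i, n in enumerate(names) if n not in fixed], dtype=int)

    n_beta = len(terms)

    def unpack(x_free: np.ndarray):
        x = x_full.copy()
        x[free_idx] = x_free
        log_cl = x[0]
        v = math.exp(x[1])
        betas = x[2 : 2 + n_beta]
        omega = math.exp(x[2 + n_beta])
        sigma = math.exp(x[3 + n_beta])
        return log_cl, v, betas, omega, sigma

    n_evals = [0]

    def objective(x_free: np.ndarray) -> float:
        n_evals[0] += 1
        log_cl, v, betas, omega, sigma = unpack(x_free)
        if not (1e-8 < v < 1e6) or omega > 10 or sigma > 10:
            return np.inf
        return _ofv_cached(cache, log_cl, betas, v, omega, sigma)

    if free_idx.size == 0:
        final_ofv = objective(np.array([]))
        ebes, shrink = _ebes_and_shrinkage(cache, x_full, n_beta)
        return FitResult(
            params=_result_params(x_full, terms, init),
            terms=terms,
            betas=dict(zip([t.name for t in terms], x_full[2 : 2 + n_beta])),
            ofv=final_ofv,
            rse={},
            covariance=None,
            ebes=ebes,
            eta_shrinkage=shrink,
            converged=True,
            n_function_evals=n_evals[0],
            message="all parameters fixed",
        )

    res = optimize.minimize(
        objective,
        x_full[free_idx],
        method="Nelder-Mead",
        options={
            "maxfev": maxfev,
            "xatol": xatol,
            "fatol": fatol,
            "adaptive": True,
        },
    )
    x_full[free_idx] = res.x
    final_ofv = float(res.fun)

    boundary = bool(
        ("omega_cl" not in fixed and x_full[2 + n_beta] <= _VARIANCE_FLOOR)
        or ("sigma_prop" not in fixed and x_full[3 + n_beta] <= _VARIANCE_FLOOR)
    )

    rse: dict = {}
    covariance = None
    if compute_rse and res.success:
        covariance, rse = _rse_from_hessian(
            objective, x_full[free_idx].copy(), free_idx, names, x_full, n_beta
        )

    ebes, shrink = _ebes_and_shrinkage(cache, x_full, n_beta)
    params_out = _result_params(x_full, terms, init)
    result = FitResult(
        params=params_out,
        terms=terms,
        betas=dict(zip([t.name for t in terms], x_full[2 : 2 + n_beta])),
        ofv=final_ofv,
        rse=rse,
        covariance=covariance,
        ebes=ebes,
        eta_shrinkage=shrink,
        converged=bool(res.success) and np.isfinite(final_ofv),
        n_function_evals=n_evals[0],
        boundary=boundary,
        message=str(res.message),
    )
    logger.info(
        "fit: OFV=%.3f converged=%s nfev=%d CL=%.3f V=%.2f",
        final_ofv,
        result.converged,
        n_evals[0],
        params_out.cl_pop,
        params_out.v_pop,
    )
    return result


def _result_params(x_full, terms, init: PopulationParameters) -> PopulationParameters:
    n_beta = len(terms)
    base = replace(
        init,
        cl_pop=math.exp(x_full[0]),
        v_pop=math.exp(x_full[1]),
        omega_cl=math.exp(x_full[2 + n_beta]),
        sigma_prop=math.exp(x_full[3 + n_beta]),
    )
    return _params_with_betas(base, terms, x_full[2 : 2 + n_beta])


def _ebes_and_shrinkage(cache, x_full, n_beta):
    log_cl = x_full[0]
    v = math.exp(x_full[1])
    betas = x_full[2 : 2 + n_beta]
    omega = math.exp(x_full[2 + n_beta])
    sigma = math.exp(x_full[3 + n_beta])
    ebes = {}
    for sd in cache:
        eta_hat, _, _ = _subject_inner(sd, log_cl, betas, v, omega, sigma)
        ebes[sd.subject.id] = float(eta_hat)
    shrink = eta_shrinkage(np.array(list(ebes.values())), omega)
    return ebes, shrink


def _rse_from_hessian(objective, x_free, free_idx, names, x_full, n_beta):
    """Covariance = 2 * inverse Hessian of the OFV (central differences on the
    transformed scale); RSEs by the delta method for log-scale parameters."""
    n = x_free.size
    h = 1e-3
    hess = np.empty((n, n))
    f0 = objective(x_free)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x_free.copy(); xp[i] += h
                xm = x_free.copy(); xm[i] -= h
                hess[i, i] = (objective(xp) - 2 * f0 + objective(xm)) / h**2
            else:
                xpp = x_free.copy(); xpp[i] += h; xpp[j] += h
                xpm = x_free.copy(); xpm[i] += h; xpm[j] -= h
                xmp = x_free.copy(); xmp[i] -= h; xmp[j] += h
                xmm = x_free.copy(); xmm[i] -= h; xmm[j] -= h
                hess[i, j] = hess[j, i] = (
                    objective(xpp) - objective(xpm) - objective(xmp) + objective(xmm)
                ) / (4 * h**2)
    try:
        cov = 2.0 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None, {}
    if np.any(np.diag(cov) < 0):
        logger.warning("non-positive-definite Hessian; RSEs unavailable")
        return cov, {}
    se_x = np.sqrt(np.diag(cov))
    rse = {}
    log_scale = {"cl_pop", "v_pop", "omega_cl", "sigma_prop"}
    for k, idx in enumerate(free_idx):
        name = names[idx]
        if name in log_scale:
            # natural-scale SE = value * SE(log value); RSE = 100 * SE(log)
            rse[name] = 100.0 * se_x[k]
        else:
            val = x_full[idx]
            rse[name] = 100.0 * se_x[k] / abs(val) if val != 0 else np.inf
    return cov, rse


def empirical_bayes(
    subject: Subject,
    params: PopulationParameters,
    terms=DEFAULT_TERMS,
):
    """MAP estimate of a subject's eta given population parameters.

    Returns ``(eta_hat, se_eta, flagged)``: the conditional mode, the
    curvature-based approximate posterior SD (sqrt(2/g'')), and a flag that is
    true when the subject has no quantifiable observations (prior mode
    returned, SE = omega).
    """
    if not subject.analysis_observations:
        return 0.0, params.omega_cl, True
    sd = _SubjectData(subject, terms)
    eta_hat, _, g2 = _subject_inner(
        sd,
        math.log(params.cl_pop),
        _betas_from_params(params, terms),
        params.v_pop,
        params.omega_cl,
        params.sigma_prop,
    )
    se = math.sqrt(2.0 / max(g2, 1e-10))
    return float(eta_hat), float(se), False


def eta_shrinkage(ebes: np.ndarray, omega_cl: float) -> float:
    """Eta-shrinkage in percent: 100 * (1 - SD(eta_hat)/omega)."""
    ebes = np.asarray(ebes, dtype=float)
    if ebes.size < 2:
        raise ValueError("need at least two subjects for shrinkage")
    if not (omega_cl > 0):
        raise ValueError("omega must be positive")
    return 100.0 * (1.0 - ebes.std(ddof=1) / omega_cl)


@dataclass
class CovariateSearchTrace:
    """Record of forward/backward stepwise covariate selection on CL."""

    steps: list = field(default_factory=list)  # (phase, name, delta_ofv, decision)
    selected: tuple = ()
    final_fit: FitResult | None = None

    def append(self, phase: str, name: str, delta_ofv: float, decision: str) -> None:
        self.steps.append((phase, name, float(delta_ofv), decision))


def covariate_search(
    data: StudyDataset,
    candidates: Sequence[CovariateTerm],
    base_terms: Sequence[CovariateTerm] = (),
    init: PopulationParameters | None = None,
    forward_threshold: float = 3.84,
    backward_threshold: float = 6.63,
    maxfev: int = 2000,
) -> CovariateSearchTrace:
    """Greedy forward-inclusion / backward-elimination of power terms on CL.

    Forward: repeatedly add the candidate with the largest OFV drop while it
    exceeds ``forward_threshold`` (chi-square(1) at p<0.05 by default).
    Backward: remove terms whose deletion raises OFV by less than
    ``backward_threshold`` (p<0.01).  Ties broken by larger OFV drop, then by
    candidate list order.  Base-model terms are never removed.
    """
    init = init or PopulationParameters()
    base_terms = tuple(base_terms)
    trace = CovariateSearchTrace()

    def fit_terms(terms):
        return fit_population(
            data, init=init, terms=terms, compute_rse=False, maxfev=maxfev
        )

    current = base_terms
    current_fit = fit_terms(current)
    remaining = [c for c in candidates if c.name not in {t.name for t in current}]

    while remaining:
        results = []
        for cand in remaining:
            f = fit_terms(current + (cand,))
            delta = current_fit.ofv - f.ofv
            results.append((delta, cand, f))
        results.sort(key=lambda r: -r[0])
        best_delta, best_cand, best_fit = results[0]
        for delta, cand, _ in results:
            decided = "included" if (cand is best_cand and delta > forward_threshold) else "excluded"
            trace.append("forward", cand.name, delta, decided)
        if best_delta > forward_threshold:
            current = current + (best_cand,)
            current_fit = best_fit
            remaining = [c for c in remaining if c is not best_cand]
        else:
            break

    # backward elimination over forward-added terms
    removable = [t for t in current if t.name not in {b.name for b in base_terms}]
    changed = True
    while changed and removable:
        changed = False
        results = []
        for term in removable:
            reduced = tuple(t for t in current if t is not term)
            f = fit_terms(reduced)
            rise = f.ofv - current_fit.ofv
            results.append((rise, term, f))
        results.sort(key=lambda r: r[0])
        worst_rise, worst_term, worst_fit = results[0]
        if worst_rise < backward_threshold:
            trace.append("backward", worst_term.name, worst_rise, "removed")
            current = tuple(t for t in current if t is not worst_term)
            current_fit = worst_fit
            removable = [t for t in removable if t is not worst_term]
            changed = True
        else:
            for rise, term, _ in results:
                trace.append("backward", term.name, rise, "retained")

    trace.selected = tuple(t.name for t in current)
    trace.final_fit = current_fit
    return trace
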