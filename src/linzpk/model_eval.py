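"""Model qualification: CWRES/GOF tables, non-parametric bootstrap, visual
predictive check, and MPE/MAPE validation metrics.

CWRES follow the first-order-conditional construction: residuals about the
population prediction are decorrelated by the model-implied covariance of
the observation vector from a first-order expansion about each subject's
conditional mode (gradient of the prediction with respect to eta times
omega^2, plus the proportional-error diagonal evaluated at the conditional
prediction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from . import _engine
from .dataset_io import StudyDataset, Subject, analysis_subset
from .nlme_fit import (
    CovariateTerm,
    DEFAULT_TERMS,
    FitResult,
    _SubjectData,
    _betas_from_params,
    empirical_bayes,
    fit_population,
)
from .structural_pk import PopulationParameters

__all__ = [
    "ResidualTable",
    "BootstrapSummary",
    "VPCResult",
    "cwres",
    "bootstrap_ci",
    "vpc",
    "mpe_mape",
    "split_development_validation",
]

logger = logging.getLogger(__name__)


def _predict(sd: _SubjectData, params: PopulationParameters, eta: float, terms) -> np.ndarray:
    base_cl = sd.base_cl(math.log(params.cl_pop), _betas_from_params(params, terms))
    conc = _engine._propagate_kernel(
        sd.design.dt, sd.design.rate, base_cl * math.exp(eta), params.v_pop
    )
    return conc[sd.design.query_idx]


@dataclass
class ResidualTable:
    """Per-observation diagnostics: population/individual predictions and
    conditional weighted residuals."""

    frame: pd.DataFrame
    n_fallback_subjects: int = 0

    @property
    def cwres(self) -> np.ndarray:
        return self.frame["cwres"].to_numpy()


def cwres(
    data: StudyDataset,
    fit: FitResult,
) -> ResidualTable:
    """Conditional weighted residuals for every quantifiable observation.

    For subject i with conditional mode eta_hat: let f(eta) be the prediction
    vector, F = df/deta at eta_hat (finite difference), and
    Sigma = diag((sigma * f(eta_hat))^2).  Then

        E[y] ~= f(eta_hat) - F eta_hat          (first-order mean)
        Cov[y] ~= F omega^2 F' + Sigma

    and CWRES = Cov^{-1/2} (y - E[y]).  Singular covariance falls back to
    unweighted residuals for that subject, with a flag.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; residuals undefined")
    params = fit.params
    terms = fit.terms
    rows = []
    n_fallback = 0
    for s in data.subjects:
        obs = s.analysis_observations
        if not obs:
            continue
        sd = _SubjectData(s, terms)
        y = sd.y
        eta_hat = fit.ebes.get(s.id)
        if eta_hat is None:
            eta_hat, _, _ = empirical_bayes(s, params, terms)
        f_hat = _predict(sd, params, eta_hat, terms)
        f_pop = _predict(sd, params, 0.0, terms)
        h = 1e-5
        grad = (_predict(sd, params, eta_hat + h, terms) - _predict(sd, params, eta_hat - h, terms)) / (2 * h)
        cov = (
            np.outer(grad, grad) * params.omega_cl**2
            + np.diag((params.sigma_prop * f_hat) ** 2)
        )
        mean = f_hat - grad * eta_hat
        resid = y - mean
        try:
            l = linalg.cholesky(cov, lower=True)
            w = linalg.solve_triangular(l, resid, lower=True)
        except linalg.LinAlgError:
            n_fallback += 1
            w = resid
        times = np.sort(np.array([o.time for o in obs], dtype=float))
        tsld = []
        for t in times:
            last = s.last_dose_time_before(t)
            tsld.append(t - last if last is not None else np.nan)
        for j in range(y.size):
            rows.append(
                {
                    "id": s.id,
                    "time": times[j],
                    "time_since_last_dose": tsld[j],
                    "observed": y[j],
                    "pred_population": f_pop[j],
                    "pred_individual": f_hat[j],
                    "cwres": w[j],
                }
            )
    return ResidualTable(frame=pd.DataFrame(rows), n_fallback_subjects=n_fallback)


@dataclass
class BootstrapSummary:
    """Bootstrap medians and percentile CIs per parameter."""

    table: pd.DataFrame  # index parameter, columns median/ci_low/ci_high
    n_success: int
    n_excluded: int
    warning: str = ""

    def ci(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])


_PARAM_COLS = ("cl_pop", "v_pop", "beta_egfr", "beta_day", "beta_age",
               "iiv_cv_percent", "ruv_cv_percent")


def _param_row(params: PopulationParameters) -> dict:
    return {
        "cl_pop": params.cl_pop,
        "v_pop": params.v_pop,
        "beta_egfr": params.beta_egfr,
        "beta_day": params.beta_day,
        "beta_age": params.beta_age,
        "iiv_cv_percent": params.iiv_cv_percent,
        "ruv_cv_percent": params.ruv_cv_percent,
    }


def bootstrap_ci(
    data: StudyDataset,
    init: PopulationParameters | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    terms=DEFAULT_TERMS,
    resample: bool = True,
    maxfev: int = 3000,
) -> BootstrapSummary:
    """Non-parametric bootstrap: resample subjects with replacement to the
    original cohort size, refit each replicate, and summarize medians and
    2.5–97.5 percentile CIs.  Replicates that fail to converge or end on a
    variance boundary are excluded (their count is reported); an exclusion
    fraction above 20 % raises a warning in the summary."""
    init = init or PopulationParameters()
    rng = np.random.default_rng(seed)
    n = len(data.subjects)
    rows = []
    n_excluded = 0
    for rep in range(n_reps):
        if resample:
            idx = rng.integers(0, n, size=n)
            subjects = []
            for j, i in enumerate(idx):
                s = data.subjects[i]
                # re-id duplicates so the dataset invariant holds
                subjects.append(
                    Subject(
                        id=f"{s.id}~{j}",
                        doses=s.doses,
                        observations=s.observations,
                        covariates=s.covariates,
                    )
                )
            rep_data = StudyDataset(subjects=tuple(subjects))
        else:
            rep_data = data
        rep_data = analysis_subset(rep_data)
        try:
            fit = fit_population(
                rep_data, init=init, terms=terms, compute_rse=False, maxfev=maxfev
            )
        except (ValueError, FloatingPointError):
            n_excluded += 1
            continue
        if not fit.converged or fit.boundary:
            n_excluded += 1
            continue
        rows.append(_param_row(fit.params))
    n_success = len(rows)
    if n_success == 0:
        raise RuntimeError("no successful bootstrap replicates")
    df = pd.DataFrame(rows)
    table = pd.DataFrame(
        {
            "median": df.median(),
            "ci_low": df.quantile(0.025),
            "ci_high": df.quantile(0.975),
        }
    )
    warning = ""
    if n_excluded > 0.2 * n_reps:
        warning = f"{n_excluded}/{n_reps} replicates excluded (>20%)"
        logger.warning(warning)
    return BootstrapSummary(
        table=table, n_success=n_success, n_excluded=n_excluded, warning=warning
    )


@dataclass
class VPCResult:
    """Visual-predictive-check bands binned on time since last dose."""

    table: pd.DataFrame  # one row per bin x percentile with obs and sim CI
    n_sim: int

    def bin_frame(self) -> pd.DataFrame:
        return self.table


def vpc(
    data: StudyDataset,
    fit: FitResult,
    n_sim: int = 1000,
    n_bins: int = 8,
    seed: int = 0,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
) -> VPCResult:
    """Visual predictive check on the time-since-last-dose axis.

    Each simulated dataset re-uses every subject's own design (doses, sampling
    times, covariates) with a fresh eta and proportional noise.  Bins are
    quantile-based; bins with fewer than 5 observations are merged with their
    neighbor.  For each bin the observed 5/50/95th percentiles are reported
    with the 2.5–97.5 percentile envelope of the same statistic across the
    ``n_sim`` replicates."""
    params = fit.params
    terms = fit.terms
    rng = np.random.default_rng(seed)

    tsld_all = []
    y_all = []
    subject_data = []
    for s in data.subjects:
        obs = s.analysis_observations
        if not obs:
            continue
        sd = _SubjectData(s, terms)
        times = np.sort(np.array([o.time for o in obs], dtype=float))
        tsld = np.array(
            [t - (s.last_dose_time_before(t) or 0.0) for t in times], dtype=float
        )
        subject_data.append(sd)
        tsld_all.append(tsld)
        y_all.append(sd.y)
    tsld_all = np.concatenate(tsld_all)
    y_all = np.concatenate(y_all)

    # quantile bin edges, then merge sparse bins
    edges = np.unique(np.quantile(tsld_all, np.linspace(0, 1, n_bins + 1)))
    bin_idx = np.clip(np.searchsorted(edges, tsld_all, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(bin_idx, minlength=len(edges) - 1)
    while len(edges) > 2 and counts.min() < 5:
        k = int(np.argmin(counts))
        drop = k + 1 if k < len(counts) - 1 else k
        edges = np.delete(edges, drop)
        bin_idx = np.clip(np.searchsorted(edges, tsld_all, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(bin_idx, minlength=len(edges) - 1)
        logger.debug("VPC: merged sparse bin; %d bins remain", len(edges) - 1)
    n_b = len(edges) - 1

    def stats(values: np.ndarray) -> np.ndarray:
        out = np.empty((n_b, len(percentiles)))
        for b in range(n_b):
            v = values[bin_idx == b]
            out[b] = np.percentile(v, percentiles) if v.size else np.nan
        return out

    obs_stats = stats(y_all)
    sim_stats = np.empty((n_sim, n_b, len(percentiles)))
    base_cls = [
        sd.base_cl(math.log(params.cl_pop), _betas_from_params(params, terms))
        for sd in subject_data
    ]
    for r in range(n_sim):
        sim_y = []
        for sd, base_cl in zip(subject_data, base_cls):
            eta = rng.normal(0.0, params.omega_cl)
            conc = _engine._propagate_kernel(
                sd.design.dt, sd.design.rate, base_cl * math.exp(eta), params.v_pop
            )[sd.design.query_idx]
            noise = 1.0 + params.sigma_prop * rng.standard_normal(conc.size)
            sim_y.append(conc * noise)
        sim_stats[r] = stats(np.concatenate(sim_y))

    rows = []
    for b in range(n_b):
        for k, pct in enumerate(percentiles):
            lo, hi = np.percentile(sim_stats[:, b, k], [2.5, 97.5])
            rows.append(
                {
                    "bin_low_h": edges[b],
                    "bin_high_h": edges[b + 1],
                    "n_obs": int(counts[b]),
                    "percentile": pct,
                    "observed": obs_stats[b, k],
                    "sim_median": float(np.median(sim_stats[:, b, k])),
                    "sim_ci_low": lo,
                    "sim_ci_high": hi,
                }
            )
    return VPCResult(table=pd.DataFrame(rows), n_sim=n_sim)


def mpe_mape(observed, predicted) -> tuple[float, float]:
    """Mean prediction error and mean absolute prediction error, in percent:

        MPE  = 100/n * sum (C_pred - C_obs) / C_obs
        MAPE = 100/n * sum |C_pred - C_obs| / C_obs

    Positive MPE means over-prediction.  MAPE >= |MPE| always.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size == 0:
        raise ValueError("empty input")
    if np.any(obs <= 0):
        raise ValueError("observed concentrations must be positive")
    rel = (pred - obs) / obs
    return float(100.0 * rel.mean()), float(100.0 * np.abs(rel).mean())


def split_development_validation(
    data: StudyDataset, seed: int = 0, ratio: float = 2.0 / 3.0
) -> tuple[StudyDataset, StudyDataset]:
    """Random subject-level split (approximately 2:1 by default)."""
    rng = np.random.default_rng(seed)
    n = len(data.subjects)
    idx = rng.permutation(n)
    n_dev = int(round(ratio * n))
    dev = tuple(data.subjects[i] for i in sorted(idx[:n_dev]))
    val = tuple(data.subjects[i] for i in sorted(idx[n_dev:]))
    prov = dict(data.provenance)
    return (
        StudyDataset(subjects=dev, provenance={**prov, "split": "development"}),
        StudyDataset(subjects=val, provenance={**prov, "split": "validation"}),
    )
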