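"""Event-stepped propagation engine for the one-compartment infusion model.

Clearance varies in time (renal function refreshed at covariate knots, the
treatment-day covariate advancing per calendar day), which breaks dose
superposition.  The engine therefore splits the timeline into segments on
which the infusion rate and clearance are constant, and carries compartment
state across segment boundaries with the analytic constant-coefficient
solution

    C(t0 + dt) = C(t0) * exp(-k dt) + (R/CL) * (1 - exp(-k dt)),   k = CL/V.

Segment boundaries: every dose start, every infusion end, every calendar-day
boundary, every eGFR knot, and every query time, so queries are evaluated
exactly at a breakpoint.  The per-segment integral is also available in
closed form for exact AUC computation.

The hot loops are numba kernels; the per-subject segment structure is built
once (it does not depend on parameter values) and reused across likelihood
evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .dataset_io import DoseEvent, Subject

__all__ = ["SubjectDesign", "build_design", "propagate", "propagate_auc", "propagate_many"]

_DAY_HOURS = 24.0


@njit(cache=True)
def _propagate_kernel(dt, rate, cl, v):
    """Concentration at every breakpoint (c[0] = 0 at the first breakpoint)."""
    n = dt.shape[0]
    c = np.empty(n + 1)
    c[0] = 0.0
    for m in range(n):
        k = cl[m] / v
        e = np.exp(-k * dt[m])
        c[m + 1] = c[m] * e + (rate[m] / cl[m]) * (1.0 - e)
    return c


@njit(cache=True)
def _propagate_auc_kernel(dt, rate, cl, v):
    """Breakpoint concentrations plus exact per-segment AUC contributions.

    Integral of C over a constant-CL segment:
        int C dt = (R/CL) dt + (C0 - C1) / k.
    """
    n = dt.shape[0]
    c = np.empty(n + 1)
    auc = np.empty(n)
    c[0] = 0.0
    for m in range(n):
        k = cl[m] / v
        e = np.exp(-k * dt[m])
        c1 = c[m] * e + (rate[m] / cl[m]) * (1.0 - e)
        auc[m] = (rate[m] / cl[m]) * dt[m] + (c[m] - c1) / k
        c[m + 1] = c1
    return c, auc


@njit(cache=True)
def _propagate_many_kernel(dt, rate, base_cl, v, eta, obs_idx):
    """Breakpoint concentrations at obs_idx for many individuals who share a
    design but differ by a clearance multiplier exp(eta_i)."""
    n_ind = eta.shape[0]
    n_seg = dt.shape[0]
    n_obs = obs_idx.shape[0]
    out = np.empty((n_ind, n_obs))
    for i in range(n_ind):
        mult = np.exp(eta[i])
        c = 0.0
        j = 0
        for m in range(n_seg):
            if j < n_obs and obs_idx[j] == m:
                out[i, j] = c
                j += 1
            clm = base_cl[m] * mult
            k = clm / v
            e = np.exp(-k * dt[m])
            c = c * e + (rate[m] / clm) * (1.0 - e)
        while j < n_obs:
            out[i, j] = c
            j += 1
    return out


@njit(cache=True)
def _propagate_many_auc_kernel(dt, rate, base_cl, v, eta):
    """Per-individual per-segment AUC contributions and breakpoint troughs."""
    n_ind = eta.shape[0]
    n_seg = dt.shape[0]
    conc = np.empty((n_ind, n_seg + 1))
    auc = np.empty((n_ind, n_seg))
    for i in range(n_ind):
        mult = np.exp(eta[i])
        c = 0.0
        conc[i, 0] = 0.0
        for m in range(n_seg):
            clm = base_cl[m] * mult
            k = clm / v
            e = np.exp(-k * dt[m])
            c1 = c * e + (rate[m] / clm) * (1.0 - e)
            auc[i, m] = (rate[m] / clm) * dt[m] + (c - c1) / k
            c = c1
            conc[i, m + 1] = c1
    return conc, auc


@njit(cache=True)
def _neg2ll_kernel(eta, dt, rate, base_cl, v, obs_idx, y, omega2, sigma):
    """-2 log joint density of (observations, eta) for one subject.

    Proportional residual error with interaction: sd_j = sigma * f_j(eta).
    Returns +inf if any predicted concentration at an observation is
    non-positive (the proportional-error likelihood is undefined there).
    """
    n_seg = dt.shape[0]
    n_obs = obs_idx.shape[0]
    mult = np.exp(eta)
    if not np.isfinite(mult) or mult <= 0.0:
        return np.inf
    if omega2 <= 0.0 or sigma <= 0.0 or v <= 0.0:
        return np.inf
    total = np.log(2.0 * np.pi * omega2) + eta * eta / omega2
    c = 0.0
    j = 0
    log2pi = np.log(2.0 * np.pi)
    for m in range(n_seg):
        while j < n_obs and obs_idx[j] == m:
            f = c
            if f <= 1e-150:  # proportional-error likelihood undefined
                return np.inf
            sd = sigma * f
            r = (y[j] - f) / sd
            total += log2pi + 2.0 * np.log(sd) + r * r
            j += 1
        clm = base_cl[m] * mult
        if clm < 1e-12 or not np.isfinite(clm):
            return np.inf
        k = clm / v
        e = np.exp(-k * dt[m])
        c = c * e + (rate[m] / clm) * (1.0 - e)
    while j < n_obs:
        f = c
        if f <= 0.0:
            return np.inf
        sd = sigma * f
        r = (y[j] - f) / sd
        total += log2pi + 2.0 * np.log(sd) + r * r
        j += 1
    return total


@njit(cache=True)
def _inner_minimize_kernel(dt, rate, base_cl, v, obs_idx, y, omega2, sigma, eta0):
    """Minimize the conditional objective over eta.

    Coarse scan over a wide interval (the Gaussian prior term makes the
    objective grow quadratically, so the mode is always interior) followed by
    golden-section refinement — unconditionally convergent for this 1-D
    problem.  Returns (eta_hat, g(eta_hat), g''(eta_hat) central difference).
    """
    lo = min(eta0, 0.0) - 6.0
    hi = max(eta0, 0.0) + 6.0
    n_scan = 25
    best_x = eta0
    best_g = _neg2ll_kernel(eta0, dt, rate, base_cl, v, obs_idx, y, omega2, sigma)
    scan_step = (hi - lo) / (n_scan - 1)
    for i in range(n_scan):
        x = lo + scan_step * i
        g = _neg2ll_kernel(x, dt, rate, base_cl, v, obs_idx, y, omega2, sigma)
        if g < best_g:
            best_g = g
            best_x = x
    a = best_x - scan_step
    b = best_x + scan_step
    # golden-section on [a, b]
    invphi = 0.6180339887498949
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    g1 = _neg2ll_kernel(x1, dt, rate, base_cl, v, obs_idx, y, omega2, sigma)
    g2 = _neg2ll_kernel(x2, dt, rate, base_cl, v, obs_idx, y, omega2, sigma)
    for _ in range(80):
        if b - a < 1e-10:
            break
        if g1 < g2:
            b = x2
            x2, g2 = x1, g1
            x1 = b - invphi * (b - a)
            g1 = _neg2ll_kernel(x1, dt, rate, base_cl, v, obs_idx, y, omega2, sigma)
        else:
            a = x1
            x1, g1 = x2, g2
            x2 = a + invphi * (b - a)
            g2 = _neg2ll_kernel(x2, dt, rate, base_cl, v, obs_idx, y, omega2, sigma)
    eta_hat = 0.5 * (a + b)
    g_hat = _neg2ll_kernel(eta_hat, dt, rate, base_cl, v, obs_idx, y, omega2, sigma)
    h = 1e-4
    gp = _neg2ll_kernel(eta_hat + h, dt, rate, base_cl, v, obs_idx, y, omega2, sigma)
    gm = _neg2ll_kernel(eta_hat - h, dt, rate, base_cl, v, obs_idx, y, omega2, sigma)
    g2nd = (gp - 2.0 * g_hat + gm) / (h * h)
    return eta_hat, g_hat, g2nd


@dataclass
class SubjectDesign:
    """Parameter-independent segment structure for one subject.

    Attributes
    ----------
    times : breakpoints (h), length n_seg + 1
    dt, rate : per-segment duration (h) and total infusion rate (mg/h)
    egfr, day : per-segment covariate values in force
    age : constant covariate
    query_idx : breakpoint index of each query time (concentration at a
        breakpoint is the value *entering* it, i.e. just before any dose
        starting there — exactly the trough convention)
    """

    times: np.ndarray
    dt: np.ndarray
    rate: np.ndarray
    egfr: np.ndarray
    day: np.ndarray
    age: float
    query_idx: np.ndarray
    extras: dict

    @property
    def n_segments(self) -> int:
        return self.dt.shape[0]

    def covariate_values(self, name: str) -> np.ndarray:
        """Per-segment values for a named covariate (for power terms on CL)."""
        if name == "egfr":
            return self.egfr
        if name == "day":
            return self.day
        if name == "age":
            return np.full(self.n_segments, self.age)
        if name in self.extras:
            return np.full(self.n_segments, float(self.extras[name]))
        raise KeyError(f"unknown covariate {name!r}")


def build_design(
    doses,
    query_times,
    age: float,
    egfr_series,
    extras: dict | None = None,
    horizon: float | None = None,
) -> SubjectDesign:
    """Build the segment structure for a dose schedule and query times.

    ``egfr_series`` is a sequence of (time, value) knots (piecewise constant).
    Query times before the first breakpoint (time 0) are rejected.
    """
    query_times = np.asarray(query_times, dtype=float)
    if query_times.size and query_times.min() < -1e-12:
        raise ValueError("query time before time 0")

    points = {0.0}
    t_end = 0.0
    for d in doses:
        points.add(d.time)
        points.add(d.time + d.infusion_duration)
        t_end = max(t_end, d.time + d.infusion_duration)
    for t in query_times:
        points.add(float(t))
        t_end = max(t_end, float(t))
    if horizon is not None:
        t_end = max(t_end, horizon)
        points.add(float(horizon))
    for kt, _ in egfr_series:
        if 0.0 <= kt <= t_end:
            points.add(float(kt))
    n_days = int(np.floor(t_end / _DAY_HOURS)) + 1
    for dday in range(1, n_days + 1):
        bt = dday * _DAY_HOURS
        if bt < t_end:
            points.add(bt)

    times = np.array(sorted(points), dtype=float)
    # drop near-duplicate breakpoints
    keep = np.concatenate(([True], np.diff(times) > 1e-12))
    times = times[keep]
    dt = np.diff(times)
    n_seg = dt.shape[0]

    rate = np.zeros(n_seg)
    for d in doses:
        t0, t1 = d.time, d.time + d.infusion_duration
        mid = 0.5 * (times[:-1] + times[1:])
        rate += np.where((mid > t0) & (mid < t1), d.rate, 0.0)

    mid = 0.5 * (times[:-1] + times[1:])
    day = np.floor(mid / _DAY_HOURS) + 1.0

    knot_t = np.array([kt for kt, _ in egfr_series], dtype=float)
    knot_v = np.array([kv for _, kv in egfr_series], dtype=float)
    idx = np.clip(np.searchsorted(knot_t, mid, side="right") - 1, 0, knot_t.size - 1)
    egfr = knot_v[idx]

    query_idx = np.searchsorted(times, query_times - 1e-12, side="left").astype(np.int64)
    query_idx = np.clip(query_idx, 0, n_seg)

    return SubjectDesign(
        times=times,
        dt=dt,
        rate=rate,
        egfr=egfr,
        day=day,
        age=float(age),
        query_idx=query_idx,
        extras=dict(extras or {}),
    )


def design_for_subject(
    subject: Subject, query_times, horizon: float | None = None
) -> SubjectDesign:
    cov = subject.covariates
    return build_design(
        subject.doses,
        query_times,
        age=cov.age,
        egfr_series=cov.egfr,
        extras=dict(cov.extras),
        horizon=horizon,
    )


def propagate(design: SubjectDesign, cl_seg: np.ndarray, v: float) -> np.ndarray:
    """Concentration at every breakpoint for a per-segment clearance vector."""
    return _propagate_kernel(design.dt, design.rate, np.asarray(cl_seg, float), float(v))


def propagate_auc(design: SubjectDesign, cl_seg: np.ndarray, v: float):
    """Breakpoint concentrations plus exact per-segment AUC contributions."""
    return _propagate_auc_kernel(design.dt, design.rate, np.asarray(cl_seg, float), float(v))


def propagate_many(design: SubjectDesign, base_cl: np.ndarray, v: float, eta: np.ndarray):
    """Query-time concentrations for many individuals sharing one design."""
    return _propagate_many_kernel(
        design.dt,
        design.rate,
        np.asarray(base_cl, float),
        float(v),
        np.asarray(eta, float),
        design.query_idx,
    )
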