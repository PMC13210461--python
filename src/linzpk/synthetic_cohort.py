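"""Synthetic TDM cohorts with the statistical structure of the study
population: elderly inpatients (65–87 y) on 600 mg IV linezolid q12h as a
1-h infusion, trough-oriented sampling driven by a TDM protocol (first
sample immediately before the 3rd–5th dose, repeats every 3–4 days), and
covariates drawn to match the published cohort summaries (median age 78,
median absolute eGFR ~49 mL/min with IQR ~26–75, median weight 70 kg,
treatment duration median 7 days, range 3–26).

Concentrations are generated from the structural model with a log-normal
clearance random effect and proportional residual error; a ground-truth
sidecar (per-subject eta and noise-free concentrations) is returned for
parameter-recovery and calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine
from .dataset_io import (
    EGFR_CAP,
    LLOQ,
    ConcentrationRecord,
    CovariateSeries,
    DoseEvent,
    StudyDataset,
    Subject,
    cap_egfr,
)
from .structural_pk import PopulationParameters, RegimenSpec, clearance_segments

__all__ = [
    "SyntheticCohortConfig",
    "sample_covariates",
    "generate_cohort",
    "apply_lloq_censoring",
]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Distributions and protocol rules for cohort generation.

    Covariate distribution families are truncated normal (age) and log-normal
    (eGFR, weight, duration), parameterized to reproduce the published
    medians, IQRs and ranges; age and log-eGFR share a Gaussian copula with a
    weak negative correlation matching the reported Spearman rho of about
    -0.2.  All values are truncated to the printed ranges.
    """

    n_subjects: int = 103
    seed: int = 0

    # age: truncated normal, median 78, range 65-87
    age_mean: float = 78.0
    age_sd: float = 6.5
    age_range: tuple[float, float] = (65.0, 87.0)

    # absolute eGFR: log-normal, median 48.8, IQR 25.9-75.4, capped at 130
    egfr_log_median: float = math.log(48.8)
    egfr_log_sd: float = 0.79
    egfr_range: tuple[float, float] = (8.0, 130.0)
    age_egfr_corr: float = -0.21  # Gaussian-copula correlation

    # weight: log-normal, median 70, IQR 60-80
    weight_log_median: float = math.log(70.0)
    weight_log_sd: float = 0.213
    weight_range: tuple[float, float] = (40.0, 140.0)

    # height (cm): normal by sex; male fraction 0.65
    male_fraction: float = 0.65
    height_mean_male: float = 168.0
    height_mean_female: float = 156.0
    height_sd: float = 7.0

    # treatment duration (days): log-normal median 7, range 3-26
    duration_log_median: float = math.log(7.0)
    duration_log_sd: float = 0.45
    duration_range: tuple[float, float] = (3.0, 26.0)

    # sampling protocol
    first_sample_dose: tuple[int, int] = (3, 5)  # before the 3rd-5th dose
    resample_gap_days: tuple[float, float] = (3.0, 4.0)
    max_samples: int = 6
    predose_window_h: tuple[float, float] = (0.1, 2.0)
    #: fraction of samples drawn mid-interval (delayed draws seen in practice)
    mid_interval_fraction: float = 0.10

    regimen: RegimenSpec = field(default_factory=RegimenSpec)
    #: when true, halve the dose after a trough above the toxicity cutoff
    adaptive_tdm: bool = False
    toxicity_cutoff: float = 8.0

    params: PopulationParameters = field(default_factory=PopulationParameters)
    lloq: float = LLOQ


def _truncated(draw, lo, hi, rng, max_tries=1000):
    """Redraw until inside [lo, hi]."""
    for _ in range(max_tries):
        x = draw(rng)
        if lo <= x <= hi:
            return x
    return min(max(x, lo), hi)


def sample_covariates(
    config: SyntheticCohortConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-subject covariate draws: age, absolute eGFR (capped), weight,
    height, sex, treatment duration.  Summary statistics of a large draw
    approximate the published cohort medians and IQRs."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    rows = []
    rho = config.age_egfr_corr
    for i in range(n):
        # correlated standard-normal pair for (age, log eGFR)
        for _ in range(1000):
            z1 = rng.standard_normal()
            z2 = rho * z1 + math.sqrt(1 - rho * rho) * rng.standard_normal()
            age = config.age_mean + config.age_sd * z1
            egfr = math.exp(config.egfr_log_median + config.egfr_log_sd * z2)
            if (
                config.age_range[0] <= age <= config.age_range[1]
                and egfr >= config.egfr_range[0]
            ):
                break
        egfr = cap_egfr(min(egfr, config.egfr_range[1]))
        male = rng.random() < config.male_fraction
        weight = _truncated(
            lambda r: math.exp(
                config.weight_log_median + config.weight_log_sd * r.standard_normal()
            ),
            *config.weight_range,
            rng,
        )
        h_mean = config.height_mean_male if male else config.height_mean_female
        height = h_mean + config.height_sd * rng.standard_normal()
        duration = _truncated(
            lambda r: math.exp(
                config.duration_log_median
                + config.duration_log_sd * r.standard_normal()
            ),
            *config.duration_range,
            rng,
        )
        rows.append(
            {
                "id": f"S{i + 1:03d}",
                "age": round(age, 1),
                "egfr": egfr,
                "weight": weight,
                "height": height,
                "sex": "male" if male else "female",
                "duration_days": duration,
            }
        )
    return pd.DataFrame(rows)


def _sample_times(config: SyntheticCohortConfig, duration_days: float, rng) -> list[float]:
    """TDM sampling times (h): first trough immediately before the 3rd-5th
    dose, then repeats every 3-4 days while treatment continues."""
    tau = config.regimen.interval
    t_end = duration_days * 24.0
    first_dose_idx = rng.integers(config.first_sample_dose[0], config.first_sample_dose[1] + 1)
    times: list[float] = []
    t_target = (first_dose_idx - 1) * tau  # time of the dose sampled before
    while len(times) < config.max_samples and t_target <= t_end + 1e-9:
        if rng.random() < config.mid_interval_fraction:
            # delayed draw: mid-interval after the previous dose
            offset = rng.uniform(2.0, tau - 1.0)
            t = t_target - tau + offset
        else:
            t = t_target - rng.uniform(*config.predose_window_h)
        if t > 0.5:
            times.append(float(t))
        gap_h = rng.uniform(*config.resample_gap_days) * 24.0
        # next sample again immediately before a scheduled dose
        t_target = math.ceil((t_target + gap_h) / tau) * tau
    return times


def generate_cohort(
    config: SyntheticCohortConfig, seed: int | None = None
) -> tuple[StudyDataset, pd.DataFrame]:
    """Generate a cohort and its ground-truth sidecar.

    Returns ``(dataset, truth)`` where ``truth`` has one row per observation
    with the subject's eta and the noise-free model concentration, plus the
    per-subject eta in its own rows-invariant columns.  BLQ records (value
    below the LLOQ) are flagged in the dataset and excluded from its analysis
    view; a subject may occasionally end up with only BLQ records, so callers
    that fit the data should first apply ``analysis_subset``.
    """
    master = np.random.default_rng(config.seed if seed is None else seed)
    cov_seed, noise_seed = master.integers(0, 2**31 - 1, size=2)
    covs = sample_covariates(config, seed=int(cov_seed))
    rng = np.random.default_rng(int(noise_seed))
    p = config.params

    subjects: list[Subject] = []
    truth_rows: list[dict] = []
    for _, row in covs.iterrows():
        eta = rng.normal(0.0, p.omega_cl)
        duration = float(row["duration_days"])
        n_doses = int(math.ceil(duration * 24.0 / config.regimen.interval))
        base_regimen = replace(config.regimen, n_doses=max(n_doses, 1))

        obs_times = _sample_times(config, duration, rng)
        if not obs_times:
            obs_times = [max((config.first_sample_dose[0] - 1) * config.regimen.interval - 0.5, 1.0)]
        obs_times = sorted(obs_times)

        doses = list(base_regimen.doses())
        if config.adaptive_tdm:
            doses = _adaptive_doses(base_regimen, obs_times, row, eta, p, config)

        design = _engine.build_design(
            doses, np.asarray(obs_times), age=float(row["age"]),
            egfr_series=((0.0, float(row["egfr"])),),
        )
        cl_seg = clearance_segments(design, p, eta)
        f = _engine.propagate(design, cl_seg, p.v_pop)[design.query_idx]

        records = []
        for t, fj in zip(obs_times, f):
            for _ in range(100):
                y = fj * (1.0 + p.sigma_prop * rng.standard_normal())
                if y > 0:
                    break
            blq = y < config.lloq
            last = max((d.time for d in doses if d.time <= t), default=None)
            records.append(
                ConcentrationRecord(
                    time=float(t),
                    value=float(y),
                    blq=bool(blq),
                    time_since_last_dose=float(t - last) if last is not None else None,
                )
            )
            truth_rows.append(
                {
                    "id": row["id"],
                    "time": float(t),
                    "true_conc": float(fj),
                    "observed": float(y),
                    "blq": bool(blq),
                    "eta": float(eta),
                }
            )
        subjects.append(
            Subject(
                id=row["id"],
                doses=tuple(doses),
                observations=tuple(records),
                covariates=CovariateSeries(
                    age=float(row["age"]),
                    egfr=((0.0, float(row["egfr"])),),
                    extras={
                        "weight": float(row["weight"]),
                        "height": float(row["height"]),
                    },
                ),
            )
        )

    dataset = StudyDataset(
        subjects=tuple(subjects),
        provenance={
            "source": "synthetic cohort generator",
            "seed": str(config.seed if seed is None else seed),
            "n_subjects": str(config.n_subjects),
        },
    )
    return dataset, pd.DataFrame(truth_rows)


def _adaptive_doses(regimen, obs_times, row, eta, params, config):
    """Protocol-faithful adaptive mode: halve the dose from the next dose on
    whenever a simulated trough exceeds the toxicity cutoff."""
    doses = []
    amount = regimen.dose
    checked = set()
    for i in range(regimen.n_doses):
        t = i * regimen.interval
        doses.append(DoseEvent(time=t, amount=amount, infusion_duration=regimen.infusion_duration))
        for ot in obs_times:
            if ot in checked or not (t <= ot < t + regimen.interval):
                continue
            checked.add(ot)
            design = _engine.build_design(
                doses, np.array([ot]), age=float(row["age"]),
                egfr_series=((0.0, float(row["egfr"])),),
            )
            cl_seg = clearance_segments(design, params, eta)
            trough = _engine.propagate(design, cl_seg, params.v_pop)[design.query_idx][0]
            if trough > config.toxicity_cutoff:
                amount = max(amount / 2.0, 150.0)
    return doses


def apply_lloq_censoring(
    dataset: StudyDataset, lloq: float = LLOQ
) -> tuple[StudyDataset, int]:
    """Flag records strictly below ``lloq`` as BLQ (ties at the limit are
    retained as quantifiable).  Returns the reflagged dataset and the count
    of BLQ records.  BLQ records stay in ``observations`` but are excluded
    from ``analysis_observations``."""
    new_subjects = []
    n_flagged = 0
    for s in dataset.subjects:
        recs = []
        for o in s.observations:
            blq = o.value < lloq
            n_flagged += int(blq)
            recs.append(
                ConcentrationRecord(
                    time=o.time,
                    value=o.value,
                    blq=blq,
                    time_since_last_dose=o.time_since_last_dose,
                )
            )
        new_subjects.append(
            Subject(id=s.id, doses=s.doses, observations=tuple(recs), covariates=s.covariates)
        )
    return (
        StudyDataset(subjects=tuple(new_subjects), provenance=dict(dataset.provenance)),
        n_flagged,
    )
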