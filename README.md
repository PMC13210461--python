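# linzpk

Population pharmacokinetics of intravenous linezolid in elderly inpatients:
a covariate-driven one-compartment model, a FOCE-I nonlinear mixed-effects
estimator, model-qualification diagnostics, Monte Carlo overexposure and
target-attainment simulation, and Bayesian dose individualization from
therapeutic drug monitoring (TDM) troughs — all exercisable on a synthetic
TDM cohort, with no external data.

## The problem

Linezolid is dosed flat (600 mg IV q12h) regardless of renal function, yet
elderly inpatients show wide exposure variability and accumulate the drug as
treatment progresses, risking thrombocytopenia at troughs above 8 mg/L. The
model implemented here describes the concentration–time course of a 1-h IV
infusion with a one-compartment model whose clearance depends on renal
function, time on treatment and age:

```
CL_i(t) = 4.25 L/h · (eGFR_i / 59.6)^0.29 · (DAY(t) / 3.5)^−0.18 · (AGE_i / 78)^−1.16 · exp(η_i)
V       = 25.6 L
η_i ~ N(0, ω²),  ω = 0.332            (IIV on CL, ≈33.2 %CV)
y_ij = f_ij · (1 + σ ε_ij),  σ = 0.265  (proportional residual, ≈26.5 %CV)
```

eGFR is the absolute (BSA-corrected) CKD-EPI estimate in mL/min, capped at
130; `DAY(t) = floor(t/24h) + 1` is the treatment day, so clearance is
piecewise-constant in time and declines day over day. Because clearance
varies with time, superposition does not hold; profiles are propagated
analytically segment by segment between dose/day/covariate breakpoints
(`numba`-compiled, exact within each segment, including segment-exact AUC).

Estimation is FOCE-I via the Laplace approximation at each subject's
conditional mode, with a Nelder–Mead outer search on log-transformed scales,
finite-difference RSEs, empirical Bayes estimates and shrinkage. Diagnostics
include CWRES, nonparametric bootstrap CIs, a VPC binned on time since last
dose, and MPE/MAPE external validation.

## Worked example

```python
from linzpk import (PopulationParameters, SyntheticCohortConfig,
                    analysis_subset, fit_population, generate_cohort,
                    overexposure_in_egfr_band)

# a 103-subject trough-oriented TDM cohort from the reference parameters
data, truth = generate_cohort(SyntheticCohortConfig(n_subjects=103, seed=11))
data = analysis_subset(data)          # drop subjects with only BLQ records

fit = fit_population(data)            # FOCE-I, all effects estimated
print(fit.parameter_table())
#           parameter  estimate  rse_percent
#        CL_pop (L/h)      5.09          9.1
#           V_pop (L)     35.2          19.1
#           beta_egfr      0.34         18.3
#            beta_day     -0.17          9.7
#            beta_age     -1.69         32.4
#        IIV CL (CV%)     32.3          10.8
#      RUV prop (CV%)     28.9           6.7
# (single-cohort sampling noise; medians over many replicate cohorts
#  recover the generating values — see "Reproducing the results")

# overexposure under standard dosing at severely reduced renal function
p, se = overexposure_in_egfr_band(egfr_band=(20, 25), day=10, seed=0)
print(f"{100*p:.0f}% of virtual individuals exceed an 8 mg/L trough")
# 64% (about two-thirds, matching the reference figure of ~70%)
```

Narrative walk-throughs live in `examples/`:

- `fit_cohort.py` — simulate, refit, compare to the generating values
- `diagnostics.py` — CWRES, VPC, bootstrap, external MPE/MAPE on a split
- `overexposure_simulation.py` — exposure and AUC24/MIC attainment grids
- `tdm_recommendation.py` — MAP forecast and regimen ranking for one patient

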