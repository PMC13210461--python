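# Methods

This note records the modelling assumptions, parameter conventions,
numerical choices and known limitations behind `linzpk`.

## Structural model

One-compartment disposition with zero-order (infusion) input and first-order
elimination. Clearance is covariate-driven and piecewise-constant in time:

```
CL_i(t) = CL_pop · (eGFR_i(t) / 59.6)^β_eGFR · (DAY(t) / 3.5)^β_day · (AGE_i / 78)^β_age · exp(η_i)
```

- `eGFR` is the absolute (BSA-corrected) CKD-EPI 2021 estimate in mL/min,
  capped at 130 (`cap_egfr`), supplied as a piecewise-constant series per
  subject.
- `DAY(t) = floor(t / 24 h) + 1`: the first 24 h of a subject's record are
  day 1. The centering value 3.5 is the typical TDM day.
- `η_i ~ N(0, ω²)` on clearance only; volume carries no random effect
  (troughs barely inform V, so IIV on V is not identifiable from this
  design).
- Proportional residual error: `y = f · (1 + σ ε)`, `ε ~ N(0, 1)`.
- Variabilities are reported as CV%: `100·ω` and `100·σ` (first-order
  convention for log-normal/proportional magnitudes of this size).

Default parameter values (`PopulationParameters`): CL_pop 4.25 L/h,
V 25.6 L, β_eGFR 0.29, β_day −0.18, β_age −1.16, ω 0.332, σ 0.265.

## Concentration propagation

Because clearance changes with calendar day (and with any eGFR knot),
superposition of single-dose solutions is invalid. Instead the engine builds
per-subject breakpoints — dose starts/ends, 24-h day boundaries, covariate
knots, query times — and propagates the concentration analytically across
each segment with constant rate `R` and clearance `CL`:

```
C(t0 + Δ) = C0 · e^(−kΔ) + (R / CL) · (1 − e^(−kΔ)),   k = CL / V
```

Within-segment AUC is exact: `(R/CL)·Δ + (C0 − C1)/k`. Troughs are read as
the concentration entering a breakpoint (the pre-dose convention). Kernels
are `numba`-compiled; a vectorized path propagates many individuals sharing
one design (Monte Carlo, VPC, TDM posterior draws). Correctness is pinned to
a stiff ODE oracle (`scipy.solve_ivp`, LSODA) on random regimens to
< 0.01 mg/L in the tests.

## Estimation (FOCE-I)

The marginal likelihood per subject is approximated by the Laplace method at
the conditional mode of the random effect, with residual variance evaluated
at the conditional estimate (FOCE with interaction). Writing

```
g(η) = Σ_j [ log(2π σ_j²) + (y_j − f_j(η))² / σ_j² ] + log(2π ω²) + η²/ω²,
σ_j = σ · f_j(η)
```

the per-subject objective is `OFV_i = g(η̂) + log(g''(η̂) / 4π)` at the inner
minimizer η̂. Two useful identities are enforced by tests: the OFV is
additive over subjects, and as ω → 0 it reduces exactly to the fixed-effects
−2 log-likelihood at η = 0. Against exact 1-D quadrature of the marginal
likelihood on small datasets the Laplace error measures ≈ 0.04–0.05 units
per subject; the tests bound it at 0.5 for a 3-subject toy set.

- Inner problem (1-D in η): 25-point coarse scan over
  `[min(η₀,0)−6, max(η₀,0)+6]` followed by golden-section refinement, with a
  finite-difference curvature at the optimum; warm-started across outer
  iterations. A safeguarded scan was chosen over Newton steps because the
  objective can be locally flat for trough-only subjects.
- Outer problem: Nelder–Mead (adaptive) on transformed scales — log for
  CL_pop, V, ω, σ; identity for the exponents. The objective embeds an inner
  optimization, so exact gradients are unavailable and a derivative-free
  method is the robust choice. Estimates at the variance-transform floor are
  flagged as boundary solutions.
- Precision: RSEs come from a central finite-difference Hessian of the OFV
  at the optimum (covariance = 2·H⁻¹), delta-method-converted so that
  log-scale parameters report `100·SE(log)`.
- Empirical Bayes: conditional modes with curvature-based posterior SDs;
  shrinkage is `100·(1 − SD(η̂)/ω)`.
- Covariate selection: greedy forward inclusion at ΔOFV > 3.84 (χ²₁,
  p < 0.05) and backward elimination at ΔOFV < 6.63 (p < 0.01).

## Monte Carlo simulation

Virtual individuals share one design per scenario; each gets a single η draw
held constant over the course (clearance still declines deterministically
with DAY). Troughs are evaluated pre-dose at `t = 24·day`; AUC24 is the
exact segment-sum over that day's window. The exposure grid draws one η
vector and reuses it across all (eGFR, day) cells, so monotonicity of the
reported fractions in both axes holds exactly, not just in expectation.

For a uniform eGFR band (e.g. 20–25 mL/min), each individual's constant
covariate effect folds exactly into the random effect
(`η_eff = η + β_eGFR · ln(eGFR_i / eGFR_mid)`), allowing a single
propagation at the band midpoint (`overexposure_in_egfr_band`).

## TDM dose individualization

`forecast_individual` computes the MAP η from a subject's quantifiable
troughs and projects the daily trough trajectory, with intervals from the
curvature-based posterior SD (optionally widened by residual error).
Subjects with no quantifiable observations fall back to the population prior
and are flagged. `recommend_regimen` scores candidate regimens over
posterior draws `N(η̂, se²)`: candidates whose probability of exceeding the
8 mg/L toxicity cutoff is above the cap are ranked after all compliant ones;
within a group, ranking is by in-band (2–7 mg/L) probability, then lower
daily dose, then longer interval.

## Synthetic cohort generator

Emulates the study population's *structure*, not its patients: truncated
normal age (mode 78, range 65–87), log-normal absolute eGFR (median ≈ 49,
IQR ≈ 26–75, capped at 130) with a weak negative Gaussian-copula correlation
to age (ρ ≈ −0.21), log-normal weight and treatment duration, and a
trough-oriented sampling protocol (first sample immediately before the
3rd–5th dose, repeats every 3–4 days, at most 6 samples, ~10% of draws
mid-interval). Observations below the LLOQ (0.8 mg/L) are flagged BLQ and
excluded from the analysis view (M1 method; ties at exactly 0.8 retained).
An optional adaptive mode halves the dose after a trough exceeds 8 mg/L
(off by default because it entangles parameter-recovery experiments).
Scope limits: no dropout or mortality process, no laboratory panels beyond
the model covariates, and correlations other than age–eGFR are left at zero
(unreported in the source material).

## Resolved open questions

- **Trough-at-breakpoint convention:** an observation at a dose time reads
  the concentration entering the breakpoint (true trough), not after the new
  infusion starts.
- **eGFR between measurements:** carried forward piecewise-constant
  (last-observation-carried-forward), matching how clinical covariates
  update.
- **CV% convention:** `100·ω` / `100·σ` rather than
  `100·sqrt(exp(ω²)−1)`; at these magnitudes the difference is < 2% relative
  and the linear convention matches the reported estimates.
- **LLOQ ties:** values exactly at 0.8 mg/L are retained as quantifiable;
  only strictly-below values are censored.

## Known limitations

- The age exponent is weakly identified (the cohort's age range is narrow);
  its single-cohort estimates scatter widely, which is why recovery is
  judged against a wide interval and aggregated over replicates.
- Nelder–Mead with an inner 1-D search is robust but slower than gradient
  methods; a full 7-parameter fit on a 103-subject cohort takes a few
  seconds.
- The bootstrap on very small cohorts (≤ 20 subjects) excludes a nontrivial
  fraction of replicates at variance boundaries; the summary reports the
  exclusion count and warns above 20%.
- No IIV on V, no covariance between random effects, and no
  between-occasion variability — none are identifiable from trough-only
  sampling.
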