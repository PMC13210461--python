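"""Model qualification on a synthetic development/validation split.

Fits the model on two-thirds of a cohort, then runs the standard
qualification battery: CWRES summary, a visual predictive check, external
MPE/MAPE on the held-out third, and a (small, illustrative) nonparametric
bootstrap of the parameter estimates.
"""

from linzpk import (
    SyntheticCohortConfig,
    analysis_subset,
    bootstrap_ci,
    cwres,
    fit_population,
    generate_cohort,
    mpe_mape,
    split_development_validation,
    vpc,
)

data, _ = generate_cohort(SyntheticCohortConfig(n_subjects=90, seed=4))
data = analysis_subset(data)
dev, val = split_development_validation(data, seed=1)
print(f"development: {len(dev.subjects)} subjects, validation: {len(val.subjects)}")

fit = fit_population(dev, compute_rse=False)
print(f"OFV {fit.ofv:.1f}, converged {fit.converged}")

res = cwres(dev, fit)
c = res.cwres
print(f"\nCWRES: mean {c.mean():+.3f}, SD {c.std(ddof=1):.3f} "
      f"(want ~0 and ~1), {res.n_fallback_subjects} fallback subjects")

v = vpc(dev, fit, n_sim=500, n_bins=6, seed=2)
t = v.table
inside = ((t.observed >= t.sim_ci_low) & (t.observed <= t.sim_ci_high)).mean()
print(f"VPC: {100 * inside:.0f}% of observed bin percentiles inside the "
      f"simulated 95% envelope ({v.n_sim} replicates)")

val_res = cwres(val, fit)  # population predictions for held-out subjects
frame = val_res.frame
mpe, mape = mpe_mape(frame["observed"], frame["pred_population"])
print(f"external validation (population predictions): "
      f"MPE {mpe:+.1f}%, MAPE {mape:.1f}%")

bs = bootstrap_ci(dev, n_reps=30, seed=3, maxfev=1500)
print(f"\nbootstrap ({bs.n_success} successful replicates, "
      f"{bs.n_excluded} excluded):")
print(bs.table.to_string(float_format=lambda x: f"{x:.3g}"))
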