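"""Stress-test the body-fat finding: measurement error, season, missing
data, alternative priors and reverse causality.

Each refit perturbs one assumption of the base model; a robust causal
conclusion should move little.
"""

import numpy as np

from canicort import (
    GeneratorConfig,
    MeasurementErrorSpec,
    fit_model,
    fit_with_alternative_prior,
    fit_with_imputation,
    fit_with_measurement_error,
    fit_with_season,
    generate_cohort,
    hpdi,
    reverse_causality_fit,
    study_model,
)

KW = dict(chains=2, iterations=1500, warmup=500, seed=3)


def line(name, fit):
    b = fit.beta
    lo, hi = hpdi(b)
    p = max(np.mean(b > 0), np.mean(b < 0))
    print(f"  {name:<28} beta {b.mean():+.2f}  97% HPDI ({lo:+.2f}, {hi:+.2f})  P(dir) {p:.0%}")


cohort, truth = generate_cohort(GeneratorConfig(seed=11))
spec = study_model("body_fat")
base = fit_model(spec, cohort, **KW)

print(f"true body-fat coefficient: {truth['betas']['body_fat_z']}\n")
line("base (complete case)", base)
line("measurement error (CV 11.8%)",
     fit_with_measurement_error(spec, cohort, MeasurementErrorSpec(0.118), **KW))
line("season added", fit_with_season(spec, cohort, **KW))
line("joint missing-data imputation", fit_with_imputation(spec, cohort, **KW))

alt, report = fit_with_alternative_prior(
    study_model("comorbidity"), cohort, "comorbidity_yes", (0.0, 1.0),
    base=fit_model(study_model("comorbidity"), cohort, **KW), **KW,
)
print(f"\ncomorbidity model, neutral prior N(0,1) instead of N(0.25,1):"
      f" shift in posterior mean = {report['shift']:+.3f}")

print("\nreverse causality (outcome = body fat, predictor = log HCC):")
line("all data", reverse_causality_fit(cohort, "all", **KW))
line("first visits only", reverse_causality_fit(cohort, "V0_only", **KW))
print("\nBecause regression associations are symmetric, a true forward effect"
      "\nleaves a nonzero but attenuated reverse coefficient; reverse estimates"
      "\nclearly smaller than the forward one (or spanning zero, as in the"
      "\nfirst-visit subset) argue against cortisol driving body fat.")
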