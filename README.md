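# canicort

Bayesian causal analysis of hair cortisol concentration (HCC) in dogs with
obesity.

Hair cortisol accumulates over weeks to months, making it a non-invasive
biomarker of chronic hypothalamic–pituitary–adrenal (HPA) axis activity.
In observational clinic cohorts, the question of whether adiposity,
comorbidity, age or coat colour *causally* raise HCC cannot be answered by
raw associations: confounding paths must be identified and blocked.
`canicort` implements that workflow end to end, for researchers analysing
per-visit cohort tables of dogs undergoing therapeutic weight reduction —
and, via its synthetic cohort generator, for anyone who wants to validate
the machinery before touching real data.

## What it does

1. **Causal identification.** A directed acyclic graph (DAG) of the assumed
   data-generating process is queried with the backdoor criterion: for each
   exposure X and outcome Y, the package enumerates the minimal sets Z of
   observed non-descendants of X such that X ⫫ Y | Z in the graph with X's
   outgoing edges removed. Exposures whose backdoor paths run through
   unmeasured variables (here: owner/environment factors behind weight-loss
   success and visit attendance) are declared unidentifiable.

2. **Skew-normal multilevel distributional regression.** For each
   identified exposure, standardised log HCC is modelled as

   ```
   logHCC*_i ~ SkewNormal(mu_i, sigma_i, alpha)
   mu_i      = b0 + beta * x_i + sum_k b_k z_ik + u_dog(i)
   u_dog     ~ Normal(0, tau)
   log sigma_i = gamma0 + gamma1 * comorbidity_i   (in comorbidity models)
   ```

   with the skew-normal in the centered parameterisation (mu and sigma are
   the mean and SD of the density; alpha > 0 gives right skew), tabulated
   weakly-regularising priors, and dog-level intercepts for repeated
   visits. Posteriors are drawn with a hand-written gradient-based HMC
   sampler (4 chains × 8,000 iterations by default) under a convergence
   contract of rank-normalised split R̂ ≤ 1.01 and bulk/tail ESS ≥ 400.

3. **Posterior reporting.** Posterior mean ± SD, 97% highest-posterior-
   density intervals, probability of direction, Bayes R², expected-value
   (`epred`) versus noise-inclusive (`predict`) prediction modes, and
   effect translation back to pg/mg of hair cortisol.

4. **Model comparison and robustness.** PSIS-LOO ranking of normal /
   Student-t / skew-normal likelihoods; sensitivity refits for assay
   measurement error (CV 11.8% on the outcome), season adjustment, joint
   Student-t imputation of missing body fat, alternative priors; and a
   reverse-causality model (body fat regressed on log HCC).

5. **Synthetic cohorts.** `generate_cohort` emulates the study conditions —
   52 dogs / 73 visits (21 paired), realistic covariate marginals, a
   skew-normal outcome with comorbidity-dependent residual scale, ~25%
   missing-completely-at-random body fat — and `recovery_experiment`
   re-enacts the generate-and-refit validation at 200 visits / 100 dogs
   with true coefficients 0, 0.2 and 0.5.

## Worked example

```bash
python examples/fit_body_fat_model.py
```

generates a study-sized synthetic cohort (true body-fat coefficient 0.33)
and fits the body-fat model. Output from one run:

```
cohort: 73 visits from 52 dogs, 21 missing body-fat values
generating body-fat coefficient: 0.33

Posterior summary (estimate = mean, error = SD, 97% HPDI):
      parameter  estimate  error  hpdi_low  hpdi_high  direction_probability
      intercept     -0.26   0.30     -0.88       0.41                   0.81
     body_fat_z      0.35   0.12      0.10       0.60                   1.00
          age_z     -0.26   0.13     -0.55       0.03                   0.97
     breed_CKCS      0.60   0.47     -0.38       1.61                   0.90
      breed_pug     -0.12   0.43     -1.07       0.83                   0.62
breed_retriever      0.06   0.32     -0.66       0.74                   0.58
    breed_other      0.11   0.29     -0.57       0.72                   0.65
       sex_male     -0.28   0.25     -0.85       0.25                   0.88
comorbidity_yes      0.35   0.28     -0.29       0.95                   0.90

P(positive body-fat effect) = 100%
Bayes R^2 = 0.34 (97% CI 0.16, 0.61)
+1 SD body fat -> +20.2 pg/mg hair cortisol on average
```

The `body_fat_z` row is the causal estimate: a one-SD increase in body fat
raises standardised log HCC by ~0.35 (97% HPDI excluding zero), close to
the generating value 0.33; the last line converts the contrast to the
natural pg/mg scale through the stored log-HCC standardiser. Other
examples cover adjustment-set identification (`adjustment_sets.py`),
likelihood selection by LOO (`likelihood_comparison.py`), the sensitivity
suite (`sensitivity_analyses.py`) and the recovery check
(`recovery_check.py`).

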