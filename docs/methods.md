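# Methods

## The scientific problem

Hair cortisol concentration (HCC, pg cortisol per mg hair) integrates
hypothalamic–pituitary–adrenal axis output over weeks to months. In a
cohort of dogs referred for therapeutic weight reduction, each clinic
visit yields one observation: age, sex, breed group, coat colour,
sampling season, comorbidity status, body fat percentage (by DXA, missing
for some visits) and HCC. Some dogs contribute two visits (before and
after weight reduction), so observations are clustered within dog. The
question is which of these variables *causally* influence HCC.

## Causal identification

The assumed data-generating process is encoded as a DAG
(`canicort/data/study_dag.txt`). The shipped graph is a **reconstruction**:
it is constrained to reproduce the analysis's published adjustment sets
(age adjusted for breed; sex, breed and season unadjusted; coat adjusted
for breed; comorbidity adjusted for age, breed and sex; body fat adjusted
for age, breed, sex and comorbidity) and the two stated unidentifiable
exposures (weight-loss success and visit, confounded by unmeasured
owner/environment factors that also drive body fat). The exact arrow set
among those unobserved factors is not uniquely determined by these
constraints; only their consequences are.

`backdoor_sets` enumerates subsets of observed non-descendants of the
exposure in increasing size, keeps the minimal valid ones (sorted by size
then lexicographically for reproducibility), and tests validity as
d-separation of exposure and outcome — given the candidate set — in the
graph with the exposure's outgoing edges removed. d-separation itself is
delegated to networkx; the test suite re-derives every result with an
independent brute-force path-enumeration oracle applying the chain / fork /
collider rules directly, over random DAGs up to 8 nodes and over the
study graph. Unobserved nodes never enter candidate sets by construction.

## Outcome model

HCC is natural-log transformed and standardised (z-scored over the pooled
analysis sample, both visits together); continuous predictors are
standardised the same way; categorical predictors are dummy-coded against
fixed reference levels (female, mixed breed, light coat, spring, no
comorbidity). Standardisation state lives in `Scaler` objects so that
effects can be mapped back to pg/mg.

The likelihood is a skew-normal in the **centered parameterisation**:
parameters (mu, sigma, alpha) are the mean, SD and shape of the density,
converted internally to the direct location/scale (xi, omega) via
delta = alpha/sqrt(1+alpha²). This matches how the priors are stated
(on mean-scale quantities) and makes alpha = 0 exactly the normal model.
Even after the log transform the outcome stays modestly right-skewed,
which is why the family comparison (below) favours the skew-normal.

Linear predictor and hierarchy:

- mu_i = intercept + beta·x_i + Σ adjustment terms + u_dog(i);
- dog intercepts are non-centered: u = tau · z, z ~ N(0,1), with a
  half-normal(0, 1) prior on tau. The tabulated "group Normal(0, 1)"
  prior is interpreted as this scale prior — the group-level quantity
  requiring a prior is a standard deviation;
- in models containing comorbidity (as predictor or adjustment), the
  residual scale is distributional: log sigma_i = gamma0 +
  gamma1·comorbidity_i with N(0,1) priors on the gammas (the published
  table omits these; a log link guarantees positivity). Other models use
  a single sigma with an exponential(1) prior;
- alpha has a Normal(4, 2) prior, untruncated (right skew favoured,
  left allowed);
- coefficient priors follow the published table: e.g. intercept N(0, 0.5),
  body fat N(0, 0.5), comorbidity N(0.25, 1) (slightly positive,
  informed), coat contrasts N(-0.070/-0.075, 1) (slightly negative,
  informed), breed contrasts N(-0.070/-0.075, 1.5) in the breed model and
  N(0, 1) as adjustments. The reverse-causality model uses a normal
  likelihood with its own tabulated priors.

`prior_predictive` draws all parameters from these priors and simulates
outcome replicates, to confirm pre-data predictions span the plausible
standardised range.

## Sampling

Posteriors are drawn with a hand-written Hamiltonian Monte Carlo sampler:
analytic gradients of the full joint (all likelihood kernels and priors
hand-differentiated and pinned by finite-difference tests), a diagonal
mass matrix estimated in expanding warmup windows, step size tuned by
dual averaging to a target acceptance of 0.85, and trajectory lengths of
~2 time units with ±20% jitter to avoid resonance. Scale parameters are
sampled on the log scale with the Jacobian included; off-support or
overflowing evaluations return -inf so divergent trajectories are
rejected rather than crashing. Per-chain RNGs are spawned from
`SeedSequence((seed, chain))`; chains run sequentially, so a seed fully
determines the output bit-for-bit.

The default budget mirrors the study protocol: 4 chains × 8,000
iterations (2,000 warmup). The contract checked on fits is rank-normalised
split R̂ ≤ 1.01 and bulk/tail ESS ≥ 400 for every parameter (diagnostics
via arviz). Tests and examples use reduced budgets (2–4 chains, ~1,000–
2,000 retained draws per chain) chosen as the package's own trade-off
between runtime and Monte-Carlo error; the contract assertions in the
acceptance suite run at 4 × 2,500.

## Posterior reporting

- **97% HPDI**: narrowest contiguous interval holding 97% of pooled
  post-warmup draws (sorted-window algorithm; ties resolve to the first,
  narrower window). Cross-checked against arviz's implementation.
- **Probability of direction**: fraction of draws strictly positive (or
  negative); reported to the nearest percent.
- **Bayes R²**: per draw, Var_obs(fitted mean) / (Var_obs(fitted mean) +
  mean residual variance), with per-observation sigma² averaged in
  distributional models; summarised by median and 97% equal-tail CI.
- **Prediction modes**: `epred` returns draws of the expected outcome
  (the centered skew-normal's mean is mu); `predict` additionally samples
  skew-normal residual noise, so its bands contain the epred bands.
- **pg/mg effects**: counterfactual predictions at two settings of the
  focal covariate for every observed row, back-transformed through the
  log-HCC scaler and averaged. Residual noise is included (predict mode)
  and **shared** between the two counterfactual arms — a same-dog,
  same-residual contrast — which leaves the mean difference unchanged
  while removing needless Monte-Carlo variance. When the contrast variable
  also drives sigma (comorbidity), each arm uses its own residual scale.

## Likelihood-family selection

`select_likelihood` fits the same specification under normal, Student-t
and skew-normal likelihoods and ranks them by PSIS-LOO (smaller LOOIC
better). The Student-t degrees of freedom get a gamma(2, 0.1) prior and
appear only in this comparison stage. LOO is computed by arviz from the
pointwise log-likelihood matrix; the test suite validates it against an
exact brute-force oracle (n refits, each leaving one observation out,
with the held-out dog's random intercept integrated out analytically).
The ranking is reported with elpd-difference standard errors and Pareto-k
counts; no automatic winner threshold is applied, since the family choice
also weighs the posterior predictive check.

## Sensitivity analyses

- **Measurement error** in the outcome: a latent true standardised log
  HCC per observation, with the observed value normal around it at SD
  sqrt(ln(1 + CV²)) / SD(logHCC) — the lognormal delta relation mapping
  the assay CV (default 11.8%) to the standardised log scale.
- **Season**: the three season contrasts (N(0,1) priors) appended to the
  adjustment set, with a comparison report against the base fit.
- **Missing body fat**: a joint model in which each missing standardised
  body-fat value is a parameter; body fat follows a Student-t submodel on
  its DAG-indicated causes (age, breed, sex, comorbidity; N(0,1)
  coefficient priors, exponential(1) scale, gamma(2, 0.1) dof), without
  its own dog-level intercepts — one visit's body fat is nearly
  deterministic given the other visit's, so the fixed-effect submodel is
  the parsimonious choice. All parameters share one posterior.
- **Alternative priors**: any coefficient prior can be swapped (e.g. the
  neutral N(0,1) comorbidity prior) with a divergence report of the
  posterior shift. This explicit refit-based check replaces power-scaling
  diagnostics: simpler, and it answers the same question directly.
- **Reverse causality**: standardised body fat regressed on log HCC with
  the same adjustment set, on all data and on first visits only (all 52
  V0 records). Note that in a linear system a true forward effect implies
  a nonzero, attenuated reverse association — regression is symmetric —
  so the diagnostic signal is attenuation and interval width, not a
  coefficient at exactly zero.

## Synthetic cohort generator

`GeneratorConfig` defaults define the emulated study conditions: 52 dogs
of which 21 contribute paired visits (73 visits); age ~ N(90, 34) months
with +18 months at the second visit; 58% female; breed mix 21/12/10/23/35%
(mixed/CKCS/pug/retriever/other); coat 35/25/40%; seasons by the observed
counts; 85% comorbidity prevalence; body fat ~ N(43, 6)% before and
~10 ± 4 points lower after weight reduction; 18/73 MCAR missingness in
body fat. The outcome is generated on the standardised log scale —
skew-normal with alpha = 4, dog SD 0.3, comorbidity-dependent residual
scale — and mapped to pg/mg via a configurable log-scale scaler (default
mean 1.3, SD 1.36). When residual scales are not set explicitly they are
solved so the standardised outcome has total variance ≈ 1 (the analysed
outcome has SD 1 by construction) with sigma_no/sigma_yes = 0.6,
emulating the larger HCC spread in comorbid dogs. Default coefficients:
body fat 0.33, comorbidity 0.5, age -0.1, sex 0.1.

What the generator does **not** emulate: owner-behaviour confounding of
weight-loss success (unidentifiable in the causal model by design),
informative missingness, season effects on the outcome, assay
quantification limits, and any nonlinearity in the covariate effects.
Tests passing on synthetic cohorts therefore validate the machinery —
identification, inference, calibration — not the substantive findings on
real clinical data.

`recovery_experiment` runs the generate-and-refit validation: cohorts of
100 dogs × 2 visits with true body-fat coefficients 0, 0.2, 0.5, fitted
with the body-fat specification; reported per effect size as mean
estimate, bias and 97%-HPDI coverage, with non-convergent replicates
flagged and excluded.

## Numerical notes and limitations

- Skew-normal log-CDF terms use `scipy.special.log_ndtr`; the phi/Phi
  ratio is computed in log space for left-tail stability.
- With a single visit per dog, sigma and tau are only weakly separated
  (the classic funnel); the non-centered parameterisation keeps this
  sampleable, but reduced-budget fits on such designs can need relaxed
  diagnostics. Paired designs identify both scales.
- HPDI and direction probabilities are Monte-Carlo quantities; with the
  default budget (24,000 pooled draws) endpoint noise is ~0.01–0.02 on
  standardised scales.
- The age unit (months vs years) is irrelevant to coefficients because
  age is standardised; months are used throughout (1 SD ≈ 34 months).
- `standardise` uses the sample SD with ddof=1 and the natural log.
- Exposures declared unidentifiable are never fitted; the package refuses
  to produce a causal estimate no observed adjustment set supports.
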