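"""Model construction: parameter layout, joint density, gradients, priors."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from canicort.cohort import Cohort
from canicort.fit import fit_model, prior_predictive
from canicort.model import (
    LinearModel,
    ModelSpec,
    PriorSpec,
    build_model,
    complete_case_rows,
    study_model,
    study_models,
)
from canicort.simulate import GeneratorConfig, generate_cohort


def finite_diff_check(model, seed=0, tol=1e-4):
    rng = np.random.default_rng(seed)
    th = model.initial_point(rng)
    lp, g = model.logp_grad(th)
    assert np.isfinite(lp)
    eps = 1e-6
    num = np.empty(model.dim)
    for i in range(model.dim):
        tp, tm = th.copy(), th.copy()
        tp[i] += eps
        tm[i] -= eps
        num[i] = (model.logp(tp) - model.logp(tm)) / (2 * eps)
    err = np.max(np.abs(num - g) / (1 + np.abs(num)))
    assert err < tol, f"max relative gradient error {err}"


@pytest.fixture(scope="module")
def cohort():
    c, _ = generate_cohort(GeneratorConfig(n_dogs=14, seed=5, missing_rate=0.25))
    return c


def test_body_fat_model_parameter_layout(study_like_cohort):
    """The body-fat model has intercept, 7 betas, alpha, 2 sigma-submodel
    coefficients, one intercept per dog and a group SD."""
    cohort, _ = study_like_cohort
    spec = study_model("body_fat")
    rows = complete_case_rows(spec, cohort)
    m = build_model(spec, cohort, rows=rows)
    assert m.colnames == [
        "intercept", "body_fat_z", "age_z", "breed_CKCS", "breed_pug",
        "breed_retriever", "breed_other", "sex_male", "comorbidity_yes",
    ]
    assert m.index["z"].stop - m.index["z"].start == m.n_groups
    assert "gamma" in m.index and "alpha" in m.index
    assert "log_sigma" not in m.index  # no fixed sigma in comorbidity models
    assert m.dim == 9 + m.n_groups + 1 + 2 + 1


@pytest.mark.parametrize(
    "variant",
    ["body_fat", "age", "reverse_causality", "student_t", "measurement_error", "imputation"],
)
def test_joint_gradient_matches_finite_differences(cohort, variant):
    if variant == "student_t":
        spec = dataclasses.replace(study_model("age"), likelihood="student_t", name="age_t")
        m = build_model(spec, cohort)
    elif variant == "measurement_error":
        m = build_model(study_model("comorbidity"), cohort, measurement_error_sd=0.1)
    elif variant == "imputation":
        m = build_model(
            study_model("body_fat"), cohort,
            imputation_terms=("age", "breed", "sex", "comorbidity"),
        )
    else:
        spec = study_model(variant)
        m = build_model(spec, cohort, rows=complete_case_rows(spec, cohort))
    finite_diff_check(m)


def test_joint_density_equals_sum_of_independent_terms(cohort):
    """Term-by-term oracle: likelihood + priors recomputed independently."""
    spec = study_model("age")
    m = build_model(spec, cohort)
    rng = np.random.default_rng(1)
    th = m.initial_point(rng)
    ix = m.index
    b = th[ix["b"]]
    z = th[ix["z"]]
    tau = np.exp(th[ix["log_tau"]][0])
    sigma = np.exp(th[ix["log_sigma"]][0])
    alpha = th[ix["alpha"]][0]

    from canicort import skewnorm

    mu = m.X @ b + tau * z[m.group_idx]
    want_full = float(np.sum(skewnorm.logpdf(m.y, mu, sigma, alpha)))
    want_full += float(np.sum(-0.5 * ((b - m.coef_prior_mean) / m.coef_prior_sd) ** 2))
    want_full += float(np.sum(-0.5 * z * z))
    want_full += -0.5 * tau**2 + np.log(tau)  # half-normal(1) + Jacobian
    want_full += -sigma + np.log(sigma)  # exponential(1) + Jacobian
    want_full += -0.5 * ((alpha - 4.0) / 2.0) ** 2
    got, _ = m.logp_grad(th)
    assert got == pytest.approx(want_full, rel=1e-12)


def test_collapses_to_fixed_effects_regression():
    """One observation per dog, group SD pinned ~0, normal likelihood:
    the joint density differs from the plain linear-model log-posterior
    only through the inert group/scale blocks."""
    c, _ = generate_cohort(GeneratorConfig(n_dogs=25, paired_fraction=0.0, seed=2,
                                           missing_rate=0.0))
    spec = dataclasses.replace(study_model("reverse_causality"), name="plain")
    m = build_model(spec, c, rows=complete_case_rows(spec, c))
    rng = np.random.default_rng(3)
    th = m.initial_point(rng)
    th[m.index["z"]] = 0.0
    b = th[m.index["b"]]
    sigma = np.exp(th[m.index["log_sigma"]][0])
    mu = m.X @ b
    lp_lik = float(np.sum(stats.norm.logpdf(m.y, mu, sigma)))
    lp_prior = float(np.sum(-0.5 * ((b - m.coef_prior_mean) / m.coef_prior_sd) ** 2))
    got, _ = m.logp_grad(th)
    tau = np.exp(th[m.index["log_tau"]][0])
    inert = -0.5 * tau**2 + np.log(tau) - sigma + np.log(sigma)
    assert got == pytest.approx(lp_lik + lp_prior + inert, rel=1e-10)


def test_missing_covariates_raise_with_imputation_hint(cohort):
    with pytest.raises(ValueError, match="imputation"):
        build_model(study_model("body_fat"), cohort)  # NaN body fat present


def test_all_study_models_build(study_like_cohort):
    cohort, _ = study_like_cohort
    for name, spec in study_models().items():
        rows = complete_case_rows(spec, cohort)
        m = build_model(spec, cohort, rows=rows)
        assert m.dim > m.p
        lp, g = m.logp_grad(m.initial_point(np.random.default_rng(0)))
        assert np.isfinite(lp) and np.all(np.isfinite(g))


def test_prior_spec_validation():
    with pytest.raises(ValueError):
        PriorSpec("sigma", "exponential", (1.0, 2.0))
    with pytest.raises(ValueError):
        PriorSpec("b", "cauchy", (0.0, 1.0))
    with pytest.raises(ValueError):
        ModelSpec(name="bad", outcome="log_hcc", predictor="age",
                  adjustment=("age",))


def test_prior_predictive_matches_tabulated_priors(study_like_cohort):
    """Comorbidity beta prior centred at 0.25 (SD 1); body fat at 0 (SD 0.5)."""
    cohort, _ = study_like_cohort
    pr = prior_predictive(study_model("comorbidity"), cohort, n_draws=4000, seed=0)
    assert pr["beta"].mean() == pytest.approx(0.25, abs=0.06)
    assert pr["beta"].std() == pytest.approx(1.0, abs=0.06)
    pr = prior_predictive(study_model("body_fat"), cohort, n_draws=4000, seed=0)
    assert pr["beta"].mean() == pytest.approx(0.0, abs=0.03)
    assert pr["beta"].std() == pytest.approx(0.5, abs=0.03)
    assert pr["y_rep"].shape[1] == complete_case_rows(study_model("body_fat"), cohort).sum()


def test_prior_predictive_spans_plausible_range(study_like_cohort):
    """Pre-data replicates must cover the standardised outcome range."""
    cohort, _ = study_like_cohort
    pr = prior_predictive(study_model("body_fat"), cohort, n_draws=1000, seed=1)
    y = cohort.df["log_hcc_z"].to_numpy()
    assert pr["y_rep"].min() < y.min() and pr["y_rep"].max() > y.max()


def test_location_equivariance_of_intercept():
    """Adding a constant to the (unstandardised-scale) outcome shifts only
    the intercept: checked on the joint density via a profile argument —
    shifting y and the intercept together leaves the likelihood unchanged."""
    c, _ = generate_cohort(GeneratorConfig(n_dogs=12, seed=9, missing_rate=0.0))
    spec = study_model("sex")
    m = build_model(spec, c)
    rng = np.random.default_rng(4)
    th = m.initial_point(rng)
    lp0, _ = m.logp_grad(th)
    shift = 0.37
    m_shifted = LinearModel(
        spec, m.X, m.colnames, m.y + shift, m.group_idx, m.n_groups
    )
    th_shifted = th.copy()
    th_shifted[m.index["b"].start] += shift  # intercept absorbs the shift
    lp1, _ = m_shifted.logp_grad(th_shifted)
    # difference comes only from the intercept prior term
    b0 = th[m.index["b"].start]
    pm, psd = m.coef_prior_mean[0], m.coef_prior_sd[0]
    prior_delta = (-0.5 * ((b0 + shift - pm) / psd) ** 2) - (-0.5 * ((b0 - pm) / psd) ** 2)
    assert lp1 - lp0 == pytest.approx(prior_delta, abs=1e-10)
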