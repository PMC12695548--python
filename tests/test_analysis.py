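"""Posterior summaries: HPDI, direction probabilities, R2, predictions,
natural-scale effects."""

import numpy as np
import pytest
import arviz as az
from hypothesis import given, settings, strategies as st
from scipy import stats

from canicort.analysis import (
    bayes_r2,
    bayes_r2_fit,
    direction_probability,
    hpdi,
    natural_scale_effect,
    predict,
    summarise_fit,
)
from canicort.cohort import Scaler


# ---------------------------------------------------------------------------
# hpdi
# ---------------------------------------------------------------------------


def test_hpdi_point_mass():
    lo, hi = hpdi(np.full(2000, 3.14))
    assert lo == hi == 3.14


def test_hpdi_standard_normal_matches_quantile_oracle():
    """For a symmetric unimodal density the HPDI equals the equal-tail
    interval: +-2.17 SD for 97% mass."""
    rng = np.random.default_rng(0)
    d = rng.standard_normal(200_000)
    lo, hi = hpdi(d, 0.97)
    q = stats.norm.ppf(0.985)
    assert lo == pytest.approx(-q, abs=0.07)
    assert hi == pytest.approx(q, abs=0.07)


def test_hpdi_asymmetric_narrower_than_equal_tail():
    rng = np.random.default_rng(1)
    d = rng.exponential(1.0, 100_000)
    lo, hi = hpdi(d, 0.9)
    et = np.quantile(d, [0.05, 0.95])
    assert (hi - lo) < (et[1] - et[0])
    assert lo == pytest.approx(0.0, abs=0.01)


def test_hpdi_agrees_with_arviz():
    rng = np.random.default_rng(2)
    d = rng.gamma(2.0, 1.0, 50_000)
    lo, hi = hpdi(d, 0.97)
    ref = az.hdi(d, hdi_prob=0.97)
    assert lo == pytest.approx(ref[0], abs=0.02)
    assert hi == pytest.approx(ref[1], abs=0.02)


def test_hpdi_invalid_mass():
    with pytest.raises(ValueError):
        hpdi(np.zeros(10), 1.5)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_hpdi_width_monotone_in_mass_and_spans_range(seed):
    rng = np.random.default_rng(seed)
    d = rng.standard_t(5, size=2000)
    widths = []
    for mass in (0.5, 0.8, 0.97, 0.999):
        lo, hi = hpdi(d, mass)
        widths.append(hi - lo)
        assert lo >= d.min() and hi <= d.max()
    assert all(w1 <= w2 + 1e-12 for w1, w2 in zip(widths, widths[1:]))
    lo, hi = hpdi(d, 0.9999999)
    assert lo == d.min() and hi == d.max()


# ---------------------------------------------------------------------------
# direction probabilities
# ---------------------------------------------------------------------------


def test_direction_probability_symmetric_draws():
    rng = np.random.default_rng(3)
    d = rng.standard_normal(100_000)
    assert direction_probability(d, "positive") == pytest.approx(0.5, abs=0.01)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.floats(-2, 2))
def test_direction_probabilities_sum_to_one(seed, shift):
    rng = np.random.default_rng(seed)
    d = rng.standard_normal(500) + shift
    p_pos = direction_probability(d, "positive")
    p_neg = direction_probability(d, "negative")
    assert p_pos + p_neg == pytest.approx(1.0)  # no ties at exactly zero a.s.
    assert 0.0 <= p_pos <= 1.0


# ---------------------------------------------------------------------------
# Bayes R^2
# ---------------------------------------------------------------------------


def test_bayes_r2_noiseless_limit_and_pure_noise():
    rng = np.random.default_rng(4)
    fits = rng.standard_normal((500, 60))
    out = bayes_r2(fits, np.full(500, 1e-12))
    assert out["median"] == pytest.approx(1.0, abs=1e-6)
    out2 = bayes_r2(np.zeros((500, 60)) + rng.standard_normal((500, 1)) * 1e-6,
                    np.ones(500))
    assert out2["median"] < 0.01
    assert np.all((out2["draws"] >= 0) & (out2["draws"] <= 1))


def test_bayes_r2_zero_total_variance_errors():
    with pytest.raises(ValueError):
        bayes_r2(np.zeros((10, 5)), np.zeros(10))


# ---------------------------------------------------------------------------
# fit-based summaries (shared reduced-budget fit)
# ---------------------------------------------------------------------------


def test_predict_variance_ordering(bodyfat_fit):
    """predict draws dominate epred draws in variance at every point."""
    fit, _ = bodyfat_fit
    ep = predict(fit, mode="epred")
    pp = predict(fit, mode="predict", seed=0)
    assert ep.shape == pp.shape
    assert np.all(pp.var(axis=0) >= ep.var(axis=0))
    with pytest.raises(ValueError):
        predict(fit, mode="wiggle")


def test_posterior_predictive_envelopes_observed_density(bodyfat_fit):
    """Replicates from the fitted skew-normal model must cover the observed
    standardised outcome distribution (posterior predictive check)."""
    fit, _ = bodyfat_fit
    pp = predict(fit, mode="predict", seed=1)
    y = fit.model.y
    rep_q = np.quantile(pp, [0.05, 0.95], axis=1)  # per-draw outcome quantiles
    # observed quantiles lie inside the spread of replicate quantiles
    for q, obs in zip((0.05, 0.95), np.quantile(y, [0.05, 0.95])):
        lo, hi = np.quantile(rep_q[(0.05, 0.95).index(q)], [0.01, 0.99])
        assert lo <= obs <= hi


def test_summary_table_shape_and_rounding(bodyfat_fit):
    fit, truth = bodyfat_fit
    t = summarise_fit(fit)
    assert list(t.parameter) == fit.model.colnames
    row = t[t.parameter == "body_fat_z"].iloc[0]
    assert row.hpdi_low <= row.estimate <= row.hpdi_high
    assert 0.5 <= row.direction_probability <= 1.0
    assert row.estimate == round(row.estimate, 2)


def test_summaries_invariant_to_chain_order_and_thinning(bodyfat_fit):
    fit, _ = bodyfat_fit
    d = fit.beta
    lo, hi = hpdi(d)
    swapped = fit.coef_chains("body_fat_z")[::-1].reshape(-1)
    lo2, hi2 = hpdi(swapped)
    assert (lo, hi) == (lo2, hi2)
    thinned = d[::2]
    assert len(thinned) >= 1000
    lo3, hi3 = hpdi(thinned)
    assert lo3 == pytest.approx(lo, abs=0.1) and hi3 == pytest.approx(hi, abs=0.1)
    assert direction_probability(thinned) == pytest.approx(
        direction_probability(d), abs=0.03
    )


def test_natural_scale_effect_null_coefficient_is_zero(bodyfat_fit):
    """If all draws of the coefficient are zero the pg/mg contrast vanishes."""
    fit, _ = bodyfat_fit
    import copy

    fit0 = copy.deepcopy(fit)
    j = fit0.model.colnames.index("body_fat_z")
    fit0.draws.theta[:, :, fit0.model.index["b"]][:, :, j] = 0.0
    # epred mode: no residual-noise Monte-Carlo error at all
    eff = natural_scale_effect(fit0, "body_fat_z", 1.0, mode="epred")
    assert eff.mean_difference == pytest.approx(0.0, abs=1e-10)


def test_natural_scale_effect_sign_and_scaler(bodyfat_fit):
    fit, truth = bodyfat_fit
    eff = natural_scale_effect(fit, "body_fat_z", 1.0, seed=0)
    assert eff.mean_difference > 0  # positive causal effect in pg/mg
    # explicit scaler on the log scale
    eff2 = natural_scale_effect(
        fit, "body_fat_z", 1.0, seed=0,
        scaler=Scaler(mean=fit.cohort.scalers["log_hcc"].mean,
                      sd=fit.cohort.scalers["log_hcc"].sd, log_applied=True),
    )
    assert eff2.mean_difference == pytest.approx(eff.mean_difference, rel=1e-9)


def test_bayes_r2_fit_in_unit_interval(bodyfat_fit):
    fit, _ = bodyfat_fit
    out = bayes_r2_fit(fit)
    assert 0.0 < out["median"] < 1.0
    assert out["ci_low"] <= out["median"] <= out["ci_high"]
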