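"""Shared fixtures: synthetic cohorts and reusable reduced-budget fits.

Posterior fits are expensive, so fits that several test modules inspect
are session-scoped; tests that only need draws re-use them rather than
refitting.  Reduced sampling budgets (2 chains, ~1000 retained draws) are
used wherever the test does not assert the full convergence contract.
"""

import numpy as np
import pytest

from canicort import GeneratorConfig, fit_model, generate_cohort, study_model


@pytest.fixture(scope="session")
def study_like_cohort():
    """52-dog cohort mirroring the study's structure and marginals."""
    cohort, truth = generate_cohort(GeneratorConfig(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny complete cohort for fast model-construction tests."""
    cfg = GeneratorConfig(n_dogs=15, seed=3, missing_rate=0.0)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def bodyfat_fit(study_like_cohort):
    """Reduced-budget body-fat fit shared across analysis tests."""
    cohort, truth = study_like_cohort
    fit = fit_model(
        study_model("body_fat"), cohort, chains=2, iterations=1400, warmup=400, seed=3
    )
    return fit, truth


@pytest.fixture(scope="session")
def comorbidity_fit(study_like_cohort):
    cohort, truth = study_like_cohort
    fit = fit_model(
        study_model("comorbidity"), cohort, chains=2, iterations=1400, warmup=400, seed=3
    )
    return fit, truth
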