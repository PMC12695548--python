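"""Sensitivity analyses: measurement error, season adjustment, joint
missing-data imputation, alternative priors, and the reverse-causality model.

Each function refits a base model under one perturbation of its
assumptions and returns the refit (plus a comparison report where a base
fit is supplied), mirroring how the robustness of the body-fat and
comorbidity findings is probed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .analysis import hpdi, majority_direction
from .cohort import Cohort, TERM_COLUMNS
from .fit import FitResult, fit_model
from .model import ModelSpec, study_model


@dataclass(frozen=True)
class MeasurementErrorSpec:
    """Known assay noise, as a coefficient of variation of the HCC assay."""

    assay_cv: float = 0.118

    def __post_init__(self):
        if self.assay_cv <= 0:
            raise ValueError("cv must be > 0")

    @property
    def log_scale_sd(self) -> float:
        """SD of multiplicative assay noise on the log scale.

        Uses the lognormal relation sd_log = sqrt(ln(1 + cv^2)).
        """
        return math.sqrt(math.log1p(self.assay_cv**2))

    def standardised_sd(self, cohort: Cohort) -> float:
        """Noise SD on the standardised log-HCC scale."""
        cohort.prepare()
        return self.log_scale_sd / cohort.scalers["log_hcc"].sd


@dataclass(frozen=True)
class ImputationSpec:
    """Joint Student-t submodel for missing body fat."""

    variable: str = "body_fat"
    predictors: Tuple[str, ...] = ("age", "breed", "sex", "comorbidity")


def compare_fits(base: FitResult, refit: FitResult, column: Optional[str] = None) -> Dict:
    """Shift in the causal coefficient between a base fit and a refit."""
    col = column or base.spec.focal_columns[0]
    b0, b1 = base.coef(col), refit.coef(col)
    d0, p0 = majority_direction(b0)
    d1, p1 = majority_direction(b1)
    return {
        "column": col,
        "base_mean": float(np.mean(b0)),
        "refit_mean": float(np.mean(b1)),
        "shift": float(np.mean(b1) - np.mean(b0)),
        "base_hpdi": hpdi(b0),
        "refit_hpdi": hpdi(b1),
        "base_direction": (d0, p0),
        "refit_direction": (d1, p1),
    }


def fit_with_measurement_error(
    spec: ModelSpec,
    cohort: Cohort,
    me: MeasurementErrorSpec = MeasurementErrorSpec(),
    **fit_kwargs,
) -> FitResult:
    """Refit with a latent true outcome observed with known assay noise.

    The observed standardised log HCC is modelled as normal around a latent
    value with SD derived from the assay CV; the latent value carries the
    skew-normal regression.
    """
    if spec.outcome != "log_hcc":
        raise ValueError("measurement-error model is defined for the log-HCC outcome")
    sd = me.standardised_sd(cohort)
    return fit_model(spec, cohort, measurement_error_sd=sd, **fit_kwargs)


def fit_with_season(spec: ModelSpec, cohort: Cohort, **fit_kwargs) -> FitResult:
    """Refit with the three sampling-season contrasts appended."""
    if "season" in spec.terms:
        raise ValueError("model already contains season")
    priors = dict(spec.coef_priors)
    for c in TERM_COLUMNS["season"]:
        priors[c] = (0.0, 1.0)
    season_spec = replace(
        spec,
        name=f"{spec.name}+season",
        adjustment=(*spec.adjustment, "season"),
        coef_priors=priors,
    )
    return fit_model(season_spec, cohort, **fit_kwargs)


def fit_with_imputation(
    spec: ModelSpec,
    cohort: Cohort,
    imp: ImputationSpec = ImputationSpec(),
    **fit_kwargs,
) -> FitResult:
    """Joint fit in which missing body-fat values are model parameters.

    Missing entries are drawn with all other parameters from a single joint
    posterior; body fat itself follows a Student-t submodel with its
    DAG-indicated predictors.  With no missing data this reduces to (and
    falls back on) the plain complete-case fit.
    """
    cohort.prepare()
    n_missing = int(cohort.df["body_fat"].isna().sum())
    if n_missing == 0:
        warnings.warn("no missing body-fat values: falling back to the plain fit")
        return fit_model(spec, cohort, **fit_kwargs)
    return fit_model(
        spec, cohort, complete_case=False, imputation_terms=imp.predictors, **fit_kwargs
    )


def fit_with_alternative_prior(
    spec: ModelSpec,
    cohort: Cohort,
    parameter: str,
    new_prior: Tuple[float, float],
    base: Optional[FitResult] = None,
    **fit_kwargs,
) -> Tuple[FitResult, Optional[Dict]]:
    """Refit with a substituted normal prior on one coefficient.

    Used for the neutral weakly-regularising comorbidity prior check.
    Returns the refit and, when ``base`` is given, a divergence report of
    posterior mean/HPDI shifts.
    """
    if parameter not in spec.coef_priors:
        raise KeyError(f"{parameter!r} has no prior in this model")
    priors = dict(spec.coef_priors)
    priors[parameter] = (float(new_prior[0]), float(new_prior[1]))
    alt_spec = replace(spec, name=f"{spec.name}|prior({parameter})", coef_priors=priors)
    refit = fit_model(alt_spec, cohort, **fit_kwargs)
    report = compare_fits(base, refit, column=parameter) if base is not None else None
    return refit, report


def reverse_causality_fit(
    cohort: Cohort, subset: str = "all", **fit_kwargs
) -> FitResult:
    """Fit standardised body fat on log HCC (exposure/outcome roles swapped).

    ``subset='V0_only'`` restricts to first visits, guarding against
    weight-reduction effects on HCC masking a reverse effect.
    """
    if subset not in ("all", "V0_only"):
        raise ValueError("subset must be 'all' or 'V0_only'")
    spec = study_model("reverse_causality")
    rows = None
    if subset == "V0_only":
        rows = (cohort.df["visit"] == "V0").to_numpy()
    return fit_model(spec, cohort, rows=rows, **fit_kwargs)
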