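"""Multilevel distributional regression models with analytic gradients.

Every model in the workflow shares one structure: a linear predictor for
the mean of a standardised outcome,

    mu_i = intercept + sum_k beta_k x_ik + u_dog(i),   u_dog ~ N(0, tau),

a likelihood family (normal, Student-t or skew-normal), and optionally a
*distributional* residual scale, log(sigma_i) = gamma0 + gamma1 * comorbidity_i,
used wherever comorbidity enters a model (the residual spread of log HCC
differs visibly between dogs with and without comorbidities).  Dog-level
intercepts use the non-centered parameterisation (u = tau * z, z ~ N(0,1))
with a half-normal(0, 1) prior on tau.

Two extensions reuse the same machinery: a latent-outcome block for
measurement error in log HCC, and a joint body-fat imputation block with a
Student-t submodel (see :mod:`canicort.sensitivity`).

The joint log-density and its gradient are hand-differentiated (the HMC
sampler needs gradients); correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import digamma, gammaln

from . import skewnorm
from .cohort import TERM_COLUMNS, Cohort

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Prior for one named parameter: normal(mu, sigma) or exponential(lambda)."""

    parameter: str
    family: str  # "normal" | "exponential" | "half_normal" | "gamma"
    params: Tuple[float, ...]

    def __post_init__(self):
        n_expected = {"normal": 2, "exponential": 1, "half_normal": 1, "gamma": 2}
        if self.family not in n_expected:
            raise ValueError(f"unknown prior family {self.family!r}")
        if len(self.params) != n_expected[self.family]:
            raise ValueError(f"{self.family} prior needs {n_expected[self.family]} params")


def normal_prior(name, mu, sigma):
    return PriorSpec(name, "normal", (float(mu), float(sigma)))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one causal model.

    ``predictor`` is the causal exposure term; ``adjustment`` the backdoor
    adjustment terms (each term may expand to several dummy columns).
    ``coef_priors`` maps design-column names (and "intercept") to
    normal-prior (mean, sd) pairs.
    """

    name: str
    outcome: str  # "log_hcc" | "body_fat" (standardised internally)
    predictor: str
    adjustment: Tuple[str, ...]
    likelihood: str = "skew_normal"  # "normal" | "student_t" | "skew_normal"
    coef_priors: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    sigma_prior_rate: float = 1.0  # exponential(lambda) when sigma is fixed
    alpha_prior: Tuple[float, float] = (4.0, 2.0)
    group_sd_prior: float = 1.0  # half-normal scale on tau
    distributional_sigma: bool = False  # log sigma ~ gamma0 + gamma1*comorbidity
    nu_prior: Tuple[float, float] = (2.0, 0.1)  # gamma(shape, rate) on Student-t dof

    def __post_init__(self):
        if self.likelihood not in ("normal", "student_t", "skew_normal"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.predictor in self.adjustment:
            raise ValueError("adjustment set must exclude the causal predictor")
        if self.outcome in (self.predictor, *self.adjustment):
            raise ValueError("adjustment set and predictor must exclude the outcome")

    @property
    def terms(self) -> List[str]:
        return [self.predictor, *self.adjustment]

    @property
    def focal_columns(self) -> List[str]:
        return TERM_COLUMNS[self.predictor]


# ---------------------------------------------------------------------------
# likelihood kernels: log-density + partials, vectorised over observations
# ---------------------------------------------------------------------------


def normal_kernel(y, mu, sigma):
    t = (y - mu) / sigma
    lp = -np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * t * t
    dmu = t / sigma
    return lp, -dmu, dmu, (t * t - 1.0) / sigma, None


def student_t_kernel(y, mu, sigma, nu):
    t = (y - mu) / sigma
    q = nu + t * t
    lp = (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
        - 0.5 * (nu + 1.0) * np.log1p(t * t / nu)
    )
    dmu = (nu + 1.0) * t / (sigma * q)
    dsigma = -1.0 / sigma + (nu + 1.0) * t * t / (sigma * q)
    dnu = (
        0.5 * digamma((nu + 1.0) / 2.0)
        - 0.5 * digamma(nu / 2.0)
        - 0.5 / nu
        - 0.5 * np.log1p(t * t / nu)
        + (nu + 1.0) * t * t / (2.0 * nu * q)
    )
    return lp, -dmu, dmu, dsigma, dnu


def skew_normal_kernel(y, mu, sigma, alpha):
    lp, dy, dmu, dsigma, dalpha = skewnorm.logpdf_and_grads(y, mu, sigma, alpha)
    return lp, dy, dmu, dsigma, dalpha


# ---------------------------------------------------------------------------
# the joint model
# ---------------------------------------------------------------------------


@dataclass
class ImputationBlock:
    """Joint Student-t submodel for a partially-missing predictor column."""

    column: int  # index into X of the imputed predictor
    missing_rows: np.ndarray  # int indices of rows with the value missing
    X_sub: np.ndarray  # submodel design (n, q), complete
    sub_colnames: List[str]
    sub_prior_mean: np.ndarray
    sub_prior_sd: np.ndarray


class LinearModel:
    """Joint log-density over all parameters of one model fit.

    Flat parameter vector (unconstrained scale) with named blocks; see
    ``index``.  ``logp_grad`` returns the joint log-density (likelihood +
    priors + change-of-variable Jacobians) and its gradient.
    """

    def __init__(
        self,
        spec: ModelSpec,
        X: np.ndarray,
        colnames: List[str],
        y: np.ndarray,
        group_idx: np.ndarray,
        n_groups: int,
        sigma_covariate: Optional[np.ndarray] = None,
        measurement_error_sd: Optional[float] = None,
        imputation: Optional[ImputationBlock] = None,
    ):
        if np.isnan(X).any():
            raise ValueError(
                "design matrix contains missing values; drop incomplete rows "
                "for a complete-case fit or use the joint imputation model"
            )
        if np.isnan(y).any():
            raise ValueError("outcome contains missing values")
        self.spec = spec
        self.X = np.asarray(X, dtype=float)
        self.colnames = list(colnames)
        self.y = np.asarray(y, dtype=float)
        self.group_idx = np.asarray(group_idx)
        self.n_groups = int(n_groups)
        self.n, self.p = self.X.shape
        if spec.distributional_sigma:
            if sigma_covariate is None:
                raise ValueError("distributional sigma requires the comorbidity indicator")
            self.sigma_covariate = np.asarray(sigma_covariate, dtype=float)
        else:
            self.sigma_covariate = None
        self.me_sd = measurement_error_sd
        self.imputation = imputation
        if imputation is not None:
            self.X = self.X.copy()
            self.X[imputation.missing_rows, imputation.column] = 0.0

        # coefficient priors, in design-column order
        pm, ps = [], []
        for c in self.colnames:
            if c not in spec.coef_priors:
                raise ValueError(f"no prior given for coefficient {c!r}")
            m, s = spec.coef_priors[c]
            pm.append(m)
            ps.append(s)
        self.coef_prior_mean = np.array(pm)
        self.coef_prior_sd = np.array(ps)

        # flat parameter layout
        self.index: Dict[str, slice] = {}
        pos = 0

        def block(name, size):
            nonlocal pos
            self.index[name] = slice(pos, pos + size)
            pos += size

        block("b", self.p)
        block("z", self.n_groups)
        block("log_tau", 1)
        if spec.distributional_sigma:
            block("gamma", 2)
        else:
            block("log_sigma", 1)
        if spec.likelihood == "skew_normal":
            block("alpha", 1)
        elif spec.likelihood == "student_t":
            block("log_nu", 1)
        if self.me_sd is not None:
            block("y_lat", self.n)
        if imputation is not None:
            block("x_mis", len(imputation.missing_rows))
            block("c_sub", imputation.X_sub.shape[1])
            block("log_sigma_sub", 1)
            block("log_nu_sub", 1)
        self.dim = pos

    # -- parameter access ---------------------------------------------------

    def unpack(self, theta: np.ndarray) -> Dict[str, np.ndarray]:
        return {k: theta[..., s] for k, s in self.index.items()}

    def constrained(self, theta: np.ndarray) -> Dict[str, np.ndarray]:
        """Natural-scale view of a (…, dim) array of draws."""
        out = dict(self.unpack(theta))
        out["tau"] = np.exp(out.pop("log_tau"))
        if "log_sigma" in out:
            out["sigma"] = np.exp(out.pop("log_sigma"))
        if "log_nu" in out:
            out["nu"] = np.exp(out.pop("log_nu"))
        if "log_sigma_sub" in out:
            out["sigma_sub"] = np.exp(out.pop("log_sigma_sub"))
            out["nu_sub"] = np.exp(out.pop("log_nu_sub"))
        return out

    def sigma_obs(self, params: Dict[str, np.ndarray]) -> np.ndarray:
        """Per-observation residual SD for (…,) draws -> (…, n)."""
        if self.sigma_covariate is not None:
            g = np.asarray(params["gamma"])
            return np.exp(g[..., :1] + g[..., 1:2] * self.sigma_covariate)
        sigma = np.asarray(params["sigma"], dtype=float)
        if sigma.ndim and sigma.shape[-1] == 1:
            sigma = sigma[..., 0]
        return np.broadcast_to(sigma[..., None], sigma.shape + (self.n,))

    # -- joint density ------------------------------------------------------

    def logp_grad(self, theta: np.ndarray) -> Tuple[float, np.ndarray]:
        """Joint log-density and gradient; -inf (zero gradient) off-support.

        Extreme unconstrained values (e.g. from a divergent trajectory)
        overflow the exp transforms; those points get log-density -inf so
        the sampler rejects the trajectory instead of crashing.
        """
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp, grad = self._logp_grad_impl(theta)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros(self.dim)
        return lp, grad

    def _logp_grad_impl(self, theta: np.ndarray) -> Tuple[float, np.ndarray]:
        s = self.spec
        ix = self.index
        grad = np.zeros(self.dim)
        b = theta[ix["b"]]
        z = theta[ix["z"]]
        log_tau = theta[ix["log_tau"]][0]
        tau = np.exp(log_tau)

        X = self.X
        if self.imputation is not None:
            x_mis = theta[ix["x_mis"]]
            X = X.copy()
            X[self.imputation.missing_rows, self.imputation.column] = x_mis

        mu = X @ b + tau * z[self.group_idx]

        if s.distributional_sigma:
            g0, g1 = theta[ix["gamma"]]
            sigma = np.exp(g0 + g1 * self.sigma_covariate)
        else:
            log_sigma = theta[ix["log_sigma"]][0]
            sigma = np.full(self.n, np.exp(log_sigma))
        if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
            # exp over/underflow from an extreme trajectory: off-support
            return -np.inf, grad

        y_eff = theta[ix["y_lat"]] if self.me_sd is not None else self.y

        if s.likelihood == "normal":
            lp_i, dy, dmu, dsig, _ = normal_kernel(y_eff, mu, sigma)
        elif s.likelihood == "student_t":
            nu = np.exp(theta[ix["log_nu"]][0])
            lp_i, dy, dmu, dsig, dnu = student_t_kernel(y_eff, mu, sigma, nu)
        else:
            alpha = theta[ix["alpha"]][0]
            lp_i, dy, dmu, dsig, dal = skew_normal_kernel(y_eff, mu, sigma, alpha)

        lp = float(np.sum(lp_i))

        grad[ix["b"]] = X.T @ dmu
        grad[ix["z"]] = np.bincount(self.group_idx, weights=dmu, minlength=self.n_groups) * tau
        grad[ix["log_tau"]] = tau * float(np.dot(dmu, z[self.group_idx]))

        if s.distributional_sigma:
            grad[ix["gamma"]] = [
                float(np.sum(dsig * sigma)),
                float(np.sum(dsig * sigma * self.sigma_covariate)),
            ]
        else:
            grad[ix["log_sigma"]] = float(np.sum(dsig)) * sigma[0]

        if s.likelihood == "skew_normal":
            grad[ix["alpha"]] = float(np.sum(dal))
        elif s.likelihood == "student_t":
            grad[ix["log_nu"]] = float(np.sum(dnu)) * nu

        if self.imputation is not None:
            imp = self.imputation
            beta_imp = b[imp.column]
            grad[ix["x_mis"]] += beta_imp * dmu[imp.missing_rows]
            # Student-t submodel over the full predictor column
            x_all = X[:, imp.column]
            c = theta[ix["c_sub"]]
            sig_sub = np.exp(theta[ix["log_sigma_sub"]][0])
            nu_sub = np.exp(theta[ix["log_nu_sub"]][0])
            mu_sub = imp.X_sub @ c
            lp_s, dy_s, dmu_s, dsig_s, dnu_s = student_t_kernel(x_all, mu_sub, sig_sub, nu_sub)
            lp += float(np.sum(lp_s))
            grad[ix["x_mis"]] += dy_s[imp.missing_rows]
            grad[ix["c_sub"]] = imp.X_sub.T @ dmu_s
            grad[ix["log_sigma_sub"]] = float(np.sum(dsig_s)) * sig_sub + (-sig_sub + 1.0)
            a_nu, r_nu = s.nu_prior
            grad[ix["log_nu_sub"]] = (
                float(np.sum(dnu_s)) * nu_sub + (a_nu - 1.0) + 1.0 - r_nu * nu_sub
            )
            lp += -sig_sub + np.log(sig_sub)  # Exp(1) prior on sigma_sub + Jacobian
            # gamma(shape, rate) prior on nu_sub, sampled as log_nu_sub
            lp += (a_nu - 1.0) * np.log(nu_sub) - r_nu * nu_sub + np.log(nu_sub)
            # prior on submodel coefficients
            lp += float(
                np.sum(-0.5 * ((c - imp.sub_prior_mean) / imp.sub_prior_sd) ** 2)
            )
            grad[ix["c_sub"]] += -(c - imp.sub_prior_mean) / imp.sub_prior_sd**2

        if self.me_sd is not None:
            y_lat = theta[ix["y_lat"]]
            resid = (self.y - y_lat) / self.me_sd
            lp += float(np.sum(-0.5 * resid * resid - np.log(self.me_sd)))
            grad[ix["y_lat"]] = dy + resid / self.me_sd

        # ---- priors -------------------------------------------------------
        db = -(b - self.coef_prior_mean) / self.coef_prior_sd**2
        lp += float(np.sum(-0.5 * ((b - self.coef_prior_mean) / self.coef_prior_sd) ** 2))
        grad[ix["b"]] += db

        lp += float(np.sum(-0.5 * z * z))
        grad[ix["z"]] += -z

        # half-normal(0, s_tau) on tau, sampled as log_tau
        s_tau = s.group_sd_prior
        lp += -0.5 * (tau / s_tau) ** 2 + log_tau
        grad[ix["log_tau"]] += -(tau / s_tau) ** 2 + 1.0

        if s.distributional_sigma:
            gam = theta[ix["gamma"]]
            lp += float(np.sum(-0.5 * gam * gam))
            grad[ix["gamma"]] += -gam
        else:
            lam = s.sigma_prior_rate
            lp += -lam * sigma[0] + log_sigma
            grad[ix["log_sigma"]] += -lam * sigma[0] + 1.0

        if s.likelihood == "skew_normal":
            m_a, s_a = s.alpha_prior
            lp += -0.5 * ((alpha - m_a) / s_a) ** 2
            grad[ix["alpha"]] += -(alpha - m_a) / s_a**2
        elif s.likelihood == "student_t":
            a_nu, r_nu = s.nu_prior
            log_nu = theta[ix["log_nu"]][0]
            lp += (a_nu - 1.0) * log_nu - r_nu * nu + log_nu
            grad[ix["log_nu"]] += (a_nu - 1.0) + 1.0 - r_nu * nu

        return lp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    # -- initial values -----------------------------------------------------

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Prior-informed jittered starting point (per-chain)."""
        theta = np.zeros(self.dim)
        ix = self.index
        theta[ix["b"]] = self.coef_prior_mean + 0.2 * self.coef_prior_sd * rng.standard_normal(self.p)
        theta[ix["z"]] = 0.1 * rng.standard_normal(self.n_groups)
        theta[ix["log_tau"]] = math.log(0.3) + 0.2 * rng.standard_normal()
        if self.spec.distributional_sigma:
            theta[ix["gamma"]] = [math.log(0.8) + 0.2 * rng.standard_normal(), 0.1 * rng.standard_normal()]
        else:
            theta[ix["log_sigma"]] = math.log(0.8) + 0.2 * rng.standard_normal()
        if self.spec.likelihood == "skew_normal":
            theta[ix["alpha"]] = self.spec.alpha_prior[0] + 0.5 * rng.standard_normal()
        elif self.spec.likelihood == "student_t":
            theta[ix["log_nu"]] = math.log(10.0) + 0.2 * rng.standard_normal()
        if self.me_sd is not None:
            theta[ix["y_lat"]] = self.y + 0.1 * self.me_sd * rng.standard_normal(self.n)
        if self.imputation is not None:
            imp = self.imputation
            theta[ix["x_mis"]] = 0.2 * rng.standard_normal(len(imp.missing_rows))
            theta[ix["c_sub"]] = 0.1 * rng.standard_normal(imp.X_sub.shape[1])
            theta[ix["log_sigma_sub"]] = math.log(0.8)
            theta[ix["log_nu_sub"]] = math.log(10.0)
        return theta

    # -- prior simulation ---------------------------------------------------

    def draw_prior_params(self, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        s = self.spec
        out: Dict[str, np.ndarray] = {
            "b": rng.normal(self.coef_prior_mean, self.coef_prior_sd),
            "z": rng.standard_normal(self.n_groups),
            "tau": np.abs(rng.normal(0.0, s.group_sd_prior)),
        }
        if s.distributional_sigma:
            out["gamma"] = rng.normal(0.0, 1.0, size=2)
        else:
            out["sigma"] = rng.exponential(1.0 / s.sigma_prior_rate)
        if s.likelihood == "skew_normal":
            out["alpha"] = rng.normal(*s.alpha_prior)
        elif s.likelihood == "student_t":
            out["nu"] = rng.gamma(s.nu_prior[0], 1.0 / s.nu_prior[1])
        return out

    def simulate_outcome(self, params: Dict[str, np.ndarray], rng) -> np.ndarray:
        mu = self.X @ params["b"] + params["tau"] * params["z"][self.group_idx]
        if self.spec.distributional_sigma:
            g = params["gamma"]
            sigma = np.exp(g[0] + g[1] * self.sigma_covariate)
        else:
            sigma = np.full(self.n, params["sigma"])
        if self.spec.likelihood == "normal":
            return rng.normal(mu, sigma)
        if self.spec.likelihood == "student_t":
            return mu + sigma * rng.standard_t(params["nu"], size=self.n)
        return skewnorm.rvs(mu, sigma, params["alpha"], rng=rng)


# ---------------------------------------------------------------------------
# building models from a cohort
# ---------------------------------------------------------------------------


def build_model(
    spec: ModelSpec,
    cohort: Cohort,
    rows: Optional[np.ndarray] = None,
    measurement_error_sd: Optional[float] = None,
    imputation_terms: Optional[Sequence[str]] = None,
) -> LinearModel:
    """Assemble the joint log-density for ``spec`` on (a subset of) the cohort.

    ``rows``: boolean mask of rows to use (default all).  Missing values in
    the resulting design raise, pointing at the imputation model; use
    :func:`complete_case_rows` to subset first.  ``imputation_terms``
    activates the joint body-fat imputation submodel with those predictors.
    """
    cohort.prepare()
    df = cohort.df
    if rows is None:
        rows = np.ones(len(df), dtype=bool)
    sub = df.loc[rows]
    X_full, cols = cohort.design_matrix(spec.terms)
    X = X_full[rows]
    outcome_col = TERM_COLUMNS[spec.outcome][0]
    y = sub[outcome_col].to_numpy(dtype=float)

    gidx_full, dogs = cohort.group_index()
    gidx = gidx_full[rows]
    used = np.unique(gidx)
    remap = {g: i for i, g in enumerate(used)}
    gidx = np.array([remap[g] for g in gidx])
    n_groups = len(used)

    sigma_cov = None
    if spec.distributional_sigma:
        sigma_cov = sub["comorbidity_yes"].to_numpy(dtype=float)

    imputation = None
    if imputation_terms is not None:
        if spec.predictor != "body_fat":
            raise ValueError("joint imputation is defined for the body-fat predictor")
        col = cols.index("body_fat_z")
        missing_rows = np.flatnonzero(np.isnan(X[:, col]))
        Xs_full, sub_cols = cohort.design_matrix(list(imputation_terms))
        X_sub = Xs_full[rows]
        if np.isnan(X_sub).any():
            raise ValueError("imputation submodel predictors must be complete")
        prior_m = np.zeros(len(sub_cols))
        prior_s = np.ones(len(sub_cols))
        imputation = ImputationBlock(
            column=col,
            missing_rows=missing_rows,
            X_sub=X_sub,
            sub_colnames=sub_cols,
            sub_prior_mean=prior_m,
            sub_prior_sd=prior_s,
        )
        X = X.copy()
        X[missing_rows, col] = 0.0

    return LinearModel(
        spec,
        X,
        cols,
        y,
        gidx,
        n_groups,
        sigma_covariate=sigma_cov,
        measurement_error_sd=measurement_error_sd,
        imputation=imputation,
    )


def complete_case_rows(spec: ModelSpec, cohort: Cohort) -> np.ndarray:
    """Rows with no missing value in the outcome or any model term."""
    cohort.prepare()
    cols = [TERM_COLUMNS[spec.outcome][0]]
    for t in spec.terms:
        cols.extend(TERM_COLUMNS[t])
    return ~cohort.df[cols].isna().any(axis=1).to_numpy()


# ---------------------------------------------------------------------------
# the study's model table
# ---------------------------------------------------------------------------


def _breed_priors(sd):
    return {
        "breed_CKCS": (-0.070, sd),
        "breed_pug": (-0.075, sd),
        "breed_retriever": (-0.070, sd),
        "breed_other": (-0.075, sd),
    }


def study_models() -> Dict[str, ModelSpec]:
    """The eight causal model specifications used in the analysis.

    Outcome is standardised log HCC (standardised body fat for the
    reverse-causality model); adjustment sets come from the study DAG;
    priors are the tabulated weakly-regularising choices, with informed
    (slightly negative) priors for coat colour and breed and a slightly
    positive prior for comorbidity.  Models containing comorbidity model
    the residual scale as a function of comorbidity instead of a fixed
    sigma.
    """
    neutral_breed = {k: (0.0, 1.0) for k in TERM_COLUMNS["breed"]}
    specs = {
        "age": ModelSpec(
            name="age",
            outcome="log_hcc",
            predictor="age",
            adjustment=("breed",),
            coef_priors={"intercept": (0.0, 0.5), "age_z": (0.0, 0.5), **neutral_breed},
        ),
        "sex": ModelSpec(
            name="sex",
            outcome="log_hcc",
            predictor="sex",
            adjustment=(),
            coef_priors={"intercept": (0.0, 0.5), "sex_male": (0.0, 1.0)},
        ),
        "breed": ModelSpec(
            name="breed",
            outcome="log_hcc",
            predictor="breed",
            adjustment=(),
            coef_priors={"intercept": (0.0, 0.5), **_breed_priors(1.5)},
        ),
        "coat": ModelSpec(
            name="coat",
            outcome="log_hcc",
            predictor="coat",
            adjustment=("breed",),
            coef_priors={
                "intercept": (0.0, 0.5),
                "coat_mixed": (-0.070, 1.0),
                "coat_dark": (-0.075, 1.0),
                **neutral_breed,
            },
        ),
        "season": ModelSpec(
            name="season",
            outcome="log_hcc",
            predictor="season",
            adjustment=(),
            coef_priors={
                "intercept": (0.0, 0.5),
                "season_summer": (0.0, 1.0),
                "season_autumn": (0.0, 1.0),
                "season_winter": (0.0, 1.0),
            },
        ),
        "comorbidity": ModelSpec(
            name="comorbidity",
            outcome="log_hcc",
            predictor="comorbidity",
            adjustment=("age", "breed", "sex"),
            distributional_sigma=True,
            coef_priors={
                "intercept": (0.0, 0.5),
                "comorbidity_yes": (0.25, 1.0),
                "age_z": (0.0, 0.5),
                **neutral_breed,
                "sex_male": (0.0, 1.0),
            },
        ),
        "body_fat": ModelSpec(
            name="body_fat",
            outcome="log_hcc",
            predictor="body_fat",
            adjustment=("age", "breed", "sex", "comorbidity"),
            distributional_sigma=True,
            coef_priors={
                "intercept": (0.0, 0.5),
                "body_fat_z": (0.0, 0.5),
                "age_z": (0.0, 0.5),
                **neutral_breed,
                "sex_male": (0.0, 1.0),
                "comorbidity_yes": (0.25, 1.0),
            },
        ),
        "reverse_causality": ModelSpec(
            name="reverse_causality",
            outcome="body_fat",
            predictor="log_hcc",
            adjustment=("age", "breed", "sex", "comorbidity"),
            likelihood="normal",
            coef_priors={
                "intercept": (0.0, 1.0),
                "log_hcc_z": (0.0, 0.5),
                "age_z": (0.0, 1.0),
                **{k: (0.0, 2.0) for k in TERM_COLUMNS["breed"]},
                "sex_male": (0.0, 1.0),
                "comorbidity_yes": (0.0, 1.0),
            },
        ),
    }
    return specs


def study_model(name: str) -> ModelSpec:
    return study_models()[name]
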