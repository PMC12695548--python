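"""Fitting workflow: posterior sampling for a model spec on a cohort.

``fit_model`` is the single entry point used by the primary analyses and
all sensitivity refits.  The sampling defaults mirror the study protocol
(4 chains, 8,000 iterations of which 2,000 warmup); tests and examples use
reduced budgets, which the convergence checks still have to pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import arviz as az

from .cohort import Cohort
from .model import LinearModel, ModelSpec, build_model, complete_case_rows
from .sampler import PosteriorDraws, SamplingError, check_convergence, sample_posterior


@dataclass
class FitResult:
    """A fitted model: spec, design, posterior draws and diagnostics."""

    spec: ModelSpec
    model: LinearModel
    draws: PosteriorDraws
    cohort: Cohort

    # -- access -------------------------------------------------------------

    def param(self, name: str) -> np.ndarray:
        """Natural-scale draws of a block, shape (chain, draw, k) or (chain, draw)."""
        con = self.model.constrained(self.draws.theta)
        arr = con[name]
        if arr.shape[-1] == 1 and name not in ("b",):
            arr = arr[..., 0]
        return arr

    def coef(self, column: str) -> np.ndarray:
        """Pooled posterior draws of one design-column coefficient."""
        j = self.model.colnames.index(column)
        return self.draws.theta[:, :, self.model.index["b"]][:, :, j].reshape(-1)

    def coef_chains(self, column: str) -> np.ndarray:
        j = self.model.colnames.index(column)
        return self.draws.theta[:, :, self.model.index["b"]][:, :, j]

    @property
    def beta(self) -> np.ndarray:
        """Pooled draws of the causal coefficient (first focal column)."""
        return self.coef(self.spec.focal_columns[0])

    def mu_draws(self, X: Optional[np.ndarray] = None, include_group: bool = True) -> np.ndarray:
        """Draws of the linear predictor, shape (chain*draw, n_obs)."""
        m = self.model
        theta = self.draws.theta.reshape(-1, m.dim)
        b = theta[:, m.index["b"]]
        if X is None:
            X = m.X
            if m.imputation is not None:
                # fill imputed column with per-draw posterior values
                mu = np.empty((theta.shape[0], X.shape[0]))
                xm = theta[:, m.index["x_mis"]]
                for s in range(theta.shape[0]):
                    Xs = X.copy()
                    Xs[m.imputation.missing_rows, m.imputation.column] = xm[s]
                    mu[s] = Xs @ b[s]
                if include_group:
                    tau = np.exp(theta[:, m.index["log_tau"]])
                    z = theta[:, m.index["z"]]
                    mu += tau * z[:, m.group_idx]
                return mu
        mu = b @ X.T
        if include_group and X is m.X:
            tau = np.exp(theta[:, m.index["log_tau"]])
            z = theta[:, m.index["z"]]
            mu = mu + tau * z[:, m.group_idx]
        return mu

    def sigma_draws(self, n_obs: Optional[int] = None) -> np.ndarray:
        """Per-observation residual SD draws, shape (chain*draw, n_obs)."""
        m = self.model
        theta = self.draws.theta.reshape(-1, m.dim)
        if m.sigma_covariate is not None:
            g = theta[:, m.index["gamma"]]
            return np.exp(g[:, :1] + g[:, 1:2] * m.sigma_covariate)
        sigma = np.exp(theta[:, m.index["log_sigma"]])
        return np.broadcast_to(sigma, (theta.shape[0], n_obs or m.n)).copy()

    def alpha_draws(self) -> Optional[np.ndarray]:
        if self.spec.likelihood != "skew_normal":
            return None
        return self.draws.theta.reshape(-1, self.model.dim)[
            :, self.model.index["alpha"]
        ][:, 0]

    # -- diagnostics ---------------------------------------------------------

    def to_inference_data(self) -> az.InferenceData:
        m = self.model
        theta = self.draws.theta
        data: Dict[str, np.ndarray] = {}
        b = theta[:, :, m.index["b"]]
        for j, c in enumerate(m.colnames):
            data[f"b_{c}"] = b[:, :, j]
        data["tau"] = np.exp(theta[:, :, m.index["log_tau"]][:, :, 0])
        if m.spec.distributional_sigma:
            g = theta[:, :, m.index["gamma"]]
            data["gamma0"], data["gamma1"] = g[:, :, 0], g[:, :, 1]
        else:
            data["sigma"] = np.exp(theta[:, :, m.index["log_sigma"]][:, :, 0])
        if m.spec.likelihood == "skew_normal":
            data["alpha"] = theta[:, :, m.index["alpha"]][:, :, 0]
        elif m.spec.likelihood == "student_t":
            data["nu"] = np.exp(theta[:, :, m.index["log_nu"]][:, :, 0])
        data["z"] = theta[:, :, m.index["z"]]
        return az.convert_to_inference_data(data)

    def diagnostics(self) -> pd.DataFrame:
        """R-hat and bulk/tail ESS for every named parameter."""
        idata = self.to_inference_data()
        r = az.rhat(idata)
        eb = az.ess(idata, method="bulk")
        et = az.ess(idata, method="tail")
        rows = []
        for v in r.data_vars:
            rows.append(
                {
                    "parameter": v,
                    "rhat": float(np.max(r[v].values)),
                    "ess_bulk": float(np.min(eb[v].values)),
                    "ess_tail": float(np.min(et[v].values)),
                }
            )
        return pd.DataFrame(rows)

    def check(self, rhat_max: float = 1.01, ess_min: float = 400) -> None:
        bad = check_convergence(self.draws.theta, rhat_max=rhat_max, ess_min=ess_min)
        if bad:
            raise SamplingError(
                f"model {self.spec.name!r} failed diagnostics: " + "; ".join(bad)
            )


def fit_model(
    spec: ModelSpec,
    cohort: Cohort,
    chains: int = 4,
    iterations: int = 8000,
    warmup: int = 2000,
    seed: int = 0,
    rows: Optional[np.ndarray] = None,
    complete_case: bool = True,
    measurement_error_sd: Optional[float] = None,
    imputation_terms: Optional[Sequence[str]] = None,
    check: bool = False,
    target_accept: float = 0.85,
) -> FitResult:
    """Fit ``spec`` on ``cohort`` and return posterior draws.

    ``complete_case`` drops rows with missing model covariates (the primary
    body-fat fit); pass ``imputation_terms`` instead to keep all rows and
    impute missing body fat jointly.  ``check=True`` raises on failed
    convergence diagnostics rather than returning a suspect posterior.
    """
    if rows is None:
        rows = np.ones(len(cohort.df), dtype=bool)
    if imputation_terms is None and complete_case:
        rows = rows & complete_case_rows(spec, cohort)
    model = build_model(
        spec,
        cohort,
        rows=rows,
        measurement_error_sd=measurement_error_sd,
        imputation_terms=imputation_terms,
    )
    draws = sample_posterior(
        model.logp_grad,
        model.initial_point,
        model.dim,
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        seed=seed,
        target_accept=target_accept,
    )
    result = FitResult(spec=spec, model=model, draws=draws, cohort=cohort)
    if check:
        result.check()
    return result


def prior_predictive(
    spec: ModelSpec, cohort: Cohort, n_draws: int = 1000, seed: int = 0
) -> Dict[str, np.ndarray]:
    """Outcome replicates simulated from the priors only.

    Returns ``y_rep`` (n_draws, n_obs) and the prior draws of the causal
    coefficient(s) under ``beta``; used to confirm that pre-data
    predictions span the plausible outcome range.
    """
    rows = complete_case_rows(spec, cohort)
    model = build_model(spec, cohort, rows=rows)
    rng = np.random.default_rng(seed)
    y_rep = np.empty((n_draws, model.n))
    focal = [model.colnames.index(c) for c in spec.focal_columns]
    beta = np.empty((n_draws, len(focal)))
    for s in range(n_draws):
        params = model.draw_prior_params(rng)
        y_rep[s] = model.simulate_outcome(params, rng)
        beta[s] = params["b"][focal]
    return {"y_rep": y_rep, "beta": beta}
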