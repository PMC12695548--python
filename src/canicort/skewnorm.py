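"""Skew-normal distribution in the centered (mean / SD / shape) parameterisation.

The skew-normal generalises the normal with a shape parameter ``alpha``
(positive values give right skew; ``alpha = 0`` recovers the normal).  Its
textbook ("direct") parameters are location ``xi`` and scale ``omega``, but
regression priors are most naturally stated on the mean and standard
deviation of the outcome.  We therefore parameterise by ``(mu, sigma,
alpha)`` where ``mu`` and ``sigma`` are the mean and SD of the density, and
convert internally:

    delta  = alpha / sqrt(1 + alpha^2)
    omega  = sigma / sqrt(1 - (2/pi) * delta^2)
    xi     = mu - omega * delta * sqrt(2/pi)

All log-density functions also return analytic partial derivatives, which
the HMC sampler consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

_C = np.sqrt(2.0 / np.pi)
_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class SkewNormalParams:
    """Centered skew-normal parameters with derived direct parameters."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def delta(self) -> float:
        return float(self.alpha / np.hypot(1.0, self.alpha))

    @property
    def omega(self) -> float:
        return float(self.sigma / np.sqrt(1.0 - _C * _C * self.delta**2))

    @property
    def xi(self) -> float:
        return float(self.mu - self.omega * self.delta * _C)


def cp_to_dp(mu, sigma, alpha):
    """Centered (mean, SD, shape) -> direct (xi, omega, alpha)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    alpha = np.asarray(alpha, dtype=float)
    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    k = np.sqrt(1.0 - _C * _C * delta * delta)
    omega = sigma / k
    xi = np.asarray(mu, dtype=float) - omega * delta * _C
    return xi, omega, alpha


def logpdf(y, mu=0.0, sigma=1.0, alpha=0.0):
    """Log-density of the centered skew-normal at ``y`` (vectorised)."""
    y = np.asarray(y, dtype=float)
    xi, omega, alpha = cp_to_dp(mu, sigma, alpha)
    z = (y - xi) / omega
    return (
        _LOG2
        - np.log(omega)
        - 0.5 * (z * z + np.log(2.0 * np.pi))
        + log_ndtr(alpha * z)
    )


def logpdf_and_grads(y, mu, sigma, alpha):
    """Log-density plus partials w.r.t. ``y``, ``mu``, ``sigma``, ``alpha``.

    Everything broadcasts; returns ``(lp, dy, dmu, dsigma, dalpha)``.
    The partials account for the dependence of the direct parameters
    ``(xi, omega)`` on all three centered parameters.
    """
    y = np.asarray(y, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")

    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    ddelta_dalpha = (1.0 + alpha * alpha) ** -1.5
    k2 = 1.0 - _C * _C * delta * delta
    k = np.sqrt(k2)
    omega = sigma / k
    xi = np.asarray(mu, dtype=float) - omega * delta * _C

    z = (y - xi) / omega
    az = alpha * z
    # phi(az)/Phi(az), stable in the left tail
    log_phi_az = -0.5 * (az * az + np.log(2.0 * np.pi))
    r = np.exp(log_phi_az - log_ndtr(az))

    lp = _LOG2 - np.log(omega) - 0.5 * (z * z + np.log(2.0 * np.pi)) + log_ndtr(az)

    dl_dz = -z + alpha * r
    dl_dxi = -dl_dz / omega
    dl_domega = (-1.0 + z * z - az * r) / omega
    dl_dalpha_direct = r * z

    # chain rule through (xi, omega)(mu, sigma, delta)
    domega_ddelta = sigma * _C * _C * delta / (k2 * k)
    dxi_ddelta = -domega_ddelta * delta * _C - omega * _C

    dy = dl_dz / omega
    dmu = dl_dxi
    dsigma = dl_dxi * (-delta * _C / k) + dl_domega / k
    dalpha = dl_dalpha_direct + (dl_dxi * dxi_ddelta + dl_domega * domega_ddelta) * ddelta_dalpha
    return lp, dy, dmu, dsigma, dalpha


def rvs(mu, sigma, alpha, size=None, rng=None):
    """Draw from the centered skew-normal via the delta representation."""
    rng = np.random.default_rng(rng)
    xi, omega, alpha = cp_to_dp(mu, sigma, alpha)
    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    if size is None:
        size = np.broadcast(np.asarray(mu), np.asarray(sigma), np.asarray(alpha)).shape
    u0 = rng.standard_normal(size)
    u1 = rng.standard_normal(size)
    z = delta * np.abs(u0) + np.sqrt(1.0 - delta * delta) * u1
    return xi + omega * z
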