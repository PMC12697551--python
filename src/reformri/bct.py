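"""Box-Cox t (BCT) distribution.

Four-parameter distribution for positive-valued outcomes, the workhorse of
centile-based growth and brain charts.  A response ``Y > 0`` follows
``BCT(mu, sigma, nu, tau)`` when the transformed variable

    z = ((Y / mu)**nu - 1) / (nu * sigma)        (nu != 0)
    z = log(Y / mu) / sigma                      (nu == 0)

follows a Student-t distribution with ``tau`` degrees of freedom, truncated
so that Y stays positive.  ``mu`` is (approximately) the median, ``sigma``
acts as a coefficient of variation, ``nu`` controls skewness through the
Box-Cox power and ``tau`` controls tail heaviness.  For small ``sigma`` the
truncation mass is negligible and the median equals ``mu`` exactly in the
limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "BCTParams",
    "bct_cdf",
    "bct_quantile",
    "bct_logpdf",
    "bct_loglik",
]


@dataclass(frozen=True)
class BCTParams:
    """Parameters of a Box-Cox t distribution.

    mu : location (> 0), in phenotype units.
    sigma : scale (> 0), roughly a coefficient of variation.
    nu : skewness power (any real).
    tau : degrees of freedom (> 0).
    """

    mu: float
    sigma: float
    nu: float
    tau: float

    def __post_init__(self):
        if not (self.mu > 0 and self.sigma > 0 and self.tau > 0):
            raise DomainError(
                f"invalid BCT parameters: mu={self.mu}, sigma={self.sigma}, "
                f"tau={self.tau} (mu, sigma, tau must be positive)"
            )


def _z_transform(y, mu, sigma, nu):
    # ((y/mu)^nu - 1)/(nu*sigma) computed as expm1(nu*log(y/mu))/(nu*sigma),
    # which stays accurate as nu -> 0 and flows into log(y/mu)/sigma at nu=0
    y, mu, sigma = np.asarray(y, float), np.asarray(mu, float), np.asarray(sigma, float)
    logr = np.log(y / mu)
    if nu == 0:
        return logr / sigma
    return np.expm1(nu * logr) / (nu * sigma)


def _truncation_norm(sigma, nu, tau):
    """P(Y > 0) mass retained after the Box-Cox transform, i.e. the
    normalising constant F_T(1/(sigma*|nu|); tau).  Equals 1 when nu == 0."""
    if np.all(nu == 0):
        return np.ones_like(np.asarray(sigma, float))
    lim = 1.0 / (np.asarray(sigma, float) * np.abs(np.where(nu == 0, np.inf, nu)))
    return stats.t.cdf(lim, df=tau)


def bct_cdf(y, params: BCTParams | None = None, *, mu=None, sigma=None, nu=None, tau=None):
    """CDF of the BCT distribution, vectorised over ``y``."""
    if params is not None:
        mu, sigma, nu, tau = params.mu, params.sigma, params.nu, params.tau
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise DomainError("BCT is supported on y > 0")
    z = _z_transform(y, mu, sigma, nu)
    base = stats.t.cdf(z, df=tau)
    if np.all(np.asarray(nu) == 0):
        return base
    norm = _truncation_norm(sigma, nu, tau)
    lower_mass = np.where(
        np.asarray(nu) > 0,
        stats.t.cdf(-1.0 / (np.asarray(sigma, float) * np.abs(np.asarray(nu, float))), df=tau),
        0.0,
    )
    return (base - lower_mass) / norm


def bct_quantile(p, params: BCTParams | None = None, *, mu=None, sigma=None, nu=None, tau=None):
    """Quantile function (inverse CDF) of the BCT distribution.

    ``p`` may be a scalar or array in (0, 1).  Raises :class:`DomainError`
    when the Box-Cox back-transform argument ``1 + nu*sigma*z_p`` is
    nonpositive, which signals that the requested level is unreachable for
    these parameters.
    """
    if params is not None:
        mu, sigma, nu, tau = params.mu, params.sigma, params.nu, params.tau
    p = np.asarray(p, float)
    if np.any((p <= 0) | (p >= 1)):
        raise DomainError("quantile level must lie strictly inside (0, 1)")
    if nu == 0:
        z = stats.t.ppf(p, df=tau)
        out = mu * np.exp(sigma * z)
        return out.item() if out.ndim == 0 else out
    norm = _truncation_norm(sigma, nu, tau)
    if nu > 0:
        lower_mass = stats.t.cdf(-1.0 / (sigma * nu), df=tau)
        z = stats.t.ppf(p * norm + lower_mass, df=tau)
    else:
        z = stats.t.ppf(p * norm, df=tau)
    arg = nu * sigma * z
    if np.any(arg <= -1.0):
        raise DomainError(
            f"level p={p} unreachable for BCT(mu={mu}, sigma={sigma}, nu={nu}, "
            f"tau={tau}): Box-Cox argument nonpositive"
        )
    # (1 + nu*sigma*z)^(1/nu) via log1p, stable for nu near 0
    out = mu * np.exp(np.log1p(arg) / nu)
    return out.item() if out.ndim == 0 else out


def bct_logpdf(y, mu, sigma, nu, tau):
    """Elementwise log-density, including the Y>0 truncation normaliser."""
    y = np.asarray(y, float)
    mu = np.broadcast_to(np.asarray(mu, float), y.shape)
    sigma = np.broadcast_to(np.asarray(sigma, float), y.shape)
    if np.any(y <= 0):
        raise DomainError("BCT log-density requires y > 0")
    if np.any(mu <= 0) or np.any(sigma <= 0) or tau <= 0:
        raise DomainError("BCT log-density requires mu > 0, sigma > 0, tau > 0")
    z = _z_transform(y, mu, sigma, nu)
    # Jacobian of y -> z: y^(nu-1) / (mu^nu * sigma)
    logjac = (nu - 1.0) * np.log(y) - nu * np.log(mu) - np.log(sigma)
    logpdf = logjac + stats.t.logpdf(z, df=tau)
    if nu != 0:
        logpdf = logpdf - np.log(_truncation_norm(sigma, nu, tau))
    return logpdf


def bct_loglik(values, mu_vec, sigma_vec, nu, tau):
    """Total log-likelihood of ``values`` under per-observation mu/sigma.

    ``mu_vec`` and ``sigma_vec`` may be scalars or arrays conformable with
    ``values``; ``nu`` and ``tau`` are shared across observations.
    """
    return float(np.sum(bct_logpdf(values, mu_vec, sigma_vec, nu, tau)))
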