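"""Count likelihoods and the Gaussian KL term.

RNA counts are modeled as zero-inflated negative binomial (ZINB): a
mixture of a point mass at zero (weight ``pi``) and a negative binomial
with mean ``mu`` and inverse dispersion ``theta``. Binarized ATAC peaks
are Bernoulli. All functions are vectorized, broadcast, and evaluated in
log space so counts up to ~1e5 do not underflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["zinb_loglik", "nb_loglik", "bernoulli_loglik", "kl_gaussian"]

_P_EPS = 1e-7


def _validate_zinb(x, mu, theta, pi):
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must lie in [0, 1]")


def nb_loglik(x, mu, theta):
    """Negative binomial log pmf with mean ``mu`` and inverse dispersion ``theta``."""
    x = np.asarray(x, dtype=np.float64)
    mu, theta = np.asarray(mu, dtype=np.float64), np.asarray(theta, dtype=np.float64)
    log_theta_mu = np.log(theta + mu)
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (np.log(theta) - log_theta_mu)
        + x * (np.log(mu) - log_theta_mu)
    )


def zinb_loglik(x, mu, theta, pi):
    """Log-likelihood of the ZINB mixture: log[pi*1{x=0} + (1-pi)*NB(x; mu, theta)]."""
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    pi = np.asarray(pi, dtype=np.float64)
    _validate_zinb(x, mu, theta, pi)
    log_nb = nb_loglik(x, mu, theta)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    ll_nonzero = log_1mpi + log_nb
    ll_zero = np.logaddexp(log_pi, log_1mpi + log_nb)  # log_nb here is NB(0) where x==0
    out = np.where(x == 0, ll_zero, ll_nonzero)
    return out if out.ndim else float(out)


def bernoulli_loglik(x, p):
    """Bernoulli log-likelihood x*ln(p) + (1-x)*ln(1-p), p clamped away from {0,1}."""
    x = np.asarray(x, dtype=np.float64)
    p = np.clip(np.asarray(p, dtype=np.float64), _P_EPS, 1.0 - _P_EPS)
    out = x * np.log(p) + (1.0 - x) * np.log1p(-p)
    return out if out.ndim else float(out)


def kl_gaussian(mean, std):
    """KL( N(mean, diag(std^2)) || N(0, I) ), summed over latent dimensions.

    Closed form per dimension: 0.5*(mean^2 + std^2 - 1 - ln std^2).
    For 2-D input (cells x dims) returns one value per cell.
    """
    mean = np.asarray(mean, dtype=np.float64)
    std = np.asarray(std, dtype=np.float64)
    if np.any(std <= 0):
        raise ValueError("std must be positive")
    per_dim = 0.5 * (mean**2 + std**2 - 1.0 - 2.0 * np.log(std))
    out = per_dim.sum(axis=-1)
    return out if np.ndim(out) else float(out)
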