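"""Marginal zero-inflated normal fits and posterior-mean latent reconstruction.

Under the model, the transformed data for taxon j follow a mixture with a
discrete part (probability Phi_{mu_j, sigma2_j}(delta_j) of a structural
zero) and a continuous normal part above the threshold.  With a diagonal
working covariance, each taxon is fit separately:

* delta_hat_j is the minimum transformed value over the taxon's nonzero
  entries (the threshold cannot exceed any observed value);
* (mu_hat_j, sigma2_hat_j) maximize the mixed log-likelihood
      sum_{zeros} log Phi_{mu,sigma2}(delta_hat_j)
    + sum_{nonzeros} log f_{mu,sigma2}(y_tilde_ij);
* the latent layer is reconstructed by posterior mean: observed entries
  pass through unchanged, zeros are replaced by the mean of the normal
  truncated above at delta_hat_j.

This is the expectation step of a one-step EM whose maximization step is
the sparse structure inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr

from .transform import TransformedMatrix

__all__ = [
    "MarginalFit",
    "LatentMatrix",
    "estimate_delta",
    "fit_marginal",
    "fit_marginals",
    "posterior_mean",
    "truncated_normal_mean",
]

# Variance floor for taxa observed at too few nonzero values to estimate spread.
SIGMA2_FLOOR = 1e-4


@dataclass
class MarginalFit:
    """Per-taxon estimates (mu_hat, sigma2_hat, delta_hat) with diagnostics.

    delta_hat = -inf flags a taxon with no zeros (vacuous zero-inflation
    component).
    """

    mu_hat: np.ndarray
    sigma2_hat: np.ndarray
    delta_hat: np.ndarray
    converged: np.ndarray
    loglik: np.ndarray

    @property
    def p(self) -> int:
        return self.mu_hat.shape[0]


@dataclass
class LatentMatrix:
    """Posterior-mean reconstruction of the latent Gaussian layer."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def estimate_delta(transformed: TransformedMatrix) -> np.ndarray:
    """Per-taxon threshold estimate: min of transformed values over nonzeros.

    Taxa with no zero counts anywhere get -inf (no evidence of zero
    inflation).  A taxon that is zero in every sample is unidentifiable and
    raises.
    """
    vals = transformed.values
    mask = transformed.zero_mask
    if mask.all(axis=0).any():
        bad = np.nonzero(mask.all(axis=0))[0]
        raise ValueError(f"unobserved taxon; filter first (all-zero columns: {bad.tolist()})")
    masked = np.where(mask, np.inf, vals)
    delta = masked.min(axis=0)
    no_zero = ~mask.any(axis=0)
    delta[no_zero] = -np.inf
    return delta


def _negloglik(params: np.ndarray, nonzero: np.ndarray, n_zero: int, delta: float) -> float:
    mu, log_s2 = params
    s2 = np.exp(log_s2)
    sd = np.sqrt(s2)
    ll = -0.5 * len(nonzero) * (np.log(2 * np.pi * s2)) - 0.5 * np.sum((nonzero - mu) ** 2) / s2
    if n_zero > 0:
        ll += n_zero * log_ndtr((delta - mu) / sd)
    return -ll


def fit_marginal(column: np.ndarray, mask: np.ndarray, delta_hat: float):
    """Fit (mu, sigma2) of one taxon's zero-inflated normal marginal.

    Masked entries contribute log Phi_{mu,sigma2}(delta_hat); the rest the
    normal log-density.  Optimization is quasi-Newton on (mu, log sigma2)
    from moment starts; on failure, falls back to the moment estimates of
    the nonzero entries with converged=False.

    Returns (mu_hat, sigma2_hat, loglik, converged).
    """
    nonzero = np.asarray(column)[~np.asarray(mask)]
    n_zero = int(np.asarray(mask).sum())
    if len(nonzero) < 1:
        raise ValueError("taxon with no nonzero observations")
    if len(nonzero) + n_zero < 3:
        raise ValueError("need at least 3 observations")

    m0 = float(nonzero.mean())
    v0 = float(nonzero.var()) if len(nonzero) > 1 else SIGMA2_FLOOR
    v0 = max(v0, SIGMA2_FLOOR)

    if n_zero == 0 or not np.isfinite(delta_hat):
        # Pure Gaussian branch: the MLE is closed form.
        ll = -_negloglik(np.array([m0, np.log(v0)]), nonzero, 0, -np.inf)
        return m0, v0, ll, True

    res = optimize.minimize(
        _negloglik,
        x0=np.array([m0, np.log(v0)]),
        args=(nonzero, n_zero, delta_hat),
        method="L-BFGS-B",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if res.success and np.isfinite(res.fun):
        mu, log_s2 = res.x
        return float(mu), float(np.exp(log_s2)), float(-res.fun), True
    ll = -_negloglik(np.array([m0, np.log(v0)]), nonzero, n_zero, delta_hat)
    return m0, v0, float(ll), False


def fit_marginals(transformed: TransformedMatrix) -> MarginalFit:
    """Fit every taxon's marginal; see :func:`fit_marginal`."""
    delta = estimate_delta(transformed)
    p = transformed.p
    mu = np.empty(p)
    s2 = np.empty(p)
    ll = np.empty(p)
    conv = np.empty(p, dtype=bool)
    for j in range(p):
        mu[j], s2[j], ll[j], conv[j] = fit_marginal(
            transformed.values[:, j], transformed.zero_mask[:, j], delta[j]
        )
    s2 = np.maximum(s2, SIGMA2_FLOOR)
    return MarginalFit(mu_hat=mu, sigma2_hat=s2, delta_hat=delta, converged=conv, loglik=ll)


def truncated_normal_mean(mu, sigma, delta):
    """Mean of N(mu, sigma^2) truncated above at delta: E[z | z <= delta].

    Closed form mu - sigma * phi(alpha) / Phi(alpha) with
    alpha = (delta - mu) / sigma, evaluated through log densities so the
    Mills ratio stays finite far in the lower tail.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    delta = np.asarray(delta, dtype=float)
    neg_inf = np.isneginf(delta)
    alpha = np.where(neg_inf, 0.0, (delta - mu) / sigma)
    # phi(a)/Phi(a) via exp(logpdf - logcdf); log_ndtr is accurate for a << 0.
    ratio = np.exp(stats.norm.logpdf(alpha) - log_ndtr(alpha))
    out = mu - sigma * ratio
    out = np.where(np.isposinf(delta), mu, out)
    # delta = -inf means no truncation region at all; the value is undefined
    # and unused (such taxa have no masked entries)
    out = np.where(neg_inf, np.nan, out)
    return out if out.ndim else float(out)


def posterior_mean(transformed: TransformedMatrix, fit: MarginalFit) -> LatentMatrix:
    """Posterior-mean reconstruction of the latent layer.

    Nonzero entries are copied through unchanged; masked entries become the
    truncated-normal mean E[z | z <= delta_hat_j] under the fitted marginal.
    With a diagonal working covariance every entry is independent, so the
    computation is entrywise.
    """
    if fit.p != transformed.p:
        raise ValueError("fit dimension does not match transformed matrix")
    vals = transformed.values.copy()
    mask = transformed.zero_mask
    sd = np.sqrt(fit.sigma2_hat)
    imputed = truncated_normal_mean(fit.mu_hat, sd, fit.delta_hat)
    # Columns with delta_hat = -inf have no masked entries by construction.
    cols = np.broadcast_to(imputed, vals.shape)
    vals[mask] = cols[mask]
    return LatentMatrix(values=vals)
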