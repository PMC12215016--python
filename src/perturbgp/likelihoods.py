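"""Observation models: Gaussian with softplus variance link, zero-inflated
Poisson with softplus rate link, and the shared link functions.

The additive structure is the whole point: expression of gene p in cell i is
basal (a function of cell covariates K_i) plus, if the binary toggle z_ip is
on, a perturbation shift that depends only on the perturbation vector C_i.
The softplus link log(exp(.)+1) maps unconstrained sums to positive variances
(Gaussian) or rates (ZIP) while staying approximately linear for large
inputs, which preserves additivity away from zero.

All functions are written with ``autograd.numpy`` so they can sit inside the
reverse-mode-differentiated training objective unchanged.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.scipy.special import gammaln

__all__ = [
    "softplus",
    "sigmoid",
    "gaussian_loglik",
    "zip_logpmf",
    "zip_mean",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def softplus(x):
    """Overflow-safe softplus log(exp(x) + 1); works on scalars and arrays."""
    return anp.logaddexp(x, 0.0)


def sigmoid(x):
    """Numerically stable logistic function."""
    return anp.where(x >= 0, 1.0 / (1.0 + anp.exp(-anp.abs(x))),
                     anp.exp(-anp.abs(x)) / (1.0 + anp.exp(-anp.abs(x))))


def gaussian_loglik(x, basal_mean, basal_logscale, effect_mean=0.0,
                    effect_logscale=0.0, toggle=0.0):
    """Log-density of X ~ N(m + z*mu, softplus(lambda + z*gamma)).

    ``toggle`` may be a hard 0/1 indicator or a relaxed value in [0, 1];
    at toggle 0 this is exactly the basal log-density.
    Broadcasts over arrays elementwise.
    """
    mean = basal_mean + toggle * effect_mean
    var = softplus(basal_logscale + toggle * effect_logscale)
    return -0.5 * (_LOG_2PI + anp.log(var) + (x - mean) ** 2 / var)


def _zip_logpmf_core(x, rate, excess):
    """ZIP log-pmf for non-negative integer arrays (no validation).

    x = 0: log(pi + (1-pi) e^{-rate}) via log-sum-exp;
    x > 0: log(1-pi) + x log(rate) - rate - lgamma(x+1).
    """
    log1m = anp.log1p(-excess)
    zero_lp = anp.logaddexp(anp.log(excess + 1e-300), log1m - rate)
    pos_lp = log1m + x * anp.log(rate) - rate - gammaln(x + 1.0)
    return anp.where(x == 0, zero_lp, pos_lp)


def zip_logpmf(x, rate, excess):
    """Log-pmf of a zero-inflated Poisson ZIP(rate, pi).

    Parameters
    ----------
    x
        Non-negative integer count(s).
    rate
        Positive Poisson rate mu.
    excess
        Excess-zero probability pi in [0, 1).
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or not np.allclose(xa, np.round(xa)):
        raise ValueError("ZIP support is the non-negative integers")
    if np.any(np.asarray(rate) <= 0):
        raise ValueError("rate must be positive")
    ex = np.asarray(excess, dtype=float)
    if np.any(ex < 0) or np.any(ex >= 1):
        raise ValueError("excess-zero probability must lie in [0, 1)")
    out = _zip_logpmf_core(xa, anp.asarray(rate, dtype=float), ex)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else np.asarray(out)


def zip_mean(rate, excess):
    """Mean of ZIP(rate, pi): (1 - pi) * rate."""
    return (1.0 - excess) * rate
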