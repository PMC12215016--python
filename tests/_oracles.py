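"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's inference code paths: the marginal
likelihood is computed by tensor-product Gauss-Hermite quadrature with the
shared toggle marginalised as a two-component mixture of products.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import logsumexp

from perturbgp.kernels import prior_marginal
from perturbgp.likelihoods import softplus


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gaussian_log_marginal_quadrature(model, dataset, n_nodes: int = 40) -> float:
    """log p(X | C, K) for a 1-gene, 1-unique-perturbation Gaussian instance.

    Quadrature over (mu, gamma, eta) with the shared toggle z marginalised
    analytically: p(X | mu, gamma, eta) = sigma(eta) * prod_i N_on(x_i)
    + (1 - sigma(eta)) * prod_i N_off(x_i).
    """
    assert model.modality == "gaussian" and dataset.n_genes == 1
    U = np.unique(dataset.C, axis=0)
    assert U.shape[0] == 1 and np.any(U != 0), "need exactly one non-null perturbation"

    x = dataset.X[:, 0]
    m = model.basal_mean(dataset.K)[:, 0]
    lam = float(model.params["lam"][0])

    # prior marginals exactly as the model builds them (jitter included)
    specs = model.kernel_specs
    jit = model.config.jitter
    var_mu = float(prior_marginal(U, specs["mu"], jit).covariance[0, 0])
    var_ga = float(prior_marginal(U, specs["gamma"], jit).covariance[0, 0])
    pm_eta = prior_marginal(U, specs["eta"], jit)
    var_eta = float(pm_eta.covariance[0, 0])
    mean_eta = float(pm_eta.mean[0])

    nodes, weights = hermegauss(n_nodes)
    logw = np.log(weights / weights.sum())
    mu_g = nodes * np.sqrt(var_mu)
    ga_g = nodes * np.sqrt(var_ga)
    eta_g = mean_eta + nodes * np.sqrt(var_eta)

    var_off = float(softplus(lam))
    ll_off = float(np.sum(-0.5 * (np.log(2 * np.pi * var_off) + (x - m) ** 2 / var_off)))

    # ll_on over the (gamma, mu) grid
    var_on = np.asarray(softplus(lam + ga_g))  # (n_gamma,)
    sq_mu = np.sum((x[None, :] - m[None, :] - mu_g[:, None]) ** 2, axis=1)  # (n_mu,)
    n = x.size
    ll_on = (-0.5 * (n * np.log(2 * np.pi * var_on)[:, None] + sq_mu[None, :] / var_on[:, None]))

    s = _sigmoid(eta_g)  # (n_eta,)
    # log mixture per (eta, gamma, mu)
    log_mix = logsumexp(
        np.stack([
            np.log(s)[:, None, None] + ll_on[None, :, :],
            np.log1p(-s)[:, None, None] + np.full_like(ll_on, ll_off)[None, :, :],
        ]),
        axis=0,
    )
    total = logsumexp(
        log_mix + logw[:, None, None] + logw[None, :, None] + logw[None, None, :]
    )
    return float(total)
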