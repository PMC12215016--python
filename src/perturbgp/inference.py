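"""Amortised variational inference for the sparse additive GP model.

Generative model (per cell i, gene p):

* continuous modality:
  ``X_ip ~ N(m_p(K_i) + z_ip mu_p(C_i), softplus(lambda_p + z_ip gamma_p(C_i)))``
* count modality:
  ``X_ip ~ ZIP(softplus(m_p(K_i) + z_ip mu_p(C_i)), pi_p)``

with GP priors on mu_p, gamma_p, eta_p over perturbation space and
``z_ip ~ Bernoulli(sigma(eta_p(C_i)))`` shared by all cells carrying the same
perturbation.  Basal parameters ``m_p`` (a network of cell covariates) and
``lambda_p`` / ``pi_p`` are point-estimated.

The variational family is amortised: a single network maps a perturbation
vector to the Gaussian variational parameters of (mu, gamma, eta) for all P
genes at once (6P outputs; 4P in the count modality, which has no gamma),
and ``q(z | eta) = Bernoulli(sigma(eta))`` matches the generative
conditional, so the z term contributes no KL.  In the magnitude-constrained
mode the mu/gamma posteriors are rescaled by ||C||_2 (variances by
||C||_2^2) and the toggle is hard-gated by 1{||C||^2 != 0}, so controls
provably carry zero effect.

Training maximises a minibatch Monte-Carlo ELBO with the Bernoulli toggles
relaxed by binary Gumbel-softmax; toggles are sampled once per unique
perturbation per step.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.tracer import getval

from .data import PerturbDataset
from .kernels import DEFAULT_JITTER, KernelSpec, PriorMarginal, prior_marginal
from .likelihoods import _zip_logpmf_core, gaussian_loglik, sigmoid, softplus
from .networks import init_mlp, mlp_forward

__all__ = [
    "TrainingConfig",
    "VariationalState",
    "FittedModel",
    "default_kernel_specs",
    "build_amortiser",
    "variational_params",
    "sample_toggles",
    "elbo_estimate",
    "fit",
    "load_model",
]


@dataclass
class TrainingConfig:
    """Optimisation constants for ELBO maximisation.

    Defaults: Adam with step size 1e-3, batches of 256 cells, 200 epochs,
    one Monte-Carlo sample per step, Gumbel-softmax temperature 1.0
    (optionally annealed geometrically to ``final_temperature``).
    """

    batch_size: int = 256
    max_epochs: int = 200
    step_size: float = 1e-3
    mc_samples: int = 1
    gumbel_temperature: float = 1.0
    temperature_schedule: str = "constant"  # or "anneal"
    final_temperature: float = 0.5
    seed: int = 0
    kl_mode: str = "diagonal"  # or "joint"
    toggle_estimator: str = "analytic"  # or "relaxed" / "straight_through"
    magnitude_constrained: bool = True
    hidden_width: int = 128
    hidden_depth: int = 2
    jitter: float = DEFAULT_JITTER

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1 or self.mc_samples < 1:
            raise ValueError("batch_size, max_epochs and mc_samples must be >= 1")
        if self.step_size <= 0 or self.gumbel_temperature <= 0:
            raise ValueError("step_size and gumbel_temperature must be positive")
        if self.kl_mode not in ("joint", "diagonal"):
            raise ValueError("kl_mode must be 'joint' or 'diagonal'")
        if self.temperature_schedule not in ("constant", "anneal"):
            raise ValueError("temperature_schedule must be 'constant' or 'anneal'")
        if self.toggle_estimator not in ("analytic", "relaxed", "straight_through"):
            raise ValueError(
                "toggle_estimator must be 'analytic', 'relaxed' or 'straight_through'"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def default_kernel_specs(modality: str, constrained: bool) -> dict[str, KernelSpec]:
    """Recommended priors: nu=(1, 0.1), g_mu=g_gamma=0, g_eta=-3."""
    specs = {
        "mu": KernelSpec(1.0, 0.1, zero_passing=constrained, mean_const=0.0),
        "eta": KernelSpec(1.0, 0.1, zero_passing=False, mean_const=-3.0),
    }
    if modality == "gaussian":
        specs["gamma"] = KernelSpec(1.0, 0.1, zero_passing=constrained, mean_const=0.0)
    return specs


def build_amortiser(
    L: int,
    P: int,
    modality: str,
    width: int = 128,
    depth: int = 2,
    rng: np.random.Generator | None = None,
):
    """Amortisation network f: R^L -> R^{6P} (gaussian) or R^{4P} (zip)."""
    if L < 1 or P < 1:
        raise ValueError("L and P must be positive")
    out_dim = 6 * P if modality == "gaussian" else 4 * P
    rng = rng or np.random.default_rng(0)
    params = init_mlp(L, out_dim, width=width, depth=depth, rng=rng)
    # small final layer + moderate initial q variances (logvar -2)
    W, b = params["layers"][-1]
    W = W * 0.05
    b = b.copy()
    n_blocks = 3 if modality == "gaussian" else 2
    for k in range(n_blocks):
        b[(2 * k + 1) * P : (2 * k + 2) * P] = -2.0
    params["layers"][-1] = (W, b)
    return params


@dataclass
class VariationalState:
    """Per (unique perturbation, gene) Gaussian variational parameters.

    Means/stds are arrays of shape (M, P); ``gate`` is an (M, 1) indicator
    that is 0 exactly on all-zero perturbation rows under the constrained
    model.  ``logvar`` fields are the effective log-variances (including the
    ||C||^2 rescaling) and are only meaningful on gated-in rows.
    """

    mu_mean: np.ndarray
    mu_std: np.ndarray
    mu_logvar: np.ndarray
    eta_mean: np.ndarray
    eta_std: np.ndarray
    eta_logvar: np.ndarray
    gate: np.ndarray
    gamma_mean: np.ndarray | None = None
    gamma_std: np.ndarray | None = None
    gamma_logvar: np.ndarray | None = None

    @property
    def toggle_prob_plugin(self) -> np.ndarray:
        """Plug-in inclusion probability sigma(eta_mean), gated."""
        return np.asarray(sigmoid(self.eta_mean)) * np.asarray(self.gate)


def variational_params(
    amortiser_params,
    C: np.ndarray,
    magnitude_constrained: bool,
    P: int,
    modality: str,
) -> VariationalState:
    """Map perturbation vectors through the amortiser to variational laws.

    In constrained mode the mu/gamma means are multiplied by ||C||_2, the
    variances by ||C||_2^2, and the toggle law is gated by 1{||C||^2 != 0}.
    All operations are autograd-differentiable in ``amortiser_params``.
    """
    C = anp.atleast_2d(C)
    out = mlp_forward(amortiser_params, C)
    norms = np.linalg.norm(np.asarray(C, dtype=float), axis=1, keepdims=True)
    log_norms = np.where(norms > 0, np.log(np.maximum(norms, 1e-300)), 0.0)
    if magnitude_constrained:
        gate = (norms > 0).astype(float)
        scale, log_scale2 = norms, 2.0 * log_norms
    else:
        gate = np.ones_like(norms)
        scale, log_scale2 = np.ones_like(norms), np.zeros_like(norms)

    def block(k: int, scaled: bool):
        mean = out[:, k * P : (k + 1) * P]
        logvar = out[:, (k + 1) * P : (k + 2) * P]
        if scaled:
            mean = scale * mean
            std = scale * anp.exp(0.5 * logvar)
            logvar = logvar + log_scale2
        else:
            std = anp.exp(0.5 * logvar)
        return mean, std, logvar

    mu_mean, mu_std, mu_lv = block(0, True)
    if modality == "gaussian":
        g_mean, g_std, g_lv = block(2, True)
        e_mean, e_std, e_lv = block(4, False)
        return VariationalState(mu_mean, mu_std, mu_lv, e_mean, e_std, e_lv, gate,
                                g_mean, g_std, g_lv)
    e_mean, e_std, e_lv = block(2, False)
    return VariationalState(mu_mean, mu_std, mu_lv, e_mean, e_std, e_lv, gate)


def sample_toggles(
    toggle_logits: np.ndarray,
    temperature: float = 1.0,
    seed: int | np.random.Generator = 0,
    hard: bool = False,
    noise: np.ndarray | None = None,
):
    """Binary Gumbel-softmax toggle samples from logits eta.

    Relaxed samples are ``sigma((eta + G)/temperature)`` with logistic noise
    G (a difference of two Gumbels); hard samples threshold the same
    perturbed logits, i.e. exact Bernoulli(sigma(eta)) draws.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if noise is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        u = rng.uniform(1e-12, 1.0 - 1e-12, size=np.shape(toggle_logits))
        noise = np.log(u) - np.log1p(-u)
    shifted = toggle_logits + noise
    if hard:
        return (np.asarray(shifted) > 0).astype(float)
    return sigmoid(anp.asarray(shifted) / temperature)


# ---------------------------------------------------------------------------
# ELBO internals
# ---------------------------------------------------------------------------


def _kl_gaussian_block(mean, logvar, prior: PriorMarginal, kl_mode: str) -> float:
    """Sum over genes of KL(diag q over M points || joint/diagonal prior)."""
    var = anp.exp(logvar)
    D = mean - prior.mean[:, None]
    if kl_mode == "joint":
        trace = anp.sum(anp.diag(prior.cov_inv)[:, None] * var)
        quad = anp.sum(D * (prior.cov_inv @ D))
        n_gene = mean.shape[1]
        return 0.5 * (trace + quad - D.size + n_gene * prior.logdet - anp.sum(logvar))
    pv = prior.marginal_variances[:, None]
    return 0.5 * anp.sum((var + D**2) / pv - 1.0 + anp.log(pv) - logvar)


def _total_kl(state: VariationalState, static) -> float:
    rows = static["kl_rows"]
    kl = _kl_gaussian_block(
        state.mu_mean[rows], state.mu_logvar[rows], static["prior_mu"], static["kl_mode"]
    )
    kl = kl + _kl_gaussian_block(
        state.eta_mean[rows], state.eta_logvar[rows], static["prior_eta"], static["kl_mode"]
    )
    if state.gamma_mean is not None:
        kl = kl + _kl_gaussian_block(
            state.gamma_mean[rows], state.gamma_logvar[rows],
            static["prior_gamma"], static["kl_mode"],
        )
    return kl


def _draw_noise(rng: np.random.Generator, S: int, M: int, P: int, modality: str) -> dict:
    noise = {
        "mu": rng.standard_normal((S, M, P)),
        "eta": rng.standard_normal((S, M, P)),
    }
    u = rng.uniform(1e-12, 1.0 - 1e-12, size=(S, M, P))
    noise["logistic"] = np.log(u) - np.log1p(-u)
    if modality == "gaussian":
        noise["gamma"] = rng.standard_normal((S, M, P))
    return noise


def _batch_elbo(params, Xb, Kb, uinv, static, noise, temperature, relax=True,
                exact_z=False):
    """Monte-Carlo ELBO estimate, scaled to the full dataset.

    ``exact_z`` replaces toggle sampling by the analytic expectation of the
    log-likelihood over z ~ Bernoulli(sigma(eta)) given the eta draw —
    exact because z enters every cell-gene term as a binary factor.  This is
    the default training path (Rao-Blackwellised over z; unbiased, lower
    variance, and fully differentiable through sigma(eta)); the
    Gumbel-softmax relaxed/straight-through estimators are kept as options.
    """
    modality = static["modality"]
    state = variational_params(
        params["amort"], static["U"], static["constrained"], static["P"], modality
    )
    m = mlp_forward(params["basal"], Kb)
    S = noise["mu"].shape[0]
    total = 0.0
    for s in range(S):
        mu = state.mu_mean + state.mu_std * noise["mu"][s]
        eta = state.eta_mean + state.eta_std * noise["eta"][s]
        mu_c = mu[uinv]
        if exact_z:
            w = sigmoid(eta) * state.gate
            w_c = w[uinv]
            if modality == "gaussian":
                gam = state.gamma_mean + state.gamma_std * noise["gamma"][s]
                ll_on = gaussian_loglik(Xb, m, params["lam"][None, :], mu_c,
                                        gam[uinv], 1.0)
                ll_off = gaussian_loglik(Xb, m, params["lam"][None, :])
            else:
                pi = sigmoid(params["pi_logit"])[None, :]
                ll_on = _zip_logpmf_core(Xb, softplus(m + mu_c), pi)
                ll_off = _zip_logpmf_core(Xb, softplus(m), pi)
            ll = w_c * ll_on + (1.0 - w_c) * ll_off
        else:
            if relax:
                z = sigmoid((eta + noise["logistic"][s]) / temperature)
                if static.get("toggle_estimator") == "straight_through":
                    # hard samples in the forward pass, relaxed gradients in
                    # the backward pass: removes the E[z^2] < E[z] bias that
                    # a purely relaxed toggle imparts to the effect scale
                    hard = (getval(z) > 0.5).astype(float)
                    z = z + (hard - getval(z))
            else:
                z = (np.asarray(eta) + noise["logistic"][s] > 0).astype(float)
            z = z * state.gate
            z_c = z[uinv]
            if modality == "gaussian":
                gam = state.gamma_mean + state.gamma_std * noise["gamma"][s]
                ll = gaussian_loglik(Xb, m, params["lam"][None, :], mu_c,
                                     gam[uinv], z_c)
            else:
                pi = sigmoid(params["pi_logit"])[None, :]
                ll = _zip_logpmf_core(Xb, softplus(m + z_c * mu_c), pi)
        total = total + anp.sum(ll)
    loglik = total / S
    scale = static["N"] / Xb.shape[0]
    return scale * loglik - _total_kl(state, static)


# ---------------------------------------------------------------------------
# Fitted model container
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """Trained networks, basal parameters, priors and provenance."""

    modality: str  # 'gaussian' or 'zip'
    params: dict
    config: TrainingConfig
    kernel_specs: dict
    unique_perturbations: np.ndarray
    unique_counts: np.ndarray
    gene_names: list[str]
    perturbation_names: list[str]
    covariate_names: list[str]
    elbo_trace: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def P(self) -> int:
        return len(self.gene_names)

    @property
    def L(self) -> int:
        return self.unique_perturbations.shape[1]

    @property
    def constrained(self) -> bool:
        return self.config.magnitude_constrained

    # -- posterior access --------------------------------------------------
    def variational_state(self, C: np.ndarray) -> VariationalState:
        return variational_params(
            self.params["amort"], np.atleast_2d(C), self.constrained, self.P,
            self.modality,
        )

    def basal_mean(self, K: np.ndarray) -> np.ndarray:
        """Basal surface m_p(K); (n, P) for (n, D) covariates."""
        return np.asarray(mlp_forward(self.params["basal"], np.atleast_2d(K)))

    def posterior_draws(self, c: np.ndarray, n_mc: int, seed: int = 0) -> dict:
        """Joint draws (n_mc, P) of mu, (gamma,) eta and hard toggles z."""
        c = np.asarray(c, dtype=float).reshape(1, -1)
        if c.shape[1] != self.L:
            raise ValueError(f"perturbation vector has length {c.shape[1]}, expected {self.L}")
        st = self.variational_state(c)
        rng = np.random.default_rng(seed)
        mu = st.mu_mean + st.mu_std * rng.standard_normal((n_mc, self.P))
        eta = st.eta_mean + st.eta_std * rng.standard_normal((n_mc, self.P))
        z = (rng.uniform(size=(n_mc, self.P)) < np.asarray(sigmoid(eta))).astype(float)
        z = z * float(st.gate[0, 0])
        out = {"mu": np.asarray(mu), "eta": np.asarray(eta), "z": z,
               "gate": float(st.gate[0, 0])}
        if self.modality == "gaussian":
            out["gamma"] = np.asarray(
                st.gamma_mean + st.gamma_std * rng.standard_normal((n_mc, self.P))
            )
        return out

    # -- serialisation -----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {}
        for net in ("amort", "basal"):
            for i, (W, b) in enumerate(self.params[net]["layers"]):
                arrays[f"{net}_{i}_W"] = W
                arrays[f"{net}_{i}_b"] = b
            arrays[f"{net}_skip"] = self.params[net]["skip"]
        for key in ("lam", "pi_logit"):
            if key in self.params:
                arrays[key] = self.params[key]
        arrays["unique_perturbations"] = self.unique_perturbations
        arrays["unique_counts"] = self.unique_counts
        arrays["elbo_trace"] = np.asarray(self.elbo_trace, dtype=float)
        meta = {
            "modality": self.modality,
            "seed": int(self.seed),
            "config": self.config.to_dict(),
            "kernel_specs": {k: v.to_dict() for k, v in self.kernel_specs.items()},
            "gene_names": list(self.gene_names),
            "perturbation_names": list(self.perturbation_names),
            "covariate_names": list(self.covariate_names),
            "n_layers": {n: len(self.params[n]["layers"]) for n in ("amort", "basal")},
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)
        return path


def load_model(path: str | Path) -> FittedModel:
    """Load a model archive written by :meth:`FittedModel.save`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        params: dict = {}
        for net in ("amort", "basal"):
            params[net] = {
                "layers": [
                    (data[f"{net}_{i}_W"], data[f"{net}_{i}_b"])
                    for i in range(meta["n_layers"][net])
                ],
                "skip": data[f"{net}_skip"],
            }
        for key in ("lam", "pi_logit"):
            if key in data:
                params[key] = data[key]
        return FittedModel(
            modality=meta["modality"],
            params=params,
            config=TrainingConfig(**meta["config"]),
            kernel_specs={k: KernelSpec.from_dict(v) for k, v in meta["kernel_specs"].items()},
            unique_perturbations=data["unique_perturbations"],
            unique_counts=data["unique_counts"],
            gene_names=meta["gene_names"],
            perturbation_names=meta["perturbation_names"],
            covariate_names=meta["covariate_names"],
            elbo_trace=list(data["elbo_trace"]),
            seed=meta["seed"],
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _inv_softplus(y: np.ndarray) -> np.ndarray:
    y = np.maximum(y, 1e-6)
    return np.where(y > 30, y, np.log(np.expm1(y)))


def _build_static(train: PerturbDataset, config: TrainingConfig,
                  kernel_specs: dict, modality: str):
    U, uinv, counts = np.unique(train.C, axis=0, return_inverse=True,
                                return_counts=True)
    uinv = np.asarray(uinv).reshape(-1)
    norms = np.linalg.norm(U, axis=1)
    if config.magnitude_constrained:
        kl_rows = np.where(norms > 0)[0]
    else:
        kl_rows = np.arange(U.shape[0])
    if kl_rows.size == 0:
        kl_rows = np.arange(U.shape[0])  # all-control data: KL over origin only
    U_kl = U[kl_rows]
    static = {
        "U": U,
        "uinv": uinv,
        "counts": counts,
        "kl_rows": kl_rows,
        "N": train.n_cells,
        "P": train.n_genes,
        "modality": modality,
        "constrained": config.magnitude_constrained,
        "kl_mode": config.kl_mode,
        "toggle_estimator": config.toggle_estimator,
        "prior_mu": prior_marginal(U_kl, kernel_specs["mu"], config.jitter),
        "prior_eta": prior_marginal(U_kl, kernel_specs["eta"], config.jitter),
    }
    if modality == "gaussian":
        static["prior_gamma"] = prior_marginal(U_kl, kernel_specs["gamma"], config.jitter)
    return static


def _moment_effect_init(train: PerturbDataset, static, modality: str,
                        pi0: np.ndarray | None) -> np.ndarray:
    """Least-squares skip-weight initialisation of the mu-mean head.

    Per-perturbation group means against the control (or grand) mean give a
    moment estimate of the pre-link effect shift; seeding the amortiser's
    linear path with it avoids the cold start in which the sparsity prior
    collapses the toggles before the effects have grown.
    """
    U, uinv = static["U"], static["uinv"]
    norms = np.linalg.norm(U, axis=1)
    ctrl = norms == 0
    base = (train.X[np.isin(uinv, np.where(ctrl)[0])].mean(axis=0)
            if ctrl.any() else train.X.mean(axis=0))
    rows, targets = [], []
    for m in np.where(~ctrl)[0]:
        gm = train.X[uinv == m].mean(axis=0)
        if modality == "gaussian":
            delta = gm - base
        else:
            keep = 1.0 - (pi0 if pi0 is not None else 0.0)
            delta = _inv_softplus(np.maximum(gm / keep, 0.02)) - _inv_softplus(
                np.maximum(base / keep, 0.02)
            )
        rows.append(U[m] / norms[m] if static["constrained"] else U[m])
        targets.append(delta / norms[m] if static["constrained"] else delta)
    if not rows:
        return np.zeros((U.shape[1], train.n_genes))
    A = np.vstack(rows)
    T = np.vstack(targets)
    W, *_ = np.linalg.lstsq(A, T, rcond=None)
    return W


def _init_params(train: PerturbDataset, config: TrainingConfig, modality: str,
                 rng: np.random.Generator, static) -> dict:
    P, L, D = train.n_genes, train.n_perturbation_axes, train.n_covariates
    params = {
        "amort": build_amortiser(L, P, modality, config.hidden_width,
                                 config.hidden_depth, rng),
        "basal": init_mlp(D, P, config.hidden_width, config.hidden_depth, rng),
    }
    colmeans = train.X.mean(axis=0)
    W, b = params["basal"]["layers"][-1]
    pi0 = None
    if modality == "gaussian":
        b = colmeans.copy()
        params["lam"] = _inv_softplus(np.maximum(train.X.var(axis=0), 1e-3))
    else:
        zero_frac = np.mean(train.X == 0, axis=0)
        pi0 = np.clip(0.5 * zero_frac, 0.01, 0.5)
        params["pi_logit"] = np.log(pi0 / (1.0 - pi0))
        b = _inv_softplus(np.maximum(colmeans / (1.0 - pi0), 0.05))
    params["basal"]["layers"][-1] = (W, b)
    skip = params["amort"]["skip"].copy()
    skip[:, :P] = _moment_effect_init(train, static, modality, pi0)
    params["amort"]["skip"] = skip
    return params


def _temperature(config: TrainingConfig, epoch: int) -> float:
    if config.temperature_schedule == "constant" or config.max_epochs <= 1:
        return config.gumbel_temperature
    frac = epoch / (config.max_epochs - 1)
    return float(
        config.gumbel_temperature
        * (config.final_temperature / config.gumbel_temperature) ** frac
    )


def fit(train: PerturbDataset, config: TrainingConfig | None = None,
        kernel_specs: dict | None = None, verbose: bool = False) -> FittedModel:
    """Maximise the ELBO by stochastic gradient ascent; returns a FittedModel.

    Deterministic given ``config.seed`` (single-threaded numpy).  Raises on
    a diverging (non-finite) objective, reporting the last finite epoch.
    """
    config = config or TrainingConfig()
    modality = "gaussian" if train.modality == "continuous" else "zip"
    kernel_specs = kernel_specs or default_kernel_specs(
        modality, config.magnitude_constrained
    )
    rng = np.random.default_rng(config.seed)
    static = _build_static(train, config, kernel_specs, modality)
    params = _init_params(train, config, modality, rng, static)

    X, K, uinv = train.X, train.K, static["uinv"]
    N, P, M = train.n_cells, train.n_genes, static["U"].shape[0]
    B = min(config.batch_size, N)
    vag = value_and_grad(_batch_elbo)

    from .networks import flatten  # re-exported autograd flatten

    flat, unflatten = flatten(params)
    m_t = np.zeros_like(flat)
    v_t = np.zeros_like(flat)
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    t = 0
    trace: list[float] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(N)
        tau = _temperature(config, epoch)
        epoch_vals = []
        for start in range(0, N, B):
            idx = order[start : start + B]
            noise = _draw_noise(rng, config.mc_samples, M, P, modality)
            p = unflatten(flat)
            val, grad = vag(p, X[idx], K[idx], uinv[idx], static, noise, tau,
                            True, config.toggle_estimator == "analytic")
            if not np.isfinite(val):
                last = epoch - 1 if not epoch_vals else epoch
                raise RuntimeError(
                    f"ELBO became non-finite at epoch {epoch}; last finite epoch {last}"
                )
            g, _ = flatten(grad)
            g = -g  # ascend
            t += 1
            m_t = b1 * m_t + (1 - b1) * g
            v_t = b2 * v_t + (1 - b2) * g * g
            flat = flat - config.step_size * (m_t / (1 - b1**t)) / (
                np.sqrt(v_t / (1 - b2**t)) + eps_adam
            )
            epoch_vals.append(float(val))
        trace.append(float(np.mean(epoch_vals)))
        if verbose and (epoch % 20 == 0 or epoch == config.max_epochs - 1):
            print(f"epoch {epoch:4d}  elbo ~ {trace[-1]:.2f}  tau {tau:.3f}")

    return FittedModel(
        modality=modality,
        params=unflatten(flat),
        config=config,
        kernel_specs=kernel_specs,
        unique_perturbations=static["U"],
        unique_counts=static["counts"],
        gene_names=list(train.gene_names),
        perturbation_names=list(train.perturbation_names),
        covariate_names=list(train.covariate_names),
        elbo_trace=trace,
        seed=config.seed,
    )


def elbo_estimate(model: FittedModel, dataset: PerturbDataset, n_mc: int = 100,
                  seed: int = 0, exact_z: bool = True) -> tuple[float, float]:
    """Full-data ELBO estimate and its Monte-Carlo standard error.

    With ``exact_z`` the expectation over toggles given eta draws is taken
    analytically (the KL over z vanishes because q(z|eta) equals the prior
    conditional); otherwise hard toggle samples are used.
    """
    config = model.config
    static = _build_static(dataset, config, model.kernel_specs, model.modality)
    rng = np.random.default_rng(seed)
    M, P = static["U"].shape[0], dataset.n_genes
    vals = []
    for _ in range(n_mc):
        noise = _draw_noise(rng, 1, M, P, model.modality)
        v = _batch_elbo(model.params, dataset.X, dataset.K, static["uinv"],
                        static, noise, 1.0, relax=False, exact_z=exact_z)
        vals.append(float(v))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_mc))
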