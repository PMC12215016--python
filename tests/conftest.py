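"""Shared fixtures: toy datasets, quickly-fitted small models, and a factory
for fully synthetic fitted models whose posteriors are known exactly."""

from __future__ import annotations

import numpy as np
import pytest

from perturbgp import (
    PerturbDataset,
    SimConfig,
    TrainingConfig,
    fit,
    simulate_dataset,
    split_train_test,
)
from perturbgp.inference import FittedModel, default_kernel_specs


def _inv_softplus(y: float) -> float:
    return float(np.log(np.expm1(y)))


@pytest.fixture(scope="session")
def toy_dataset() -> PerturbDataset:
    """3 cells, 2 genes, 1 perturbation axis, 2 covariates."""
    return PerturbDataset(
        X=np.array([[1.0, 2.0], [0.0, 3.0], [4.0, 1.0]]),
        C=np.array([[1.0], [0.0], [1.0]]),
        K=np.array([[0.1, -0.2], [0.5, 0.0], [-0.3, 0.7]]),
        gene_names=["gA", "gB"],
        perturbation_names=["guide1"],
        covariate_names=["lib_size", "mt_percent"],
        modality="count",
    )


@pytest.fixture(scope="session")
def small_gaussian_sim():
    cfg = SimConfig(N=600, P=12, L=5, n_unique_perturbations=5, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_gaussian_fit(small_gaussian_sim):
    data, truth = small_gaussian_sim
    split = split_train_test(data, 0.2, 7)
    train = data.subset(split.train_rows)
    test = data.subset(split.test_rows)
    model = fit(train, TrainingConfig(max_epochs=80, seed=7))
    return model, truth, train, test


@pytest.fixture(scope="session")
def dosage_fit():
    cfg = SimConfig(N=800, P=8, L=2, D=2, dosage_mode=True,
                    dosage_levels=(0.25, 0.5, 1.0, 2.0, 4.0), seed=3)
    data, truth = simulate_dataset(cfg)
    model = fit(data, TrainingConfig(max_epochs=80, seed=3))
    return model, truth, data


@pytest.fixture(scope="session")
def make_synthetic_model():
    """Factory for a FittedModel with constant, exactly-known posteriors.

    The amortiser is a single linear layer with zero weights, so every
    perturbation vector maps to the same variational parameters (modulo the
    magnitude rescaling in constrained mode); the basal network outputs a
    constant per-gene vector.
    """

    def build(
        modality: str = "gaussian",
        P: int = 3,
        L: int = 2,
        mu_mean: float = 2.0,
        mu_logvar: float = -40.0,
        gamma_mean: float = 0.0,
        gamma_logvar: float = -40.0,
        eta_mean: float = 20.0,
        eta_logvar: float = -40.0,
        basal: float = 1.0,
        lam_value: float = _inv_softplus(1.0),
        pi_value: float = 0.2,
        constrained: bool = True,
        unique_perturbations: np.ndarray | None = None,
        D: int = 2,
    ) -> FittedModel:
        out_dim = 6 * P if modality == "gaussian" else 4 * P
        blocks = [mu_mean, mu_logvar]
        if modality == "gaussian":
            blocks += [gamma_mean, gamma_logvar]
        blocks += [eta_mean, eta_logvar]
        b = np.concatenate([np.full(P, v) for v in blocks])
        amort = {"layers": [(np.zeros((L, out_dim)), b)],
                 "skip": np.zeros((L, out_dim))}
        basal_net = {"layers": [(np.zeros((D, P)), np.full(P, float(basal)))],
                     "skip": np.zeros((D, P))}
        params = {"amort": amort, "basal": basal_net}
        if modality == "gaussian":
            params["lam"] = np.full(P, float(lam_value))
        else:
            params["pi_logit"] = np.full(P, float(np.log(pi_value / (1 - pi_value))))
        U = (np.eye(L) if unique_perturbations is None
             else np.asarray(unique_perturbations, dtype=float))
        config = TrainingConfig(magnitude_constrained=constrained)
        return FittedModel(
            modality=modality,
            params=params,
            config=config,
            kernel_specs=default_kernel_specs(modality, constrained),
            unique_perturbations=U,
            unique_counts=np.full(U.shape[0], 10),
            gene_names=[f"g{i}" for i in range(P)],
            perturbation_names=[f"p{j}" for j in range(L)],
            covariate_names=[f"k{d}" for d in range(D)],
            elbo_trace=[0.0],
            seed=0,
        )

    return build
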