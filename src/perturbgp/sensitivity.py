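"""Derivative-based dosage sensitivity.

For a dosage screen the fitted effect surface of gene i under perturbation
axis j is a smooth function of the dose x, D_ij(x).  Its sensitivity score
is the integral of the squared derivative over the observed dose range

    D_i^j = integral_{A_min}^{A_max} (d/dx D_ij(x))^2 dx,

which is zero exactly when the dose-response curve is constant and grows
with the magnitude of its rate of change, so it captures monotone and
non-monotone dose dependence alike.  The derivative is exact (reverse-mode
automatic differentiation through the amortisation network); the integral
uses trapezoidal quadrature on a uniform grid.

Whether a gene responds at all is treated as dose-independent: the
inclusion probability is evaluated once per (gene, axis) at a reference
dose and multiplies the differentiable mean-effect curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import elementwise_grad, grad

from .effects import inclusion_probability
from .inference import FittedModel
from .networks import mlp_forward

__all__ = [
    "SensitivityResult",
    "effect_curve",
    "effect_derivative",
    "sensitivity_metric",
    "sensitivity_table",
    "rank_sensitive_genes",
    "integrated_squared_derivative",
]

DEFAULT_N_GRID = 201


@dataclass(frozen=True)
class SensitivityResult:
    gene: str
    perturbation: str
    metric: float
    dose_min: float
    dose_max: float
    n_grid: int


def integrated_squared_derivative(fn, lo: float, hi: float,
                                  n_grid: int = DEFAULT_N_GRID) -> float:
    """Trapezoidal quadrature of (fn')^2 on [lo, hi].

    ``fn`` must map a 1-D autograd array elementwise; its derivative is
    obtained by automatic differentiation.
    """
    if hi <= lo:
        raise ValueError("degenerate dose range: need hi > lo")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    xs = np.linspace(lo, hi, n_grid)
    d = elementwise_grad(fn)(xs)
    return float(np.trapezoid(np.asarray(d) ** 2, xs))


def _check_indices(model: FittedModel, gene: int, axis: int) -> None:
    if not model.constrained:
        raise ValueError("dosage sensitivity requires the magnitude-constrained model")
    if not (0 <= gene < model.P):
        raise IndexError(f"gene index {gene} out of range [0, {model.P})")
    if not (0 <= axis < model.L):
        raise IndexError(f"perturbation axis {axis} out of range [0, {model.L})")


def observed_doses(model: FittedModel, axis: int) -> np.ndarray:
    """Distinct non-zero doses of ``axis`` among the training perturbations."""
    U = model.unique_perturbations
    on_axis = (U[:, axis] != 0) & (np.count_nonzero(U, axis=1) == 1)
    return np.unique(U[on_axis, axis])


def _reference_inclusion(model: FittedModel, gene: int, axis: int,
                         n_mc: int, seed: int) -> float:
    doses = observed_doses(model, axis)
    x_ref = float(doses.mean()) if doses.size else 1.0
    c = np.zeros(model.L)
    c[axis] = x_ref
    return float(inclusion_probability(model, c, n_mc=n_mc, seed=seed)[gene])


def _mean_curve_fn(model: FittedModel, gene: int, axis: int):
    """Vectorised x -> x * f^(gene)(x e_axis), autograd-differentiable."""
    e = np.zeros(model.L)
    e[axis] = 1.0
    amort = model.params["amort"]

    def fn(xs):
        xs = anp.atleast_1d(xs)
        C = xs[:, None] * e[None, :]
        out = mlp_forward(amort, C)
        return xs * out[:, gene]

    return fn


def effect_curve(model: FittedModel, gene: int, axis: int, x,
                 n_mc: int = 256, seed: int = 0):
    """Estimated perturbation effect of axis ``axis`` on ``gene`` at dose x.

    The curve is the dose-constant inclusion probability times the
    magnitude-scaled posterior mean of mu; it is continuous in x and exactly
    0 at x = 0.
    """
    _check_indices(model, gene, axis)
    p_ref = _reference_inclusion(model, gene, axis, n_mc, seed)
    fn = _mean_curve_fn(model, gene, axis)
    vals = p_ref * np.asarray(fn(np.atleast_1d(np.asarray(x, dtype=float))))
    return float(vals[0]) if np.ndim(x) == 0 else vals


def effect_derivative(model: FittedModel, gene: int, axis: int, x,
                      n_mc: int = 256, seed: int = 0):
    """Exact derivative d/dx of :func:`effect_curve` via autodiff."""
    _check_indices(model, gene, axis)
    p_ref = _reference_inclusion(model, gene, axis, n_mc, seed)
    fn = _mean_curve_fn(model, gene, axis)
    d = elementwise_grad(fn)(np.atleast_1d(np.asarray(x, dtype=float)))
    vals = p_ref * np.asarray(d)
    return float(vals[0]) if np.ndim(x) == 0 else vals


def sensitivity_metric(model: FittedModel, gene: int, axis: int,
                       n_grid: int = DEFAULT_N_GRID, n_mc: int = 256,
                       seed: int = 0) -> SensitivityResult:
    """Integral of the squared dose-derivative over the observed dose range."""
    _check_indices(model, gene, axis)
    doses = observed_doses(model, axis)
    if doses.size < 2:
        raise ValueError(
            f"axis {axis} has {doses.size} distinct observed dose(s); need >= 2"
        )
    lo, hi = float(doses.min()), float(doses.max())
    p_ref = _reference_inclusion(model, gene, axis, n_mc, seed)
    fn = _mean_curve_fn(model, gene, axis)
    metric = p_ref**2 * integrated_squared_derivative(fn, lo, hi, n_grid)
    return SensitivityResult(
        gene=model.gene_names[gene],
        perturbation=model.perturbation_names[axis],
        metric=metric,
        dose_min=lo,
        dose_max=hi,
        n_grid=n_grid,
    )


def sensitivity_table(model: FittedModel, axes=None, n_grid: int = DEFAULT_N_GRID,
                      n_mc: int = 256, seed: int = 0) -> pd.DataFrame:
    """Sensitivity metric for every gene on the given axes (default: all)."""
    axes = range(model.L) if axes is None else axes
    rows = []
    for j in axes:
        for i in range(model.P):
            r = sensitivity_metric(model, i, j, n_grid=n_grid, n_mc=n_mc, seed=seed)
            rows.append({
                "gene": r.gene,
                "perturbation": r.perturbation,
                "metric": r.metric,
                "log_metric": float(np.log(r.metric)) if r.metric > 0 else -np.inf,
                "dose_min": r.dose_min,
                "dose_max": r.dose_max,
                "n_grid": r.n_grid,
            })
    return pd.DataFrame(rows)


def rank_sensitive_genes(results: pd.DataFrame, per: str = "perturbation") -> pd.DataFrame:
    """Order by descending metric; ties broken alphabetically by gene."""
    if results.empty:
        raise ValueError("empty sensitivity table")
    if per == "perturbation":
        out = results.sort_values(
            ["perturbation", "metric", "gene"], ascending=[True, False, True]
        )
    elif per == "overall":
        out = results.sort_values(["metric", "gene"], ascending=[False, True])
    else:
        raise ValueError("per must be 'perturbation' or 'overall'")
    return out.reset_index(drop=True)
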