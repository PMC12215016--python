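"""Small feed-forward networks and a self-contained Adam optimiser.

Two networks drive the amortised inference: the amortiser maps a
perturbation vector (length L) to the per-gene variational parameters
(6P outputs for the Gaussian modality, 4P for ZIP), and the basal network
maps cell covariates (length D) to the P basal means.  Both are plain
tanh MLPs; parameters are nested lists of (W, b) arrays so that autograd
can differentiate straight through them.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.misc.flatten import flatten

__all__ = ["init_mlp", "mlp_forward", "adam"]


def init_mlp(
    in_dim: int,
    out_dim: int,
    width: int = 128,
    depth: int = 2,
    rng: np.random.Generator | None = None,
    scale: float | None = None,
):
    """Xavier-initialised MLP with a linear input->output skip path.

    Returns ``{"layers": [(W0, b0), ..., (Wk, bk)], "skip": W_skip}``.  The
    skip term lets the linear component of the target map (per-perturbation
    offsets for one-hot inputs, the affine part of a basal surface) be
    learned directly, with the tanh trunk fitting the nonlinear remainder.
    """
    rng = rng or np.random.default_rng(0)
    dims = [in_dim] + [width] * depth + [out_dim]
    layers = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        s = scale if scale is not None else np.sqrt(2.0 / (d_in + d_out))
        W = rng.standard_normal((d_in, d_out)) * s
        b = np.zeros(d_out)
        layers.append((W, b))
    return {"layers": layers, "skip": np.zeros((in_dim, out_dim))}


def mlp_forward(params, x):
    """Forward pass; tanh hidden layers, linear output plus linear skip."""
    h = x
    layers = params["layers"]
    for W, b in layers[:-1]:
        h = anp.tanh(h @ W + b)
    W, b = layers[-1]
    return h @ W + b + x @ params["skip"]


def adam(grad_fn, init_params, n_steps, step_size=1e-3, b1=0.9, b2=0.999,
         eps=1e-8, callback=None):
    """Adam ascent-agnostic minimiser over an arbitrary parameter pytree.

    ``grad_fn(params, step)`` returns the gradient pytree of the loss;
    ``callback(params, step)``, if given, is invoked after each update.
    """
    flat, unflatten = flatten(init_params)
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    for t in range(n_steps):
        g, _ = flatten(grad_fn(unflatten(flat), t))
        m = b1 * m + (1.0 - b1) * g
        v = b2 * v + (1.0 - b2) * g * g
        mhat = m / (1.0 - b1 ** (t + 1))
        vhat = v / (1.0 - b2 ** (t + 1))
        flat = flat - step_size * mhat / (np.sqrt(vhat) + eps)
        if callback is not None:
            callback(unflatten(flat), t)
    return unflatten(flat)
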