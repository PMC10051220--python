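"""Fidelity terms and regularizers as differentiable scalar functionals.

All reductions are sums (not means), so regularization weights are
comparable across image sizes only when stated.  Subgradient convention:
the derivative of |x| at 0 is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor
from .diffops import ComplexField, safe_sqrt

__all__ = ["LossWeights", "l2_fidelity", "l1_norm", "huber", "tv2d", "tv1d",
           "magnitude_excess_l1"]


@dataclass
class LossWeights:
    """Weights of the composite losses.

    lambda1 : weight of the sparsity (L1) or TV term, model-dependent.
    lambda2 : weight of the secondary regularizer (TV or kernel L1).
    delta   : Huber knee; residuals below it are penalized quadratically.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    delta: float = 1.0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.delta <= 0:
            raise ValueError("Huber delta must be positive")


def l2_fidelity(sim, data) -> Tensor:
    """Sum of squared elementwise differences ||sim - data||^2."""
    sim, data = astensor(sim), astensor(data)
    if sim.shape != data.shape:
        raise ValueError(f"shape mismatch: {sim.shape} vs {data.shape}")
    d = sim - data
    return (d * d).sum()


def l1_norm(x) -> Tensor:
    """Sum of absolute values; for a complex duplet, sum of moduli."""
    if isinstance(x, ComplexField):
        return x.modulus().sum()
    return ad.absolute(astensor(x)).sum()


def huber(sim, data, delta: float = 1.0) -> Tensor:
    """Summed symmetric Huber penalty of the residual ``sim - data``:
    0.5 r^2 where |r| < delta, delta (|r| - delta/2) elsewhere; continuous
    and continuously differentiable at the knee."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    sim, data = astensor(sim), astensor(data)
    if sim.shape != data.shape:
        raise ValueError(f"shape mismatch: {sim.shape} vs {data.shape}")
    r = sim - data
    a = ad.absolute(r)
    quad = 0.5 * (r * r)
    lin = delta * (a - 0.5 * delta)
    return ad.where(np.abs(r.value) < delta, quad, lin).sum()


def tv2d(image, epsilon: float = 1e-8, printed_form: bool = False) -> Tensor:
    """Isotropic total variation of a 2D image.

    Sum over interior pixels of sqrt(epsilon + dr^2 + dc^2) - sqrt(epsilon)
    with forward row/column differences: ``epsilon`` keeps the gradient
    finite in flat regions while the subtraction keeps the value exactly
    zero on constants; with ``epsilon=0`` the value is the exact TV.  The
    ``printed_form`` switch replaces the column *difference* by a column
    *sum* (a variant that appears in print but is not a variation measure).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    image = astensor(image)
    if image.ndim != 2:
        raise ValueError("tv2d expects a 2D image")
    dr = image[1:, :-1] - image[:-1, :-1]
    if printed_form:
        dc = image[:-1, 1:] + image[:-1, :-1]
    else:
        dc = image[:-1, 1:] - image[:-1, :-1]
    mag2 = dr * dr + dc * dc + epsilon
    if epsilon == 0.0:
        return safe_sqrt(mag2).sum()
    return (ad.sqrt(mag2) - np.sqrt(epsilon)).sum()


def tv1d(vector) -> Tensor:
    """Sum of absolute successive differences of a 1D (serialized) array."""
    vector = astensor(vector)
    v = vector.ravel()
    if v.size < 2:
        raise ValueError("tv1d needs at least 2 samples")
    return ad.absolute(v[1:] - v[:-1]).sum()


def magnitude_excess_l1(field: ComplexField) -> Tensor:
    """Energy-conservation penalty for a transmission function: the sum of
    moduli over exactly those elements whose modulus exceeds 1.  Elements at
    or below unit magnitude contribute neither value nor gradient (the
    selection set is held fixed, as with boolean fancy indexing)."""
    mod = field.modulus()
    sel = mod.value > 1.0
    return ad.where(sel, mod, ad.constant(np.zeros_like(mod.value))).sum()
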