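"""Compressive-sensing reconstruction of sparsely sampled scan images.

The measured image ``y`` is a sparsely sampled raster scan (pixels outside
the sampling mask are zero-filled).  The latent unknown is the coefficient
array ``x`` of the image in a sparsifying basis (2D DCT by default, wavelet
optionally); reconstruction minimizes

    L(x) = || Phi Psi x - y ||_2^2 + lambda1 ||x||_1

where ``Psi`` is the synthesis transform and ``Phi`` the sampling operator.
A background-corrected variant co-estimates a slowly varying multiplicative
field ``w`` (reciprocal beam-intensity gain) with a 1D total-variation
penalty on its raster serialization:

    L(x, w) = || Phi Psi x - y * Phi w ||_2^2 + lambda1 ||x||_1
              + lambda2 TV1(w).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor
from .diffops import SamplingMask, WaveletBasis, apply_mask, idct2
from .losses import LossWeights, l1_norm, l2_fidelity, tv1d
from .model import InverseModel, ReconstructionResults
from .solver import OptimResult, minimize

__all__ = ["CompressiveSensingModel", "CSResults", "cs_loss",
           "cs_background_loss", "reconstruct_cs",
           "reconstruct_cs_background", "default_weights"]

_SOFTPLUS_INV_1 = float(np.log(np.expm1(1.0)))  # u with softplus(u) = 1
_W_FLOOR = 1e-6


def default_weights(y: np.ndarray) -> LossWeights:
    """Data-scaled defaults: lambda1 = 1e-3 max|y|, lambda2 = 1e-2 max|y|."""
    scale = float(np.max(np.abs(y))) or 1.0
    return LossWeights(lambda1=1e-3 * scale, lambda2=1e-2 * scale)


def _synthesize(x, basis: str, shape, levels: int):
    if basis == "dct":
        return idct2(astensor(x))
    if basis == "wavelet":
        return WaveletBasis(shape, levels=levels).synthesize(x)
    raise ValueError(f"unknown basis {basis!r}")


def cs_loss(x, mask: SamplingMask, y: np.ndarray, weights: LossWeights,
            basis: str = "dct", levels: int = 3) -> Tensor:
    """Sparse-sampling data fidelity plus L1 sparsity of the coefficients."""
    y = np.asarray(y, dtype=np.float64)
    img = _synthesize(x, basis, y.shape, levels)
    sim = apply_mask(img, mask)
    return l2_fidelity(sim, y) + weights.lambda1 * l1_norm(x)


def cs_background_loss(x, w, mask: SamplingMask, y: np.ndarray,
                       weights: LossWeights, basis: str = "dct",
                       levels: int = 3, model_side: bool = False) -> Tensor:
    """Background-corrected loss.

    The default residual follows the data-side form ``Phi Psi x - y Phi w``
    (``w`` multiplies the measured data, so at the optimum it approximates
    the reciprocal of the beam gain).  ``model_side=True`` switches to the
    physically motivated alternative ``Phi(Psi x * w) - y``.
    """
    y = np.asarray(y, dtype=np.float64)
    img = _synthesize(x, basis, y.shape, levels)
    w = astensor(w)
    if model_side:
        residual_sim = apply_mask(img * w, mask)
        data_term = l2_fidelity(residual_sim, y)
    else:
        data_term = l2_fidelity(apply_mask(img, mask),
                                ad.constant(y) * apply_mask(w, mask))
    return (data_term + weights.lambda1 * l1_norm(x)
            + weights.lambda2 * tv1d(w.ravel()))


class CompressiveSensingModel(InverseModel):
    """Gradient-based CS reconstruction model.

    Parameters
    ----------
    y : measured image, zero-filled outside the mask support.
    mask : boolean :class:`SamplingMask` (or plain boolean array).
    basis : ``"dct"`` (default) or ``"wavelet"``.
    weights : loss weights; data-scaled defaults if omitted.
    background : co-estimate the slowly varying intensity field ``w``.
    model_side : place ``w`` on the model side of the residual instead of
        the data side.
    """

    def __init__(self, y: np.ndarray, mask, basis: str = "dct",
                 weights: LossWeights | None = None, levels: int = 3,
                 background: bool = False, model_side: bool = False):
        self.y = np.asarray(y, dtype=np.float64)
        if not isinstance(mask, SamplingMask):
            mask = SamplingMask(mask, scheme="custom")
        if mask.shape != self.y.shape:
            raise ValueError("mask and image shapes differ")
        if mask.fraction <= 0:
            raise ValueError("mask fraction must be positive")
        self.mask = mask
        self.basis = basis
        self.levels = levels
        self.weights = weights if weights is not None else default_weights(y)
        self.background = background
        self.model_side = model_side
        if basis == "wavelet":
            self._n_coeffs = WaveletBasis(self.y.shape, levels=levels).n_coeffs
        else:
            self._n_coeffs = self.y.size

    # -- solver plumbing ----------------------------------------------------
    def _x0(self) -> np.ndarray:
        if self.basis == "wavelet":
            return np.zeros(self._n_coeffs)
        return np.zeros_like(self.y)

    def loss_closure(self):
        w_mask = self.mask

        if not self.background:
            def closure(params):
                return cs_loss(params["x"], w_mask, self.y, self.weights,
                               basis=self.basis, levels=self.levels)
            return closure, {"x": self._x0()}

        def closure(params):
            w = ad.softplus(params["u"]) + _W_FLOOR
            return cs_background_loss(params["x"], w, w_mask, self.y,
                                      self.weights, basis=self.basis,
                                      levels=self.levels,
                                      model_side=self.model_side)
        u0 = np.full(self.y.shape, _SOFTPLUS_INV_1)
        return closure, {"x": self._x0(), "u": u0}

    def synthesize(self, x: np.ndarray) -> np.ndarray:
        return _synthesize(astensor(x), self.basis, self.y.shape,
                           self.levels).value

    def fit(self, method: str = "quasi-newton", max_iter: int = 500,
            tol: float = 1e-9, seed: int = 0) -> "CSResults":
        closure, params = self.loss_closure()
        res = minimize(closure, params, method=method, max_iter=max_iter,
                       tol=tol, seed=seed)
        return CSResults(self, res)


class CSResults(ReconstructionResults):
    """Reconstruction, coefficients and (optionally) the background field.

    The joint scale ambiguity of the background-corrected model is resolved
    for reporting by normalizing ``median(w) = 1`` (the image is rescaled
    accordingly).
    """

    def __init__(self, model: CompressiveSensingModel, optim: OptimResult):
        super().__init__(model, optim)
        self.coefficients = optim.params["x"]
        image = model.synthesize(self.coefficients)
        if model.background:
            u = optim.params["u"]
            w = np.logaddexp(0.0, u) + _W_FLOOR  # softplus reparameterization
            scale = float(np.median(w)) or 1.0
            self.background_w = w / scale
            self.image = image / scale
            with np.errstate(divide="ignore"):
                self.gain = 1.0 / self.background_w
        else:
            self.background_w = None
            self.gain = None
            self.image = image

    def _estimate_rows(self):
        rows = [("Sampling fraction", f"{self.model.mask.fraction:.3f}"),
                ("Basis", self.model.basis)]
        if self.background_w is not None:
            rows.append(("Background range",
                         f"[{self.background_w.min():.3f}, "
                         f"{self.background_w.max():.3f}]"))
        return rows


# -- functional interface -----------------------------------------------------

def reconstruct_cs(y: np.ndarray, mask, weights: LossWeights | None = None,
                   basis: str = "dct", method: str = "quasi-newton",
                   max_iter: int = 500, tol: float = 1e-9, seed: int = 0):
    """Minimize the CS loss from x0 = 0; returns (image, OptimResult)."""
    model = CompressiveSensingModel(y, mask, basis=basis, weights=weights)
    res = model.fit(method=method, max_iter=max_iter, tol=tol, seed=seed)
    return res.image, res.optim_result


def reconstruct_cs_background(y: np.ndarray, mask,
                              weights: LossWeights | None = None,
                              basis: str = "dct",
                              method: str = "quasi-newton",
                              max_iter: int = 800, tol: float = 1e-9,
                              seed: int = 0, model_side: bool = False):
    """Joint (x, w) minimization from x0 = 0, w0 = 1; returns the de-striped
    image, the estimated background field and the trace."""
    model = CompressiveSensingModel(y, mask, basis=basis, weights=weights,
                                    background=True, model_side=model_side)
    res = model.fit(method=method, max_iter=max_iter, tol=tol, seed=seed)
    return res.image, res.background_w, res.optim_result
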