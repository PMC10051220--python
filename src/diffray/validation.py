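"""Gradient validation harness: backend versus finite differences.

Builds small random instances of every composite loss in the package and
compares the AD-engine gradients against the central finite-difference
oracle.  This operationalizes the framework's core correctness claim: the
automatically derived gradients equal the numerical ones for every forward
model, including the geometry parameters (shifts, tilt, scan positions,
propagation distance).
"""

from __future__ import annotations

import numpy as np

from .cs import cs_background_loss, cs_loss
from .diffops import ComplexField, PropagationSpec, SamplingMask
from .losses import LossWeights
from .ptycho import PtychoDataset, ptycho_loss
from .sisr import DegradationSpec, sisr_loss
from .solver import verify_gradients
from .synth import make_mask
from .tomo import ProjectionGeometry, ProjectionStack, tomo_loss, \
    tomo_loss_aligned

__all__ = ["gradient_checks", "toy_closures"]


def _cs_instance(rng):
    n = 8
    mask = make_mask((n, n), 0.5, "uniform-random",
                     seed=int(rng.integers(2 ** 31)))
    y = np.where(mask.values, rng.standard_normal((n, n)), 0.0)
    weights = LossWeights(lambda1=0.05)

    def closure(p):
        return cs_loss(p["x"], mask, y, weights)

    return closure, {"x": rng.standard_normal((n, n)) * 0.3}


def _cs_background_instance(rng):
    n = 8
    mask = make_mask((n, n), 0.6, "uniform-random",
                     seed=int(rng.integers(2 ** 31)))
    y = np.where(mask.values, rng.standard_normal((n, n)) + 2.0, 0.0)
    weights = LossWeights(lambda1=0.05, lambda2=0.05)

    def closure(p):
        return cs_background_loss(p["x"], p["w"], mask, y, weights)

    return closure, {"x": rng.standard_normal((n, n)) * 0.3,
                     "w": 1.0 + 0.1 * rng.standard_normal((n, n))}


def _sisr_instance(rng):
    n, k, f = 8, 3, 2
    spec = DegradationSpec(factor=f, kernel_size=k)
    y = rng.standard_normal((n // f, n // f))
    weights = LossWeights(lambda1=0.05, lambda2=0.05, delta=1.0)

    def closure(p):
        return sisr_loss(p["x"], p["h"], y, weights, spec)

    return closure, {"x": rng.standard_normal((n, n)) * 0.5,
                     "h": rng.standard_normal((k, k)) * 0.3}


def _tomo_geometry(rng, n=8, depth=1, n_angles=4):
    angles = np.sort(rng.uniform(0.0, 120.0, size=n_angles))
    return ProjectionGeometry(angles_deg=angles,
                              volume_shape=(depth, n, n))


def _tomo_instance(rng):
    geometry = _tomo_geometry(rng)
    images = rng.standard_normal(
        (geometry.n_projections,) + geometry.detector_shape)
    data = ProjectionStack(images, geometry)
    weights = LossWeights(lambda1=0.02, lambda2=0.02)
    from .diffops import WaveletBasis
    nc = WaveletBasis((8, 8), levels=2).n_coeffs

    def closure(p):
        return tomo_loss(p["x"], data, weights, levels=2)

    return closure, {"x": rng.standard_normal((1, nc)) * 0.2}


def _tomo_aligned_instance(rng):
    geometry = _tomo_geometry(rng, depth=2, n_angles=4)
    images = rng.standard_normal(
        (geometry.n_projections,) + geometry.detector_shape)
    data = ProjectionStack(images, geometry)
    weights = LossWeights(lambda1=0.02, lambda2=0.02)
    from .diffops import WaveletBasis
    nc = WaveletBasis((8, 8), levels=2).n_coeffs

    def closure(p):
        return tomo_loss_aligned(p["x"], data, p["shifts"], p["tilt"],
                                 weights, levels=2)

    return closure, {
        "x": rng.standard_normal((2, nc)) * 0.2,
        "shifts": rng.uniform(-0.8, 0.8, size=(geometry.n_projections, 2)),
        "tilt": np.asarray(rng.uniform(-3.0, 3.0)),
    }


def _ptycho_instance(rng):
    box, obj_n = 8, 16
    spec = PropagationSpec(regime="angular-spectrum", distance_m=1e-4,
                           wavelength_m=1e-9, pixel_size_m=5e-8)
    positions = np.array([[1.3, 1.7], [1.2, 6.4], [6.1, 1.9], [5.8, 6.2]])
    intensities = np.abs(rng.standard_normal((4, box, box))) + 0.1
    dataset = PtychoDataset(intensities=intensities, positions=positions,
                            spec=spec)
    weights = LossWeights(lambda1=0.05)
    m = 2

    def closure(p):
        obj = ComplexField(p["obj_re"], p["obj_im"])
        probes = [ComplexField(p["probe_re"][i], p["probe_im"][i])
                  for i in range(m)]
        return ptycho_loss(obj, probes, dataset, positions=p["positions"],
                           z=p["z_rel"] * spec.distance_m, weights=weights)

    return closure, {
        "obj_re": 1.0 + 0.2 * rng.standard_normal((obj_n, obj_n)),
        "obj_im": 0.2 * rng.standard_normal((obj_n, obj_n)),
        "probe_re": rng.standard_normal((m, box, box)) * 0.5,
        "probe_im": rng.standard_normal((m, box, box)) * 0.5,
        "positions": positions + rng.uniform(-0.3, 0.3, positions.shape),
        "z_rel": np.asarray(1.0),
    }


TOY_BUILDERS = {
    "cs": _cs_instance,
    "cs_background": _cs_background_instance,
    "sisr": _sisr_instance,
    "tomo": _tomo_instance,
    "tomo_aligned": _tomo_aligned_instance,
    "ptycho": _ptycho_instance,
}


def toy_closures(name: str, seed: int = 0):
    """One random toy (closure, params) instance of the named loss."""
    rng = np.random.default_rng(seed)
    return TOY_BUILDERS[name](rng)


def gradient_checks(seed: int = 0, n_instances: int = 4,
                    eps: float = 1e-5) -> dict:
    """Worst relative backend-vs-finite-difference discrepancy per loss
    family over ``n_instances`` random instances each."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, builder in TOY_BUILDERS.items():
        worst = 0.0
        for _ in range(n_instances):
            closure, params = builder(rng)
            report = verify_gradients(closure, params, eps=eps)
            worst = max(worst, report.worst_rel)
        out[name] = worst
    return out
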