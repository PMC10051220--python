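"""Reference desk-scale recovery studies, one per modality.

Each study generates a synthetic dataset with known ground truth, runs the
corresponding reconstruction at its default protocol, and returns the
recovery metrics.  The studies double as the package's reproducibility
suite: the acceptance script reports their numbers and the acceptance tests
assert them.  All randomness is derived from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cs import CompressiveSensingModel
from .diffops import ComplexField, PropagationSpec
from .losses import LossWeights
from .ptycho import (PtychoDataset, PtychographyModel, complex_correlation,
                     disk_probe, remove_phase_ramp)
from .sisr import (DegradationSpec, SuperResolutionModel, bilinear_upsample,
                   frc, gaussian_kernel, psnr)
from .solver import analytic_grad_A, analytic_grad_x, minimize
from .synth import (PhantomSpec, make_mask, make_phantom,
                    make_ptycho_object, make_volume_phantom, simulate_cs_scan,
                    simulate_lr, simulate_ptycho, simulate_sinogram)
from .tomo import ProjectionGeometry, TomographyModel
from .validation import gradient_checks

__all__ = ["study_gradients", "study_cs", "study_cs_background",
           "study_sisr", "study_tomo", "study_tomo_alignment",
           "study_ptycho", "study_ptycho_positions", "study_ptycho_distance",
           "limited_angle_protocol"]


def _sub(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2 ** 31 - 1))


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def study_gradients(seed: int = 0, n_instances: int = 4) -> dict:
    """Backend-vs-finite-difference discrepancy across every loss family,
    plus backend-vs-analytic agreement on the generic dense-operator loss."""
    report = gradient_checks(seed=seed, n_instances=n_instances)
    rng = np.random.default_rng(_sub(seed, 1))
    a = rng.standard_normal((8, 6))
    x0 = rng.standard_normal(6) + 0.25 * np.sign(rng.standard_normal(6))
    y = rng.standard_normal(8)

    def closure(p):
        r = ad.matmul(ad.constant(a), p["x"]) - y
        return (r * r).sum() + ad.absolute(p["x"]).sum()

    t = Tensor(x0, requires_grad=True)
    closure({"x": t}).backward()
    g_analytic = analytic_grad_x(a, x0, y)
    err_x = np.abs(t.grad - g_analytic).max()

    at = Tensor(a, requires_grad=True)
    r = ad.matmul(at, ad.constant(x0)) - y
    (r * r).sum().backward()
    err_a = np.abs(at.grad - analytic_grad_A(a, x0, y)).max()
    return {
        "max_rel_fd_discrepancy": max(report.values()),
        "per_family": report,
        "analytic_grad_x_error": float(err_x),
        "analytic_grad_A_error": float(err_a),
    }


# ---------------------------------------------------------------------------
# compressive sensing
# ---------------------------------------------------------------------------

def study_cs(seed: int = 0) -> dict:
    """Exact-sparsity recovery: 64x64 image, 40-sparse in the DCT basis,
    30% uniform-random sampling, noiseless."""
    truth = make_phantom(PhantomSpec(kind="sparse-dct", size=64, sparsity=40,
                                     seed=_sub(seed, 2)))
    mask = make_mask((64, 64), 0.3, "uniform-random", seed=_sub(seed, 3))
    y, _ = simulate_cs_scan(truth, mask)
    res = CompressiveSensingModel(y, mask).fit(max_iter=800)
    rel = float(np.linalg.norm(res.image - truth) / np.linalg.norm(truth))
    return {"rel_l2_error": rel, "n": 64 * 64}


def study_cs_background(seed: int = 0) -> dict:
    """Joint image/background recovery under a per-row beam drift in
    [0.8, 1.2] on a compressible bright-transmission image."""
    truth = make_phantom(PhantomSpec(kind="sparse-dct", size=64, sparsity=40,
                                     seed=_sub(seed, 4), dc_level=1.0))
    mask = make_mask((64, 64), 0.3, "uniform-random", seed=_sub(seed, 5))
    y, gain = simulate_cs_scan(truth, mask, gain_amplitude=0.2,
                               seed=_sub(seed, 6))
    res = CompressiveSensingModel(y, mask, background=True).fit(max_iter=4000)
    corr = float(np.corrcoef(res.gain.ravel(), gain.ravel())[0, 1])
    err_bg = float(np.linalg.norm(res.image - truth)
                   / np.linalg.norm(truth))
    plain = CompressiveSensingModel(y, mask).fit(max_iter=800)
    err_plain = float(np.linalg.norm(plain.image - truth)
                      / np.linalg.norm(truth))
    return {"gain_correlation": corr, "rel_error_destriped": err_bg,
            "rel_error_plain": err_plain, "n": 64 * 64}


# ---------------------------------------------------------------------------
# super-resolution
# ---------------------------------------------------------------------------

def study_sisr(seed: int = 0) -> dict:
    """Blind x4 super-resolution of a 104x104 piecewise-constant phantom
    degraded by a known 13x13 Gaussian kernel (sigma = 2), noiseless."""
    truth = make_phantom(PhantomSpec(kind="piecewise-constant-ellipses",
                                     size=104, seed=_sub(seed, 7)))
    spec = DegradationSpec(factor=4, kernel_size=13)
    kernel_true = gaussian_kernel(13, 2.0)
    y = simulate_lr(truth, kernel_true, spec)
    baseline = bilinear_upsample(y, 4)
    res = SuperResolutionModel(y, spec=spec).fit()
    ncc = float(np.sum(res.kernel * kernel_true)
                / np.sqrt(np.sum(res.kernel ** 2)
                          * np.sum(kernel_true ** 2)))
    return {
        "psnr_gain_db": psnr(res.image, truth) - psnr(baseline, truth),
        "kernel_ncc": ncc,
        "frc_crossing_recon": frc(res.image, truth).crossing,
        "frc_crossing_bilinear": frc(baseline, truth).crossing,
        "n": 104 * 104,
    }


# ---------------------------------------------------------------------------
# tomography
# ---------------------------------------------------------------------------

def study_tomo(seed: int = 0) -> dict:
    """Limited-angle reconstruction: 64x64 slice, 60 angles over 120 deg,
    noiseless; regularized versus the lambda = 0 ablation, and the
    180-degree full-range control."""
    truth = make_phantom(PhantomSpec(kind="piecewise-constant-ellipses",
                                     size=64, seed=_sub(seed, 8)))
    vol = truth[None]

    def run(span, weights=None):
        geo = ProjectionGeometry(
            angles_deg=np.linspace(0.0, span, 60, endpoint=False),
            volume_shape=vol.shape)
        stack, _ = simulate_sinogram(vol, geo)
        res = TomographyModel(stack, weights=weights).fit(max_iter=300)
        return float(np.sqrt(np.mean((res.volume - vol) ** 2)))

    return {
        "rmse_regularized": run(120.0),
        "rmse_unregularized": run(120.0, LossWeights(0.0, 0.0)),
        "rmse_full_range": run(180.0),
        "n": 60 * 64,
    }


def study_tomo_alignment(seed: int = 0) -> dict:
    """Joint alignment: shifts uniform in +-3 px plus a 2-degree global
    detector tilt, recovered by pre-alignment + alternating refinement."""
    vol = make_volume_phantom(16, 48, seed=_sub(seed, 9), margin=5.0)
    geo = ProjectionGeometry(
        angles_deg=np.linspace(0.0, 120.0, 40, endpoint=False),
        volume_shape=vol.shape)
    stack, truth = simulate_sinogram(vol, geo, shift_range_px=3.0,
                                     tilt_deg=2.0, seed=_sub(seed, 10))
    res = TomographyModel(stack, refine_alignment=True).fit()
    align = res.alignment
    return {
        "shift_rms_error_px": float(np.sqrt(np.mean(
            (align.shifts - truth.shifts) ** 2))),
        "tilt_error_deg": float(abs(align.tilt_deg - truth.tilt_deg)),
        "n": geo.n_projections,
    }


# ---------------------------------------------------------------------------
# ptychography
# ---------------------------------------------------------------------------

_PT_SPEC = PropagationSpec(regime="farfield", wavelength_m=1e-9,
                           pixel_size_m=5e-8)


def _illumination_mask(shape, probe, positions, box):
    illum = np.zeros(shape)
    p2 = np.abs(probe) ** 2
    for (r, c) in positions:
        ri, ci = int(round(r)), int(round(c))
        illum[ri:ri + box, ci:ci + box] += p2
    return illum > 0.1 * illum.max()


def study_ptycho(seed: int = 0, max_iter: int = 2000) -> dict:
    """Far-field phase retrieval: 5x5 scan, 12 px step, 48 px defocused disk
    probe, encoder-recorded stage jitter, blind probe; correlation is scored
    after removing the global phase and the exact linear phase-ramp
    ambiguity, on the illuminated region."""
    obj = make_ptycho_object(100, seed=_sub(seed, 11))
    probe = disk_probe(48, radius=12.0, power=1.0, defocus_rad=1.0)
    dataset, truth = simulate_ptycho(obj, probe[None], (5, 5, 12.0),
                                     jitter_px=1.0, spec=_PT_SPEC,
                                     seed=_sub(seed, 12),
                                     record_positions=True)
    model = PtychographyModel(dataset, object_shape=obj.shape,
                              refine_probe=True)
    res = model.fit(max_iter=max_iter)
    mask = _illumination_mask(obj.shape, probe, truth["positions"], 48)
    aligned = remove_phase_ramp(res.object, obj, mask)
    return {
        "object_correlation": complex_correlation(aligned, obj, mask),
        "probe_correlation": complex_correlation(res.probes[0], probe),
        "n": dataset.n_patterns,
    }


def study_ptycho_positions(seed: int = 0, max_iter: int = 7000) -> dict:
    """Scan-position refinement: +-1 px unrecorded jitter; errors scored
    after removing the exact global-translation gauge."""
    obj = make_ptycho_object(100, seed=_sub(seed, 13))
    probe = disk_probe(48, radius=12.0, power=1.0, defocus_rad=1.0)
    dataset, truth = simulate_ptycho(obj, probe[None], (5, 5, 12.0),
                                     jitter_px=1.0, spec=_PT_SPEC,
                                     seed=_sub(seed, 14))

    def gauge_rms(positions):
        r = positions - truth["positions"]
        r = r - r.mean(axis=0, keepdims=True)
        return float(np.sqrt(np.mean(r ** 2)))

    refined = PtychographyModel(dataset, object_shape=obj.shape,
                                refine_probe=True,
                                refine_positions=True).fit(max_iter=max_iter)
    frozen = PtychographyModel(dataset, object_shape=obj.shape,
                               refine_probe=True,
                               refine_positions=False).fit(max_iter=400)
    return {
        "position_rms_injected_px": gauge_rms(dataset.positions),
        "position_rms_refined_px": gauge_rms(refined.positions),
        "position_rms_unrefined_px": gauge_rms(frozen.positions),
        "n": dataset.n_patterns,
    }


def study_ptycho_distance(seed: int = 0, max_iter: int = 2000) -> dict:
    """Near-field propagation-distance refinement from a 20% perturbed
    start, with a characterized (fixed) probe."""
    import dataclasses
    obj = make_ptycho_object(100, seed=_sub(seed, 15))
    probe = disk_probe(48, radius=12.0, power=1.0, defocus_rad=1.0)
    z_true = 5e-4
    spec = dataclasses.replace(_PT_SPEC, regime="angular-spectrum",
                               distance_m=z_true)
    dataset, _ = simulate_ptycho(obj, probe[None], (5, 5, 12.0),
                                 jitter_px=1.0, spec=spec,
                                 seed=_sub(seed, 16), record_positions=True)
    bad = PtychoDataset(dataset.intensities, dataset.positions,
                        dataclasses.replace(spec, distance_m=1.2 * z_true))
    res = PtychographyModel(bad, object_shape=obj.shape,
                            probe_init=probe[None], refine_probe=False,
                            refine_distance=True).fit(max_iter=max_iter)
    return {
        "distance_rel_error": float(abs(res.distance_m - z_true) / z_true),
        "distance_start_rel_error": 0.2,
        "n": dataset.n_patterns,
    }


# ---------------------------------------------------------------------------
# protocol bookkeeping
# ---------------------------------------------------------------------------

def limited_angle_protocol(n_full: int = 180, step_full_deg: float = 1.0,
                           subsample: int = 2, max_angle_deg: float = 120.0
                           ) -> dict:
    """The limited-angle emulation protocol applied to a full scan's angle
    list: subsample by a factor and restrict the angular range; reports the
    resulting projection count (60 for the 180 x 1 deg reference scan)."""
    angles = np.arange(n_full) * step_full_deg
    kept = angles[::subsample]
    kept = kept[kept < max_angle_deg]
    return {"projection_count": int(len(kept)),
            "angle_step_deg": float(step_full_deg * subsample),
            "n": n_full}
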