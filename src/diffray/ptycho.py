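"""Differentiable ptychography: multimode-probe forward model and
reconstruction with optional probe / scan-position / distance refinement.

The object transmission function x and the probe modes p_m are complex
fields carried as real/imaginary duplets.  The measured intensity at scan
position i is the incoherent sum over modes

    I_i = sum_m | D_z ( p_m * crop(x, r_i) ) |^2

with D_z the far-field (single Fourier transform) or angular-spectrum
propagator.  The loss is

    L(x; p, z, r) = sum_i || I_i - y_i ||^2 + lambda1 || x_{|x|>1} ||_1

where the regularizer penalizes transmission moduli above 1 (the object
cannot amplify the beam).  Cropping is an affine (translation) resampler,
so gradients flow to the real-valued scan positions; the propagation
distance enters through the transfer-function phase and is refinable too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, astensor
from .diffops import (ComplexField, PropagationSpec, propagate, subpixel_crop)
from .losses import LossWeights, magnitude_excess_l1
from .model import InverseModel, ReconstructionResults
from .solver import OptimResult, minimize

__all__ = ["PtychoDataset", "ptycho_forward_intensity", "ptycho_loss",
           "reconstruct_ptycho", "PtychographyModel", "PtychoResults",
           "disk_probe", "complex_correlation"]


@dataclass
class PtychoDataset:
    """Measured diffraction intensities with scan and propagation metadata.

    intensities : (N, h, w) nonnegative patterns.
    positions : (N, 2) nominal scan positions — (row, col) of the
        computational box corner, in object pixels (real-valued).
    spec : :class:`PropagationSpec` (regime is a dataset field).
    """

    intensities: np.ndarray
    positions: np.ndarray
    spec: PropagationSpec

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.positions = np.asarray(self.positions,
                                    dtype=np.float64).reshape(-1, 2)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (N, h, w)")
        if len(self.positions) != len(self.intensities):
            raise ValueError("position count != pattern count")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_patterns(self) -> int:
        return len(self.intensities)

    @property
    def box(self) -> tuple[int, int]:
        return self.intensities.shape[1:]


def disk_probe(box: int, radius: float | None = None, power: float = 1.0,
               soft: float = 1.0, defocus_rad: float = 0.0) -> np.ndarray:
    """A smooth-edged disk illumination, optionally with a quadratic
    (defocus-like) phase; total power normalized to ``power``."""
    r = np.hypot(*np.meshgrid(np.arange(box) - (box - 1) / 2,
                              np.arange(box) - (box - 1) / 2, indexing="ij"))
    if radius is None:
        radius = box / 4.0
    amp = 1.0 / (1.0 + np.exp((r - radius) / max(soft, 1e-6)))
    phase = defocus_rad * (r / radius) ** 2
    p = amp * np.exp(1j * phase)
    p *= np.sqrt(power / np.sum(np.abs(p) ** 2))
    return p


def _mode_stack(probes) -> list[ComplexField]:
    """Normalize the probe argument to a list of ComplexFields."""
    if isinstance(probes, ComplexField):
        return [probes]
    if isinstance(probes, (list, tuple)):
        return [p if isinstance(p, ComplexField)
                else ComplexField.from_complex(p) for p in probes]
    arr = np.asarray(probes)
    if arr.ndim == 2:
        return [ComplexField.from_complex(arr)]
    return [ComplexField.from_complex(arr[m]) for m in range(arr.shape[0])]


def _forward_intensities(obj: ComplexField, probes, positions, box,
                         spec: PropagationSpec, z=None) -> Tensor:
    """Batched intensities at every position: (N, h, w) Tensor."""
    views = subpixel_crop(obj, positions, box)  # (N, h, w) duplet
    total = None
    for p in _mode_stack(probes):
        exit_wave = ComplexField(p.re * views.re - p.im * views.im,
                                 p.re * views.im + p.im * views.re)
        det = propagate(exit_wave, spec, z=z)
        inten = det.abs2()
        total = inten if total is None else total + inten
    return total


def ptycho_forward_intensity(obj: ComplexField, probes, position,
                             spec: PropagationSpec, z=None) -> Tensor:
    """Simulated intensity pattern at one scan position (incoherent sum of
    the per-mode diffracted intensities)."""
    pos = astensor(position)
    box = _mode_stack(probes)[0].shape
    single = pos.value.ndim == 1
    pos2 = pos.reshape(-1, 2)
    out = _forward_intensities(obj, probes, pos2, box, spec, z=z)
    if single:
        out = out.reshape(box)
    return out


def ptycho_loss(obj: ComplexField, probes, dataset: PtychoDataset,
                positions=None, z=None,
                weights: LossWeights | None = None) -> Tensor:
    """Summed L2 intensity misfit plus the magnitude-excess penalty."""
    if weights is None:
        weights = LossWeights()
    pos = astensor(dataset.positions if positions is None else positions)
    sims = _forward_intensities(obj, probes, pos.reshape(-1, 2),
                                dataset.box, dataset.spec, z=z)
    diff = sims - ad.constant(dataset.intensities)
    loss = (diff * diff).sum()
    if weights.lambda1 > 0:
        loss = loss + weights.lambda1 * magnitude_excess_l1(obj)
    return loss


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PtychographyModel(InverseModel):
    """Joint phase retrieval over object, probe modes and geometry.

    Parameters
    ----------
    dataset : measured intensities + nominal positions + propagation spec.
    object_shape : field-of-view size; derived from the scan extent plus a
        margin when omitted.
    n_modes : number of mutually incoherent probe modes.
    probe_init : (M, h, w) complex array, a single (h, w) array, or None for
        a disk scaled to the dataset's mean total intensity.
    refine_probe / refine_positions / refine_distance : parameter groups to
        optimize alongside the object.
    """

    def __init__(self, dataset: PtychoDataset, object_shape=None,
                 n_modes: int = 1, probe_init=None,
                 weights: LossWeights | None = None,
                 refine_probe: bool = True, refine_positions: bool = False,
                 refine_distance: bool = False):
        if dataset.n_patterns < 4:
            raise ValueError("ptychography needs >= 4 overlapping positions")
        self.dataset = dataset
        h, w = dataset.box
        if object_shape is None:
            margin = 2
            H = int(np.ceil(dataset.positions[:, 0].max())) + h + margin
            W = int(np.ceil(dataset.positions[:, 1].max())) + w + margin
            object_shape = (H, W)
        self.object_shape = tuple(object_shape)
        self.n_modes = int(n_modes)
        if probe_init is None:
            mean_power = float(dataset.intensities.sum(axis=(1, 2)).mean())
            probe_init = np.stack([
                disk_probe(h, power=mean_power / n_modes * (0.8 ** m))
                for m in range(n_modes)])
        probe_init = np.asarray(probe_init, dtype=np.complex128)
        if probe_init.ndim == 2:
            probe_init = probe_init[None]
        self.probe_init = probe_init
        self.weights = weights if weights is not None else LossWeights(
            lambda1=1e-3 * float(dataset.intensities.max()))
        self.refine_probe = refine_probe
        self.refine_positions = refine_positions
        self.refine_distance = refine_distance

    def loss_closure(self):
        ds = self.dataset
        H, W = self.object_shape

        params = {
            "obj_re": np.ones((H, W)),
            "obj_im": np.zeros((H, W)),
        }
        if self.refine_probe:
            params["probe_re"] = self.probe_init.real.copy()
            params["probe_im"] = self.probe_init.imag.copy()
        if self.refine_positions:
            params["positions"] = ds.positions.copy()
        if self.refine_distance:
            # refine z as a dimensionless factor of the nominal distance so
            # the optimizer and the FD oracle see an O(1) coordinate
            params["z_rel"] = np.asarray(1.0)

        const_probe_re = ad.constant(self.probe_init.real)
        const_probe_im = ad.constant(self.probe_init.imag)

        def closure(p):
            obj = ComplexField(p["obj_re"], p["obj_im"])
            if self.refine_probe:
                pr, pi = p["probe_re"], p["probe_im"]
            else:
                pr, pi = const_probe_re, const_probe_im
            probes = [ComplexField(pr[m], pi[m])
                      for m in range(self.probe_init.shape[0])]
            if self.refine_positions:
                # keep the computational box inside the object support even
                # if the optimizer momentarily overshoots
                h_box, w_box = ds.box
                positions2 = p["positions"].reshape(-1, 2)
                pr_ = ad.clip(positions2[:, 0], 0.0, H - h_box)
                pc_ = ad.clip(positions2[:, 1], 0.0, W - w_box)
                positions = ad.stack([pr_, pc_], axis=1)
            else:
                positions = None
            z = (p["z_rel"] * ds.spec.distance_m
                 if self.refine_distance else None)
            return ptycho_loss(obj, probes, ds, positions=positions, z=z,
                               weights=self.weights)

        return closure, params

    def fit(self, method: str = "staged", max_iter: int = 1500,
            tol: float = 1e-12, lr: float = 0.005, seed: int = 0,
            sweep_rounds: int = 2, sweep_iters: tuple[int, int] = (120, 100)
            ) -> "PtychoResults":
        """Reconstruct by staged optimization (default):

        1. quasi-Newton sweeps that alternate object-only and probe-only
           blocks (each block is well conditioned on its own, which carries
           the blind probe estimate into the right basin), then
        2. a joint first-order adaptive polish over every enabled parameter
           group (object, probe modes, scan positions, distance).

        ``method="adam"`` or ``"quasi-newton"`` run a single simultaneous
        minimization instead.
        """
        closure, params = self.loss_closure()
        if method != "staged":
            res = minimize(closure, params, method=method, max_iter=max_iter,
                           tol=tol, lr=lr, seed=seed)
            return PtychoResults(self, res)

        ds, w = self.dataset, self.weights
        o_re = params["obj_re"]
        o_im = params["obj_im"]
        p_re = params.get("probe_re", self.probe_init.real.copy())
        p_im = params.get("probe_im", self.probe_init.imag.copy())
        m = self.probe_init.shape[0]
        trace: list[float] = []
        for _ in range(sweep_rounds):
            def c_obj(prm, p_re=p_re, p_im=p_im):
                obj = ComplexField(prm["re"], prm["im"])
                probes = [ComplexField(Tensor(p_re[k]), Tensor(p_im[k]))
                          for k in range(m)]
                return ptycho_loss(obj, probes, ds, weights=w)
            ro = minimize(c_obj, {"re": o_re, "im": o_im},
                          max_iter=sweep_iters[0], tol=tol, seed=seed)
            o_re, o_im = ro.params["re"], ro.params["im"]
            trace.extend(ro.loss_trace)
            if not self.refine_probe:
                continue

            def c_probe(prm, o_re=o_re, o_im=o_im):
                obj = ComplexField(Tensor(o_re), Tensor(o_im))
                probes = [ComplexField(prm["re"][k], prm["im"][k])
                          for k in range(m)]
                return ptycho_loss(obj, probes, ds, weights=w)
            rp = minimize(c_probe, {"re": p_re, "im": p_im},
                          max_iter=sweep_iters[1], tol=tol, seed=seed)
            p_re, p_im = rp.params["re"], rp.params["im"]
            trace.extend(rp.loss_trace)

        params["obj_re"], params["obj_im"] = o_re, o_im
        if self.refine_probe:
            params["probe_re"], params["probe_im"] = p_re, p_im
        res = minimize(closure, params, method="adam", max_iter=max_iter,
                       tol=tol, lr=lr, seed=seed)
        res.loss_trace = np.concatenate([np.asarray(trace), res.loss_trace])
        res.n_iter = len(res.loss_trace)
        return PtychoResults(self, res)


class PtychoResults(ReconstructionResults):
    """Estimates with the probe/object scale ambiguity resolved by
    renormalizing total probe power to the dataset's mean total intensity."""

    def __init__(self, model: PtychographyModel, optim: OptimResult):
        super().__init__(model, optim)
        obj = optim.params["obj_re"] + 1j * optim.params["obj_im"]
        if model.refine_probe:
            probes = optim.params["probe_re"] + 1j * optim.params["probe_im"]
        else:
            probes = model.probe_init.copy()
        # fix the multiplicative split (the data term sees only p * x)
        target = float(model.dataset.intensities.sum(axis=(1, 2)).mean())
        power = float(np.sum(np.abs(probes) ** 2))
        if power > 0 and model.refine_probe:
            c = np.sqrt(target / power)
            probes = probes * c
            obj = obj / c
        self.object = obj
        self.probes = probes
        self.positions = (optim.params["positions"].copy()
                          if model.refine_positions
                          else model.dataset.positions.copy())
        self.distance_m = (float(optim.params["z_rel"])
                           * model.dataset.spec.distance_m
                           if model.refine_distance
                           else model.dataset.spec.distance_m)

    def _estimate_rows(self):
        return [("Patterns", str(self.model.dataset.n_patterns)),
                ("Probe modes", str(self.probes.shape[0])),
                ("Object shape", str(self.object.shape)),
                ("Distance", f"{self.distance_m:.6g} m")]


def reconstruct_ptycho(dataset: PtychoDataset, n_modes: int = 1,
                       probe_init=None, weights: LossWeights | None = None,
                       refine_probe: bool = True,
                       refine_positions: bool = False,
                       refine_distance: bool = False, method: str = "staged",
                       max_iter: int = 1500, lr: float = 0.005,
                       tol: float = 1e-12, seed: int = 0):
    """Minimize the ptychography loss over the enabled parameter groups;
    returns (object, probes, positions, z, OptimResult)."""
    model = PtychographyModel(dataset, n_modes=n_modes, probe_init=probe_init,
                              weights=weights, refine_probe=refine_probe,
                              refine_positions=refine_positions,
                              refine_distance=refine_distance)
    res = model.fit(method=method, max_iter=max_iter, lr=lr, tol=tol,
                    seed=seed)
    return (res.object, res.probes, res.positions, res.distance_m,
            res.optim_result)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def complex_correlation(a: np.ndarray, b: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Magnitude of the normalized complex inner product — invariant to the
    global phase offset between the two fields."""
    a = np.asarray(a, dtype=np.complex128)
    b = np.asarray(b, dtype=np.complex128)
    if mask is not None:
        a, b = a[mask], b[mask]
    num = np.abs(np.vdot(a, b))
    den = np.sqrt(np.vdot(a, a).real * np.vdot(b, b).real)
    return float(num / den) if den > 0 else 0.0


def remove_phase_ramp(estimate: np.ndarray, reference: np.ndarray,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Align the exact object/probe phase-ramp ambiguity of ptychography:
    a linear phase across the object (with the conjugate ramp on the probe)
    leaves every measured intensity unchanged, so reconstructions are
    compared after fitting the ramp e^{i(a r + b c)} that best matches the
    reference and dividing it out."""
    import scipy.optimize as sopt
    est = np.asarray(estimate, dtype=np.complex128)
    ref = np.asarray(reference, dtype=np.complex128)
    g = est * np.conj(ref)
    if mask is not None:
        g = np.where(mask, g, 0.0)
    H, W = g.shape
    # coarse ramp frequency from the cross-spectrum peak
    spec = np.fft.fft2(g)
    idx = np.unravel_index(np.argmax(np.abs(spec)), spec.shape)
    fr = np.fft.fftfreq(H)[idx[0]]
    fc = np.fft.fftfreq(W)[idx[1]]
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")

    def neg_overlap(p):
        return -np.abs(np.sum(g * np.exp(-1j * (p[0] * rr + p[1] * cc))))

    opt = sopt.minimize(neg_overlap, x0=[2 * np.pi * fr, 2 * np.pi * fc],
                        method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-12})
    a_, b_ = opt.x
    return est * np.exp(-1j * (a_ * rr + b_ * cc))
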