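"""Synthetic phantoms and forward simulators with known ground truth.

Every simulator is a pure function of its inputs and an explicit seed, so
repeated calls are bitwise identical.  Noise defaults to none: the
reconstruction losses are plain L2/Huber fits, so the reference conditions
are noiseless forward simulations, with noise available as a robustness
control.

The generators emulate the acquisition artefacts the reconstruction models
are designed to undo: sparse regular-mask raster scans with a slow beam
intensity drift, blur + binning degradation, limited-angle sinograms with
per-projection shifts and a global detector tilt, and overlapping-scan
diffraction data with position jitter and (optionally) multimode
illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
import scipy.ndimage as ndi

from .autodiff import Tensor
from .diffops import (AffineMap, ComplexField, PropagationSpec, SamplingMask,
                      affine_warp, apply_mask)
from .ptycho import PtychoDataset, disk_probe, ptycho_forward_intensity
from .sisr import DegradationSpec, degrade
from .tomo import (AlignmentParams, ProjectionGeometry, ProjectionStack,
                   tomo_forward)

__all__ = ["NoiseSpec", "PhantomSpec", "make_phantom", "make_mask",
           "simulate_cs_scan", "simulate_lr", "simulate_sinogram",
           "simulate_ptycho", "smooth_gain", "make_ptycho_object"]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: none, additive Gaussian (std = level), or
    Poisson with ``level`` the expected total counts per image."""

    model: str = "none"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("none", "additive-gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.level < 0:
            raise ValueError("noise level must be nonnegative")

    def apply(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        if self.model == "none" or self.level == 0:
            return y.copy()
        rng = np.random.default_rng(self.seed)
        if self.model == "additive-gaussian":
            return y + rng.normal(0.0, self.level, size=y.shape)
        # poisson: scale so the expected total is `level` counts
        total = float(np.abs(y).sum()) or 1.0
        scale = self.level / total
        return rng.poisson(np.maximum(y, 0.0) * scale) / scale


@dataclass(frozen=True)
class PhantomSpec:
    """kind: 'sparse-dct' | 'piecewise-constant-ellipses' | 'cell-like-blobs'."""

    kind: str = "piecewise-constant-ellipses"
    size: int = 64
    sparsity: int = 40
    seed: int = 0
    dc_level: float = 0.0  # sparse-dct only: mean transmission level

    def __post_init__(self):
        if self.size < 16:
            raise ValueError("phantom size must be >= 16")
        if self.sparsity > self.size ** 2:
            raise ValueError("sparsity exceeds pixel count")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic 2D phantom of the requested kind."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    if spec.kind == "sparse-dct":
        # exactly K-sparse in the orthonormal DCT basis; with dc_level > 0
        # the DC coefficient is one of the K (a bright transmission image)
        coeffs = np.zeros((n, n))
        k_random = spec.sparsity - (1 if spec.dc_level > 0 else 0)
        flat_idx = rng.choice(n * n - 1, size=k_random, replace=False) + 1
        vals = rng.uniform(0.5, 2.0, size=k_random) \
            * rng.choice([-1.0, 1.0], size=k_random)
        coeffs.reshape(-1)[flat_idx] = vals
        if spec.dc_level > 0:
            coeffs[0, 0] = spec.dc_level * n
        return sfft.idctn(coeffs, type=2, norm="ortho")
    if spec.kind == "piecewise-constant-ellipses":
        img = np.zeros((n, n))
        levels = np.linspace(0.2, 1.0, 7)  # <= 8 distinct values incl. 0
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        for _ in range(6):
            cy, cx = rng.uniform(0.25 * n, 0.75 * n, size=2)
            ay, ax = rng.uniform(0.08 * n, 0.3 * n, size=2)
            t = rng.uniform(0, np.pi)
            ry = (yy - cy) * np.cos(t) + (xx - cx) * np.sin(t)
            rx = -(yy - cy) * np.sin(t) + (xx - cx) * np.cos(t)
            inside = (ry / ay) ** 2 + (rx / ax) ** 2 <= 1.0
            img[inside] = rng.choice(levels)
        return img
    if spec.kind == "cell-like-blobs":
        noise = rng.standard_normal((n, n))
        img = ndi.gaussian_filter(noise, sigma=n / 16.0)
        img -= img.min()
        peak = img.max() or 1.0
        return img / peak
    raise ValueError(f"unknown phantom kind {spec.kind!r}")


def make_volume_phantom(depth: int, size: int, seed: int = 0,
                        margin: float = 4.0, n_beads: int = 12,
                        bead_value: float = 2.0) -> np.ndarray:
    """3D phantom for tomographic tests: smooth blobs plus bright fiducial
    beads (the gold-nanobead markers of cryo-tomography practice, which are
    what makes projection alignment well determined).

    The sample is embedded in empty space: intensity tapers to exactly zero
    within ``margin`` voxels of every face, so moderate detector shifts,
    tilts and rotations move only empty voxels across the field edge.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((depth, size, size))
    vol = ndi.gaussian_filter(noise, sigma=(depth / 8.0, size / 12.0,
                                            size / 12.0))
    vol -= vol.min()
    peak = vol.max() or 1.0
    vol /= peak
    if n_beads > 0:
        # fiducials ring the specimen rim at the top/bottom surfaces, where
        # their leverage on detector tilt and shifts is largest — mirroring
        # where experimentalists deposit gold beads
        beads = np.zeros_like(vol)
        lo = int(np.ceil(margin + 1))
        lo_z = max(1, min(lo, depth // 2 - 1))
        n_rim = max(n_beads - 4, n_beads // 2)
        radius = size / 2.0 - margin - 3.0
        for k in range(n_rim):
            ang = 2.0 * np.pi * k / n_rim + rng.uniform(0.0, 0.3)
            r = int(round(size / 2 + radius * np.cos(ang)))
            c = int(round(size / 2 + radius * np.sin(ang)))
            z = lo_z if k % 2 == 0 else depth - lo_z - 1
            beads[z, r, c] = 1.0
        for _ in range(n_beads - n_rim):
            beads[rng.integers(lo_z, max(depth - lo_z, lo_z + 1)),
                  rng.integers(lo + 1, size - lo - 1),
                  rng.integers(lo + 1, size - lo - 1)] = 1.0
        vol = vol + ndi.gaussian_filter(beads, sigma=1.0) * bead_value * 5.0
    rr = np.hypot(*np.meshgrid(np.arange(size) - (size - 1) / 2,
                               np.arange(size) - (size - 1) / 2,
                               indexing="ij"))
    taper_plane = np.clip((size / 2.0 - margin - rr) / 3.0, 0.0, 1.0)
    zz = np.arange(depth, dtype=np.float64)
    margin_z = min(margin, depth / 2.0 - 2.0)  # shallow stacks keep content
    taper_depth = np.clip(
        (np.minimum(zz, depth - 1 - zz) - margin_z + 1.0) / 2.0, 0.0, 1.0)
    return vol * taper_plane[None] * taper_depth[:, None, None]


def make_mask(shape, fraction: float, scheme: str = "regular-stride",
              seed: int = 0) -> SamplingMask:
    """Sampling mask with realized fraction within 1/size of the request.

    Regular scheme keeps pixel (i, j) when (i*W + j) mod round(1/fraction)
    == 0, matching a sorted-coordinate-list scan path.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    h, w = shape
    if scheme == "regular-stride":
        stride = int(round(1.0 / fraction))
        flat = np.arange(h * w)
        mask = (flat % stride) == 0
        return SamplingMask(mask.reshape(h, w), scheme=scheme)
    if scheme == "uniform-random":
        rng = np.random.default_rng(seed)
        k = int(round(fraction * h * w))
        idx = rng.choice(h * w, size=k, replace=False)
        mask = np.zeros(h * w, dtype=bool)
        mask[idx] = True
        return SamplingMask(mask.reshape(h, w), scheme=scheme)
    raise ValueError(f"unknown mask scheme {scheme!r}")


def smooth_gain(shape, amplitude: float, seed: int = 0) -> np.ndarray:
    """Beam-intensity drift of a long raster scan: a bounded random walk
    over the scan rows (the dwell drift between scan lines), lightly
    smoothed, constant within each row.  Serialized in raster order it is a
    smooth bounded walk; in 2D it is the familiar striping artefact.
    max|gain - 1| equals ``amplitude`` exactly (unless degenerate)."""
    h, w = shape
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.standard_normal(h))
    walk = ndi.gaussian_filter1d(walk, sigma=2.0)
    walk -= walk.mean()
    peak = np.abs(walk).max()
    if peak > 0:
        walk = walk / peak * amplitude
    return np.repeat((1.0 + walk)[:, None], w, axis=1)


def simulate_cs_scan(image: np.ndarray, mask: SamplingMask,
                     gain_amplitude: float = 0.0,
                     noise: NoiseSpec = NoiseSpec(), seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sparse raster scan y = Phi(image * gain) + noise (on sampled pixels,
    zero elsewhere).  Returns (y, gain)."""
    image = np.asarray(image, dtype=np.float64)
    gain = (smooth_gain(image.shape, gain_amplitude, seed=seed)
            if gain_amplitude > 0 else np.ones_like(image))
    y = apply_mask(Tensor(image * gain), mask).value
    y_noisy = noise.apply(y)
    return np.where(mask.values, y_noisy, 0.0), gain


def simulate_lr(hr: np.ndarray, kernel: np.ndarray, spec: DegradationSpec,
                noise: NoiseSpec = NoiseSpec()) -> np.ndarray:
    """Low-resolution measurement y = B H x + n."""
    y = degrade(Tensor(np.asarray(hr, dtype=np.float64)),
                Tensor(np.asarray(kernel, dtype=np.float64)), spec).value
    return noise.apply(y)


def _misaligned_projections(volume: np.ndarray,
                            geometry: ProjectionGeometry,
                            shifts: np.ndarray,
                            tilt_deg: float) -> np.ndarray:
    """Render projections of a misaligned acquisition in one sampling pass.

    Detector pixel (z, j) of projection i reads the line integral through
    the detector position C_i^{-1}(z, j): the inverse of the alignment
    correction C_i = shift(s_i) o rotation(phi).  The volume is sampled
    trilinearly along the beam (single interpolation footprint, as a real
    detector would), so the correction C_i applied to the data undoes the
    misalignment up to one interpolation, not two.
    """
    d, h, w = geometry.volume_shape
    n = geometry.n_projections
    out = np.empty((n, d, w))
    zc = np.arange(d, dtype=np.float64) - (d - 1) / 2.0
    jc = np.arange(w, dtype=np.float64) - (w - 1) / 2.0
    zz, jj = np.meshgrid(zc, jc, indexing="ij")
    ar, ac = geometry.axis
    phi = np.deg2rad(tilt_deg)
    cphi, sphi = np.cos(phi), np.sin(phi)
    a_c = np.array([[cphi, -sphi], [sphi, cphi]])  # C pull-back linear part
    a_inv = a_c.T
    rr = np.arange(h, dtype=np.float64) - (h - 1) / 2.0
    for i in range(n):
        b_c = -a_c @ shifts[i]
        b_inv = -a_inv @ b_c
        zp = a_inv[0, 0] * zz + a_inv[0, 1] * jj + b_inv[0] + (d - 1) / 2.0
        jp = a_inv[1, 0] * zz + a_inv[1, 1] * jj + b_inv[1]  # centered col
        t = np.deg2rad(geometry.angles_deg[i])
        # in-plane rotated source for every beam row r and detector col j'
        src_r = (np.cos(t) * (rr[:, None, None] - ar)
                 - np.sin(t) * (jp[None] - ac) + ar + (h - 1) / 2.0)
        src_c = (np.sin(t) * (rr[:, None, None] - ar)
                 + np.cos(t) * (jp[None] - ac) + ac + (w - 1) / 2.0)
        z0 = np.floor(zp).astype(np.int64)
        fz = zp - z0
        acc = np.zeros((d, w))
        for dz, wz in ((0, 1.0 - fz), (1, fz)):
            zi = z0 + dz
            ok_z = (zi >= 0) & (zi < d)
            zi_s = np.clip(zi, 0, d - 1)
            r0 = np.floor(src_r).astype(np.int64)
            c0 = np.floor(src_c).astype(np.int64)
            fr, fc = src_r - r0, src_c - c0
            plane = np.zeros((h, d, w))
            for dr, dc, wt in ((0, 0, (1 - fr) * (1 - fc)),
                               (0, 1, (1 - fr) * fc),
                               (1, 0, fr * (1 - fc)),
                               (1, 1, fr * fc)):
                ri, ci = r0 + dr, c0 + dc
                ok = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
                ri_s = np.clip(ri, 0, h - 1)
                ci_s = np.clip(ci, 0, w - 1)
                vals = volume[zi_s[None, :, :], ri_s, ci_s]
                plane += np.where(ok, vals * wt, 0.0)
            acc += np.where(ok_z, wz, 0.0) * plane.sum(axis=0)
        out[i] = acc * geometry.step
    return out


def simulate_sinogram(volume: np.ndarray, geometry: ProjectionGeometry,
                      shift_range_px: float = 0.0, tilt_deg: float = 0.0,
                      noise: NoiseSpec = NoiseSpec(), seed: int = 0
                      ) -> tuple[ProjectionStack, AlignmentParams]:
    """Simulate a (possibly misaligned) parallel-beam acquisition.

    Per-projection detector shifts are drawn uniformly in
    +-``shift_range_px``; the detector tilt is common to all projections.
    The misaligned geometry is sampled in a single interpolation pass, so
    applying the alignment correction C(s_i, phi) with the returned truth
    parameters undoes the injected misalignment (up to one bilinear
    interpolation).
    """
    volume = np.asarray(volume, dtype=np.float64)
    rng = np.random.default_rng(seed)
    n = geometry.n_projections
    if shift_range_px > 0:
        shifts = rng.uniform(-shift_range_px, shift_range_px, size=(n, 2))
        # jitter has no net drift: remove the components degenerate with a
        # rigid volume translation so the truth is a well-defined target
        shifts = AlignmentParams(shifts, 0.0).gauge_normalized(
            geometry.angles_deg).shifts
        peak = np.abs(shifts).max()
        if peak > shift_range_px:
            shifts *= shift_range_px / peak
    else:
        shifts = np.zeros((n, 2))
    truth = AlignmentParams(shifts, tilt_deg)
    if shift_range_px > 0 or tilt_deg != 0.0:
        out = _misaligned_projections(volume, geometry, shifts, tilt_deg)
    else:
        basis_coeffs = _volume_coeffs(volume, geometry)
        out = np.stack([
            tomo_forward(basis_coeffs, geometry, i).value
            for i in range(n)])
    out = noise.apply(out)
    return ProjectionStack(out, geometry), truth


def _volume_coeffs(volume: np.ndarray, geometry: ProjectionGeometry,
                   levels: int = 3) -> np.ndarray:
    from .diffops import WaveletBasis
    d, h, w = geometry.volume_shape
    basis = WaveletBasis((h, w), levels=levels)
    return np.stack([basis.analyze(volume[i]) for i in range(d)])


def make_ptycho_object(size: int, seed: int = 0,
                       amp_range: tuple[float, float] = (0.6, 1.0),
                       phase_max: float = np.pi / 2) -> np.ndarray:
    """A transmission function with amplitude <= 1 and bounded phase."""
    blobs = make_phantom(PhantomSpec(kind="cell-like-blobs", size=size,
                                     seed=seed))
    blobs2 = make_phantom(PhantomSpec(kind="cell-like-blobs", size=size,
                                      seed=seed + 1))
    amp = amp_range[0] + (amp_range[1] - amp_range[0]) * blobs
    phase = phase_max * (2.0 * blobs2 - 1.0)
    return amp * np.exp(1j * phase)


def simulate_ptycho(obj: np.ndarray, probes: np.ndarray,
                    grid: tuple[int, int, float], jitter_px: float = 0.0,
                    spec: PropagationSpec | None = None,
                    noise: NoiseSpec = NoiseSpec(), seed: int = 0,
                    record_positions: bool = False
                    ) -> tuple[PtychoDataset, dict]:
    """Raster-scan diffraction simulation.

    ``grid`` = (rows, cols, step) in object pixels.  Stage jitter of
    ``jitter_px`` (uniform per axis) perturbs each position; by default the
    dataset stores the nominal (unjittered) positions and the truth record
    the actual ones, emulating unrecorded mechanical errors.  With
    ``record_positions=True`` the dataset stores the actual positions
    (encoder-recorded jitter), which also breaks the raster-grid pathology
    of perfectly periodic scans.
    """
    obj = np.asarray(obj, dtype=np.complex128)
    probes = np.asarray(probes, dtype=np.complex128)
    if probes.ndim == 2:
        probes = probes[None]
    box = probes.shape[-1]
    if spec is None:
        spec = PropagationSpec(regime="farfield", wavelength_m=1e-9,
                               pixel_size_m=5e-8)
    rows, cols, step = grid
    margin = 2.0
    r0 = np.arange(rows) * step + margin
    c0 = np.arange(cols) * step + margin
    nominal = np.array([(r, c) for r in r0 for c in c0], dtype=np.float64)
    if nominal[:, 0].max() + box + margin > obj.shape[0] \
            or nominal[:, 1].max() + box + margin > obj.shape[1]:
        raise ValueError("scan grid does not fit inside the object")
    rng = np.random.default_rng(seed)
    actual = nominal + (rng.uniform(-jitter_px, jitter_px,
                                    size=nominal.shape)
                        if jitter_px > 0 else 0.0)
    cf = ComplexField.from_complex(obj)
    pf = [ComplexField.from_complex(probes[m]) for m in range(len(probes))]
    inten = ptycho_forward_intensity(cf, pf, actual, spec).value
    inten = np.maximum(noise.apply(inten), 0.0)
    stored = actual if record_positions else nominal
    dataset = PtychoDataset(intensities=inten, positions=stored, spec=spec)
    truth = {"positions": actual, "object": obj, "probes": probes,
             "distance_m": spec.distance_m}
    return dataset, truth
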