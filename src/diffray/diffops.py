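"""Differentiable operator primitives for imaging forward models.

Every forward model in the package (compressive sensing, super-resolution,
tomography, ptychography) is composed from the primitives below, each of
which propagates derivatives to all of its real-valued inputs through the
:mod:`diffray.autodiff` engine.

Conventions
-----------
* 0-based pixel indices; sampling at pixel centers; affine origin at the
  image center, so rotation about the volume midpoint is the zero-parameter
  case.
* Interpolation is bilinear with zero padding outside the support.
* Complex fields are carried as explicit (real, imaginary) duplets
  (:class:`ComplexField`), so complex-valued models are differentiated as
  ordinary real functions of the paired coordinates.
* Transforms are orthonormal (DCT-II, centered FFT) so Parseval/unitarity
  hold exactly up to rounding.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
import scipy.fft as sfft
import scipy.ndimage as ndi
import scipy.signal as ssig

from . import autodiff as ad
from .autodiff import Tensor, astensor

__all__ = [
    "ComplexField", "AffineMap", "PropagationSpec", "SamplingMask",
    "cosine_synthesis", "dct2", "idct2",
    "WaveletBasis", "wavelet_synthesis",
    "bilinear_sample", "affine_warp", "rotate_volume",
    "riemann_project", "apply_mask", "blur2d", "downsample",
    "farfield_propagate", "farfield_backpropagate",
    "angular_spectrum_propagate", "subpixel_crop", "safe_sqrt",
]

PLANCK_HC_EV_M = 1.239841984e-6  # h*c in eV*m


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class ComplexField:
    """A 2D complex field stored as a (real, imaginary) duplet of Tensors."""

    __slots__ = ("re", "im")

    def __init__(self, re, im):
        self.re = astensor(re)
        self.im = astensor(im)
        if self.re.shape != self.im.shape:
            raise ValueError("real and imaginary parts must be congruent")

    @classmethod
    def from_complex(cls, z, requires_grad: bool = False) -> "ComplexField":
        z = np.asarray(z, dtype=np.complex128)
        return cls(Tensor(z.real.copy(), requires_grad=requires_grad),
                   Tensor(z.imag.copy(), requires_grad=requires_grad))

    def to_complex(self) -> np.ndarray:
        return self.re.value + 1j * self.im.value

    @property
    def shape(self):
        return self.re.shape

    def conj(self) -> "ComplexField":
        return ComplexField(self.re, -self.im)

    def __mul__(self, other) -> "ComplexField":
        if isinstance(other, ComplexField):
            return ComplexField(self.re * other.re - self.im * other.im,
                                self.re * other.im + self.im * other.re)
        return ComplexField(self.re * other, self.im * other)

    __rmul__ = __mul__

    def __add__(self, other: "ComplexField") -> "ComplexField":
        return ComplexField(self.re + other.re, self.im + other.im)

    def __sub__(self, other: "ComplexField") -> "ComplexField":
        return ComplexField(self.re - other.re, self.im - other.im)

    def abs2(self) -> Tensor:
        """Pointwise squared modulus (a real Tensor)."""
        return self.re * self.re + self.im * self.im

    def modulus(self) -> Tensor:
        """Pointwise modulus with subgradient 0 at the origin."""
        return safe_sqrt(self.abs2())


def safe_sqrt(x: Tensor) -> Tensor:
    """sqrt with derivative defined as 0 where the input is exactly 0."""
    x = astensor(x)
    val = np.sqrt(np.maximum(x.value, 0.0))
    inv = np.where(val > 0, 0.5 / np.where(val > 0, val, 1.0), 0.0)
    return ad.custom(val, [(x, lambda g: g * inv)])


@dataclass(frozen=True)
class AffineMap:
    """A 2x3 affine map on centered pixel coordinates (row, col).

    ``source = A @ out_centered + b`` — the map is a pull-back: it tells the
    resampler where in the input each output pixel reads from.  Content
    motion is therefore the inverse of the stored map.
    """

    matrix: np.ndarray  # shape (2, 3)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if not np.all(np.isfinite(m)):
            raise ValueError("affine matrix must be finite")
        if abs(np.linalg.det(m[:, :2])) <= 1e-12:
            raise ValueError("affine linear part is not invertible")
        object.__setattr__(self, "matrix", m)

    @staticmethod
    def identity() -> "AffineMap":
        return AffineMap(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @staticmethod
    def translation(dr: float, dc: float) -> "AffineMap":
        """Move image content by (+dr, +dc) pixels."""
        return AffineMap(np.array([[1.0, 0.0, -dr], [0.0, 1.0, -dc]]))

    @staticmethod
    def rotation(theta_deg: float, center: tuple[float, float] = (0.0, 0.0)
                 ) -> "AffineMap":
        """Rotate image content by ``theta_deg`` about ``center`` (centered
        coordinates; positive = from +row towards +col axis)."""
        t = np.deg2rad(theta_deg)
        c, s = np.cos(t), np.sin(t)
        rot = np.array([[c, -s], [s, c]])  # inverse rotation (pull-back)
        cr, cc = center
        off = np.array([cr, cc]) - rot @ np.array([cr, cc])
        return AffineMap(np.column_stack([rot, off]))

    def compose(self, other: "AffineMap") -> "AffineMap":
        """Map equivalent to applying ``other`` to the image first, then
        ``self`` (pull-backs compose in reverse)."""
        a, b = self.matrix, other.matrix
        lin = b[:, :2] @ a[:, :2]
        off = b[:, :2] @ a[:, 2] + b[:, 2]
        return AffineMap(np.column_stack([lin, off]))

    def inverse(self) -> "AffineMap":
        lin = np.linalg.inv(self.matrix[:, :2])
        off = -lin @ self.matrix[:, 2]
        return AffineMap(np.column_stack([lin, off]))


@dataclass(frozen=True)
class PropagationSpec:
    """Geometry of a free-space propagation step.

    Parameters
    ----------
    distance_m : propagation distance z in meters.
    wavelength_m : photon wavelength in meters (give this or ``energy_ev``).
    pixel_size_m : detector/object pixel pitch in meters.
    regime : ``"farfield"`` (single Fourier transform) or
        ``"angular-spectrum"`` (transfer-function propagation).
    """

    distance_m: float = 0.0
    wavelength_m: float | None = None
    energy_ev: float | None = None
    pixel_size_m: float = 1.0
    regime: str = "farfield"

    def __post_init__(self):
        if self.wavelength_m is None:
            if self.energy_ev is None:
                raise ValueError("give wavelength_m or energy_ev")
            object.__setattr__(self, "wavelength_m",
                               PLANCK_HC_EV_M / float(self.energy_ev))
        if self.wavelength_m <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel size must be positive")
        if not np.isfinite(self.distance_m):
            raise ValueError("distance must be finite")
        if self.regime not in ("farfield", "angular-spectrum"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class SamplingMask:
    """Boolean measurement support for sparse raster scans."""

    values: np.ndarray
    scheme: str = "regular-stride"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def fraction(self) -> float:
        return float(self.values.mean())

    @property
    def shape(self):
        return self.values.shape


# ---------------------------------------------------------------------------
# orthonormal transforms
# ---------------------------------------------------------------------------

def dct2(image: Tensor) -> Tensor:
    """Orthonormal type-II 2D DCT (analysis)."""
    image = astensor(image)
    if image.ndim != 2:
        raise ValueError("dct2 expects a 2D image")
    return ad.linear_map(
        image,
        lambda v: sfft.dctn(v, type=2, norm="ortho"),
        lambda g: sfft.idctn(g, type=2, norm="ortho"),
    )


def idct2(coeffs: Tensor) -> Tensor:
    """Orthonormal 2D inverse DCT (synthesis of DCT coefficients)."""
    coeffs = astensor(coeffs)
    if coeffs.ndim != 2:
        raise ValueError("idct2 expects a 2D coefficient grid")
    return ad.linear_map(
        coeffs,
        lambda v: sfft.idctn(v, type=2, norm="ortho"),
        lambda g: sfft.dctn(g, type=2, norm="ortho"),
    )


def cosine_synthesis(coeffs: Tensor, inverse: bool = False) -> Tensor:
    """Synthesize an image from DCT coefficients (or analyze, with
    ``inverse=True``); the two calls are exact inverses of each other."""
    return dct2(coeffs) if inverse else idct2(coeffs)


class WaveletBasis:
    """Multi-level 2D wavelet synthesis as an explicit linear operator.

    Coefficients are carried as a flat vector (pywt ``coeffs_to_array``
    ordering).  Synthesis ``coeffs -> image`` is linear; its matrix is
    materialised once per (shape, wavelet, levels, mode) so the adjoint —
    needed for gradient propagation — is exact.  Default family is the
    biorthogonal 4.4 wavelet with symmetric extension.
    """

    def __init__(self, shape: tuple[int, int], levels: int = 3,
                 wavelet: str = "bior4.4", mode: str = "symmetric"):
        h, w = shape
        if levels > int(np.log2(min(h, w))):
            raise ValueError(
                f"{levels} levels exceed log2(min(shape)) for shape {shape}")
        self.shape = (int(h), int(w))
        self.levels = int(levels)
        self.wavelet = wavelet
        self.mode = mode
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            template = pywt.wavedec2(np.zeros(self.shape), wavelet,
                                     mode=mode, level=levels)
        arr, self._slices = pywt.coeffs_to_array(template)
        self._coef_shape = arr.shape
        self.n_coeffs = arr.size
        self.n_pixels = int(h) * int(w)

    # matrix cached per basis signature (shared across instances)
    @staticmethod
    @functools.lru_cache(maxsize=8)
    def _matrix(shape, levels, wavelet, mode, coef_shape):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            template = pywt.wavedec2(np.zeros(shape), wavelet, mode=mode,
                                     level=levels)
        _, slices = pywt.coeffs_to_array(template)
        n = int(np.prod(coef_shape))
        cols = np.empty((shape[0] * shape[1], n))
        e = np.zeros(coef_shape)
        flat = e.reshape(-1)
        for j in range(n):
            flat[j] = 1.0
            coeffs = pywt.array_to_coeffs(e, slices, output_format="wavedec2")
            cols[:, j] = pywt.waverec2(coeffs, wavelet, mode=mode)[
                :shape[0], :shape[1]].reshape(-1)
            flat[j] = 0.0
        return cols

    @property
    def matrix(self) -> np.ndarray:
        return WaveletBasis._matrix(self.shape, self.levels, self.wavelet,
                                    self.mode, self._coef_shape)

    @staticmethod
    @functools.lru_cache(maxsize=8)
    def _matrix_transposed(shape, levels, wavelet, mode, coef_shape):
        return np.ascontiguousarray(WaveletBasis._matrix(
            shape, levels, wavelet, mode, coef_shape).T)

    @property
    def matrix_t(self) -> np.ndarray:
        """Transposed synthesis matrix (coefficients-to-pixels, row layout
        suited to batched per-slice synthesis)."""
        return WaveletBasis._matrix_transposed(self.shape, self.levels,
                                               self.wavelet, self.mode,
                                               self._coef_shape)

    def analyze(self, image: np.ndarray) -> np.ndarray:
        """Image -> flat coefficient vector (plain NumPy; not traced)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            coeffs = pywt.wavedec2(np.asarray(image, dtype=np.float64),
                                   self.wavelet, mode=self.mode,
                                   level=self.levels)
        arr, _ = pywt.coeffs_to_array(coeffs)
        return arr.reshape(-1)

    def synthesize(self, coeffs: Tensor) -> Tensor:
        """Flat coefficient vector (Tensor) -> image (Tensor)."""
        coeffs = astensor(coeffs)
        if coeffs.value.size != self.n_coeffs:
            raise ValueError("coefficient vector length mismatch")
        m = self.matrix
        img = ad.matmul(m, coeffs.ravel())
        return img.reshape(self.shape)

    def synthesize_np(self, coeffs: np.ndarray) -> np.ndarray:
        c = pywt.array_to_coeffs(
            np.asarray(coeffs, dtype=np.float64).reshape(self._coef_shape),
            self._slices, output_format="wavedec2")
        return pywt.waverec2(c, self.wavelet, mode=self.mode)[
            :self.shape[0], :self.shape[1]]


def wavelet_synthesis(coeffs, shape=None, levels: int = 3,
                      wavelet: str = "bior4.4", inverse: bool = False):
    """Multi-level biorthogonal wavelet synthesis (or analysis).

    ``inverse=False``: flat coefficients (Tensor) -> image Tensor;
    ``inverse=True``: image (ndarray) -> flat coefficients ndarray.
    """
    if shape is None:
        raise ValueError("image shape is required for wavelet bookkeeping")
    basis = WaveletBasis(shape, levels=levels, wavelet=wavelet)
    if inverse:
        return basis.analyze(np.asarray(coeffs if not isinstance(coeffs, Tensor)
                                        else coeffs.value))
    return basis.synthesize(coeffs)


# ---------------------------------------------------------------------------
# bilinear resampling and affine geometry
# ---------------------------------------------------------------------------

def bilinear_sample(img: Tensor, rows: Tensor, cols: Tensor) -> Tensor:
    """Sample ``img`` at real-valued (row, col) coordinates, bilinear with
    zero fill outside the support; differentiable in the image and in the
    coordinates.

    Shapes: ``img`` (H, W) gives output ``rows.shape``;
    ``img`` (D, H, W) with 2D coords gives (D,) + coords shape (shared
    coordinates per slice); ``img`` (N, H, W) with coords (N, ...) samples
    item-wise.
    """
    img, rows, cols = astensor(img), astensor(rows), astensor(cols)
    a = img.value
    r, c = rows.value, cols.value
    if r.shape != c.shape:
        raise ValueError("row/col coordinate shapes must match")
    H, W = a.shape[-2], a.shape[-1]

    batched = a.ndim == 3 and r.ndim >= 1 and r.shape[:1] == a.shape[:1] \
        and r.ndim == 3
    shared = a.ndim == 3 and not batched
    if a.ndim not in (2, 3):
        raise ValueError("image must be 2D or 3D")

    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    fr = r - r0
    fc = c - c0

    def corner(dr, dc):
        rr, cc = r0 + dr, c0 + dc
        inside = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        rr_s = np.clip(rr, 0, H - 1)
        cc_s = np.clip(cc, 0, W - 1)
        return rr_s, cc_s, inside.astype(np.float64)

    r00, c00, m00 = corner(0, 0)
    r01, c01, m01 = corner(0, 1)
    r10, c10, m10 = corner(1, 0)
    r11, c11, m11 = corner(1, 1)

    if a.ndim == 2:
        def gather(ri, ci, mi):
            return a[ri, ci] * mi
        batch_idx = None
    elif batched:
        batch_idx = np.arange(a.shape[0])[:, None, None]

        def gather(ri, ci, mi):
            return a[batch_idx, ri, ci] * mi
    else:  # shared coords across leading axis
        def gather(ri, ci, mi):
            return a[:, ri, ci] * mi

    v00 = gather(r00, c00, m00)
    v01 = gather(r01, c01, m01)
    v10 = gather(r10, c10, m10)
    v11 = gather(r11, c11, m11)

    w00 = (1 - fr) * (1 - fc)
    w01 = (1 - fr) * fc
    w10 = fr * (1 - fc)
    w11 = fr * fc
    value = v00 * w00 + v01 * w01 + v10 * w10 + v11 * w11

    corners = ((r00, c00, m00, w00), (r01, c01, m01, w01),
               (r10, c10, m10, w10), (r11, c11, m11, w11))

    def vjp_img(g):
        out = np.zeros_like(a)
        for ri, ci, mi, wi in corners:
            contrib = g * wi * mi
            if a.ndim == 2:
                np.add.at(out, (ri, ci), contrib)
            elif batched:
                np.add.at(out, (batch_idx, ri, ci), contrib)
            else:
                # shared coords: scatter each leading slice at same indices
                for d in range(a.shape[0]):
                    np.add.at(out[d], (ri, ci), contrib[d])
        return out

    # d value / d fractional coordinates
    dv_dr = (v10 - v00) * (1 - fc) + (v11 - v01) * fc
    dv_dc = (v01 - v00) * (1 - fr) + (v11 - v10) * fr

    def reduce_coord(g, d):
        prod = g * d
        if shared:  # coords shared across leading axis: sum it out
            prod = prod.sum(axis=0)
        return prod

    return ad.custom(value, [
        (img, vjp_img),
        (rows, lambda g: reduce_coord(g, dv_dr)),
        (cols, lambda g: reduce_coord(g, dv_dc)),
    ])


def _centered_grid(H: int, W: int):
    rr, cc = np.meshgrid(np.arange(H, dtype=np.float64),
                         np.arange(W, dtype=np.float64), indexing="ij")
    return rr - (H - 1) / 2.0, cc - (W - 1) / 2.0


def affine_warp(image, amap) -> Tensor | ComplexField:
    """Resample ``image`` under an affine map of centered pixel coordinates.

    ``amap`` may be an :class:`AffineMap`, a constant 2x3 array, or a Tensor
    of shape (2, 3) — or (N, 2, 3) for an (N, H, W) stack warped item-wise —
    in which case the warp is differentiable with respect to the map
    parameters as well.  Complex fields are warped part-by-part.
    """
    if isinstance(image, ComplexField):
        return ComplexField(affine_warp(image.re, amap),
                            affine_warp(image.im, amap))
    image = astensor(image)
    if isinstance(amap, AffineMap):
        theta = astensor(amap.matrix)
    else:
        theta = astensor(amap)
    tval = theta.value
    if tval.shape[-2:] != (2, 3):
        raise ValueError("affine parameters must have shape (..., 2, 3)")
    if not np.all(np.abs(np.linalg.det(tval[..., :2, :2])) > 1e-12):
        raise ValueError("affine linear part is not invertible")

    H, W = image.shape[-2], image.shape[-1]
    rr, cc = _centered_grid(H, W)
    rr_t, cc_t = ad.constant(rr), ad.constant(cc)
    r_off, c_off = (H - 1) / 2.0, (W - 1) / 2.0

    if tval.ndim == 2:
        src_r = theta[0, 0] * rr_t + theta[0, 1] * cc_t + theta[0, 2] + r_off
        src_c = theta[1, 0] * rr_t + theta[1, 1] * cc_t + theta[1, 2] + c_off
    else:
        def e(i, j):  # (N,) -> (N,1,1)
            return theta[:, i, j].reshape(-1, 1, 1)
        rr_b, cc_b = ad.constant(rr[None]), ad.constant(cc[None])
        src_r = e(0, 0) * rr_b + e(0, 1) * cc_b + e(0, 2) + r_off
        src_c = e(1, 0) * rr_b + e(1, 1) * cc_b + e(1, 2) + c_off

    return bilinear_sample(image, src_r, src_c)


def rotation_matrix(theta_deg: Tensor, center=(0.0, 0.0)) -> Tensor:
    """In-graph 2x3 pull-back matrix for a content rotation by ``theta_deg``
    about ``center`` (centered coordinates); differentiable in the angle and,
    if the center components are Tensors, in the center too."""
    theta_deg = astensor(theta_deg)
    t = theta_deg * (np.pi / 180.0)
    c, s = ad.cos(t), ad.sin(t)
    cr, cc = astensor(center[0]), astensor(center[1])
    row0 = ad.stack([c, -s, cr - (c * cr - s * cc)])
    row1 = ad.stack([s, c, cc - (s * cr + c * cc)])
    return ad.stack([row0, row1], axis=0)


def rotate_volume(volume, theta_deg, center=(0.0, 0.0)) -> Tensor:
    """Rotate every horizontal slice of a (D, H, W) volume in-plane by the
    same angle about ``center`` (centered coords); differentiable in the
    volume and in the angle."""
    volume = astensor(volume)
    if volume.ndim != 3:
        raise ValueError("rotate_volume expects a 3D (slices, H, W) grid")
    H, W = volume.shape[1], volume.shape[2]
    if abs(center[0]) > (H - 1) / 2.0 or abs(center[1]) > (W - 1) / 2.0:
        raise ValueError("rotation center outside slice bounds")
    theta = rotation_matrix(theta_deg, center)
    return affine_warp(volume, theta)


# ---------------------------------------------------------------------------
# measurement / degradation operators
# ---------------------------------------------------------------------------

def riemann_project(volume, step: float = 1.0) -> Tensor:
    """Line-integral projection: ``step`` times the sum over the beam axis
    (axis 1 of a (slices, rows, cols) volume), giving a (slices, cols)
    detector image.  Exact adjoint: back-smearing along the same axis."""
    volume = astensor(volume)
    if volume.ndim != 3:
        raise ValueError("riemann_project expects a 3D volume")
    if step <= 0:
        raise ValueError("step must be positive")
    return volume.sum(axis=1) * step


def riemann_backproject(projection: np.ndarray, depth: int,
                        step: float = 1.0) -> np.ndarray:
    """Adjoint of :func:`riemann_project` (plain NumPy)."""
    p = np.asarray(projection, dtype=np.float64)
    return np.broadcast_to(p[:, None, :] * step,
                           (p.shape[0], depth, p.shape[1])).copy()


def apply_mask(image, mask) -> Tensor:
    """Keep values where the mask is true, zero elsewhere (idempotent)."""
    image = astensor(image)
    m = mask.values if isinstance(mask, SamplingMask) else np.asarray(mask)
    if m.shape != image.shape:
        raise ValueError(f"mask shape {m.shape} != image shape {image.shape}")
    return image * m.astype(np.float64)


def blur2d(image: Tensor, kernel: Tensor) -> Tensor:
    """Same-size 2D correlation with zero padding; differentiable in both
    the image and the kernel.  Kernel dimensions must be odd."""
    image, kernel = astensor(image), astensor(kernel)
    a, k = image.value, kernel.value
    if a.ndim != 2 or k.ndim != 2:
        raise ValueError("blur2d expects 2D image and kernel")
    if k.shape[0] % 2 == 0 or k.shape[1] % 2 == 0:
        raise ValueError("kernel dimensions must be odd")
    value = ndi.correlate(a, k, mode="constant", cval=0.0)

    def vjp_image(g):
        return ndi.convolve(g, k, mode="constant", cval=0.0)

    def vjp_kernel(g):
        pr, pc = k.shape[0] // 2, k.shape[1] // 2
        a_pad = np.pad(a, ((pr, pr), (pc, pc)))
        return ssig.correlate(a_pad, g, mode="valid", method="auto")

    return ad.custom(value, [(image, vjp_image), (kernel, vjp_kernel)])


def downsample(image: Tensor, factor: int) -> Tensor:
    """factor x factor mean binning, modelling detector pixel integration."""
    image = astensor(image)
    H, W = image.shape
    f = int(factor)
    if H % f or W % f:
        raise ValueError(f"image shape {image.shape} not divisible by {f}")
    a = image.value
    value = a.reshape(H // f, f, W // f, f).mean(axis=(1, 3))

    def vjp(g):
        return np.repeat(np.repeat(g, f, axis=0), f, axis=1) / (f * f)

    return ad.custom(value, [(image, vjp)])


# ---------------------------------------------------------------------------
# wave propagation
# ---------------------------------------------------------------------------

def _fft2c_np(z):
    ax = (-2, -1)
    return sfft.fftshift(sfft.fft2(sfft.ifftshift(z, axes=ax),
                                   norm="ortho", axes=ax), axes=ax)


def _ifft2c_np(z):
    ax = (-2, -1)
    return sfft.fftshift(sfft.ifft2(sfft.ifftshift(z, axes=ax),
                                    norm="ortho", axes=ax), axes=ax)


def _fft2c_pair(xr: Tensor, xi: Tensor, inverse: bool = False):
    """Centered orthonormal 2D (i)FFT on a duplet; batched over leading axes.

    The VJP of a unitary complex-linear map is its inverse applied to the
    complex cotangent.
    """
    fwd = _ifft2c_np if inverse else _fft2c_np
    adj = _fft2c_np if inverse else _ifft2c_np
    Z = fwd(xr.value + 1j * xi.value)
    out_re = ad.custom(Z.real, [
        (xr, lambda g: adj(g).real),
        (xi, lambda g: adj(g).imag),
    ])
    out_im = ad.custom(Z.imag, [
        (xr, lambda g: -adj(g).imag),
        (xi, lambda g: adj(g).real),
    ])
    return out_re, out_im


def farfield_propagate(field: ComplexField) -> ComplexField:
    """Far-field (Fraunhofer) propagation: centered orthonormal 2D Fourier
    transform of the duplet field; conserves total intensity."""
    re, im = _fft2c_pair(field.re, field.im, inverse=False)
    return ComplexField(re, im)


def farfield_backpropagate(field: ComplexField) -> ComplexField:
    """Exact inverse of :func:`farfield_propagate`."""
    re, im = _fft2c_pair(field.re, field.im, inverse=True)
    return ComplexField(re, im)


@functools.lru_cache(maxsize=32)
def _angular_spectrum_kz(shape, wavelength_m, pixel_size_m):
    """z-independent prefactors: 2*pi*k_z per frequency and the mask of
    propagating (non-evanescent) components; cached across iterations."""
    H, W = shape
    fr = sfft.fftshift(sfft.fftfreq(H, d=pixel_size_m))
    fc = sfft.fftshift(sfft.fftfreq(W, d=pixel_size_m))
    f2 = fr[:, None] ** 2 + fc[None, :] ** 2
    arg = 1.0 / wavelength_m ** 2 - f2
    mask = arg > 0
    kz = 2.0 * np.pi * np.sqrt(np.maximum(arg, 0.0))
    return kz, mask.astype(np.float64)


def angular_spectrum_propagate(field: ComplexField, spec: PropagationSpec,
                               z=None) -> ComplexField:
    """Transfer-function (angular-spectrum) propagation.

    The z-independent prefactor 2*pi*k_z per spatial frequency is
    precomputed and cached; at run time only the two transforms and one
    elementwise product remain.  ``z`` may be a Tensor, making the result
    differentiable in the propagation distance; evanescent components are
    suppressed.
    """
    H, W = field.shape[-2], field.shape[-1]
    if H != W:
        raise ValueError("angular spectrum propagation expects square fields")
    kz, mask = _angular_spectrum_kz((H, W), spec.wavelength_m,
                                    spec.pixel_size_m)
    zt = astensor(spec.distance_m if z is None else z)
    phase = zt * ad.constant(kz)
    hr = ad.cos(phase) * mask
    hi = ad.sin(phase) * mask
    Fr, Fi = _fft2c_pair(field.re, field.im, inverse=False)
    Gr = Fr * hr - Fi * hi
    Gi = Fr * hi + Fi * hr
    re, im = _fft2c_pair(Gr, Gi, inverse=True)
    return ComplexField(re, im)


def propagate(field: ComplexField, spec: PropagationSpec, z=None
              ) -> ComplexField:
    """Dispatch on the propagation regime of ``spec``."""
    if spec.regime == "farfield":
        return farfield_propagate(field)
    return angular_spectrum_propagate(field, spec, z=z)


# ---------------------------------------------------------------------------
# differentiable cropping (scan-position model)
# ---------------------------------------------------------------------------

def subpixel_crop(obj, positions, box: tuple[int, int]):
    """Extract box-sized views of ``obj`` at real-valued (row, col) corner
    positions via bilinear resampling; differentiable with respect to the
    object and the positions.

    ``positions`` may be a single (row, col) pair or an (N, 2) Tensor; the
    output is correspondingly (h, w) or (N, h, w).  Complex fields are
    cropped part-by-part.  Positions must keep the box (plus a 1-px
    interpolation margin) inside the object.
    """
    if isinstance(obj, ComplexField):
        return ComplexField(subpixel_crop(obj.re, positions, box),
                            subpixel_crop(obj.im, positions, box))
    obj = astensor(obj)
    positions = astensor(positions)
    h, w = int(box[0]), int(box[1])
    H, W = obj.shape
    pv = np.atleast_2d(positions.value)
    if np.any(pv[:, 0] < 0) or np.any(pv[:, 1] < 0) \
            or np.any(pv[:, 0] + h > H) or np.any(pv[:, 1] + w > W):
        raise ValueError("crop box outside object support")

    single = positions.value.ndim == 1
    pos2 = positions.reshape(-1, 2)
    rows = pos2[:, 0].reshape(-1, 1, 1) + ad.constant(
        np.arange(h, dtype=np.float64)[None, :, None])
    cols = pos2[:, 1].reshape(-1, 1, 1) + ad.constant(
        np.arange(w, dtype=np.float64)[None, None, :])
    rows = rows + ad.constant(np.zeros((1, h, w)))
    cols = cols + ad.constant(np.zeros((1, h, w)))
    out = bilinear_sample(obj, rows, cols)
    if single:
        out = out.reshape(h, w)
    return out
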