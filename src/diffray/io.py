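"""Readers/writers for the on-disk formats and run configuration.

TIFF (single or multipage, 32-bit float) for images, volumes and kernels;
PNG or TIFF for boolean masks; CSV for angle lists and positions; HDF5 for
ptychography datasets with the layout::

    /data       (N, h, w) float intensities
    /positions  (N, 2) float pixels
    attrs: energy_ev | wavelength_m, distance_m, pixel_size_m, regime
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .diffops import PropagationSpec, SamplingMask
from .losses import LossWeights
from .ptycho import PtychoDataset

__all__ = ["read_image_stack", "write_image_stack", "read_mask",
           "write_mask", "read_ptycho_h5", "write_ptycho_h5", "RunConfig",
           "write_manifest"]


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match the expected layout."""


def read_image_stack(path) -> np.ndarray:
    """Read a single- or multi-page TIFF as float64 (2D or 3D)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - delegated parsing
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"unsupported dtype {arr.dtype} in {path}")
    return np.asarray(arr, dtype=np.float64)


def write_image_stack(stack: np.ndarray, path) -> None:
    """Write a 2D image or 3D stack as 32-bit float TIFF."""
    arr = np.asarray(stack, dtype=np.float32)
    if arr.ndim not in (2, 3):
        raise ValueError("only 2D images or 3D stacks are supported")
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def read_mask(path) -> SamplingMask:
    """Read a boolean sampling mask from PNG or TIFF (nonzero = sampled)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A) PNG: any nonzero channel counts
        arr = arr.max(axis=-1)
    return SamplingMask(arr > 0, scheme="custom")


def write_mask(mask: SamplingMask, path) -> None:
    path = Path(path)
    values = mask.values.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, values)
    else:
        iio.imwrite(path, values)


def read_ptycho_h5(path) -> PtychoDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        missing = [k for k in ("data", "positions") if k not in f]
        if missing:
            raise FormatError(f"{path}: missing datasets {missing}")
        data = f["data"][...]
        positions = f["positions"][...]
        attrs = dict(f.attrs)
    needed = [k for k in ("distance_m", "pixel_size_m", "regime")
              if k not in attrs]
    if "energy_ev" not in attrs and "wavelength_m" not in attrs:
        needed.append("energy_ev|wavelength_m")
    if needed:
        raise FormatError(f"{path}: missing attributes {needed}")
    regime = attrs["regime"]
    if isinstance(regime, bytes):
        regime = regime.decode()
    spec = PropagationSpec(
        distance_m=float(attrs["distance_m"]),
        wavelength_m=(float(attrs["wavelength_m"])
                      if "wavelength_m" in attrs else None),
        energy_ev=(float(attrs["energy_ev"])
                   if "energy_ev" in attrs else None),
        pixel_size_m=float(attrs["pixel_size_m"]),
        regime=str(regime),
    )
    return PtychoDataset(intensities=data, positions=positions, spec=spec)


def write_ptycho_h5(dataset: PtychoDataset, path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("data", data=dataset.intensities)
        f.create_dataset("positions", data=dataset.positions)
        f.attrs["distance_m"] = dataset.spec.distance_m
        f.attrs["wavelength_m"] = dataset.spec.wavelength_m
        if dataset.spec.energy_ev is not None:
            f.attrs["energy_ev"] = dataset.spec.energy_ev
        f.attrs["pixel_size_m"] = dataset.spec.pixel_size_m
        f.attrs["regime"] = dataset.spec.regime


@dataclass
class RunConfig:
    """Structured configuration of a CLI run; flags override file values."""

    modality: str = "cs"
    inputs: dict = field(default_factory=dict)
    output_dir: str = "."
    lambda1: float | None = None
    lambda2: float | None = None
    delta: float = 1.0
    method: str = "quasi-newton"
    max_iter: int = 300
    tol: float = 1e-9
    lr: float = 0.02
    seed: int = 0
    refine: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: raw.pop(k) for k in list(raw)
                 if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra.update(raw)
        return cfg

    def weights(self, data_scale: float = 1.0) -> LossWeights:
        l1 = self.lambda1 if self.lambda1 is not None else 1e-3 * data_scale
        l2 = self.lambda2 if self.lambda2 is not None else 1e-2 * data_scale
        return LossWeights(lambda1=l1, lambda2=l2, delta=self.delta)


def write_manifest(path, config: RunConfig, seed: int,
                   loss_trace: np.ndarray | None, wall_time_s: float,
                   outputs: dict) -> None:
    """JSON record sufficient to reproduce a run bitwise (deterministic
    methods): config, seed, trace and the artifact paths written."""
    payload = {
        "config": asdict(config),
        "seed": int(seed),
        "wall_time_s": float(wall_time_s),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    if loss_trace is not None:
        payload["loss_trace"] = [float(v) for v in np.asarray(loss_trace)]
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)
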