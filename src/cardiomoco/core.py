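"""Shared containers and low-level numerics.

Conventions used throughout the package:

* Image axis 0 is foot-head (FH), axis 1 is right-left (RL); an optional
  axis 2 is the long (slice) axis in thin-3D mode.
* Displacement fields are stored in **voxel units** with the vector
  component on the last axis, and warps are pull-backs:
  ``out(x) = in(x + u(x))``.
* k-space uses a centered DFT (origin at the grid center) with
  orthonormal scaling, so the adjoint of the full transform is its
  inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from numpy.fft import fftn, fftshift, ifftn, ifftshift
from scipy.ndimage import map_coordinates


@dataclass
class ImageVolume:
    """A gridded scalar volume with physical voxel spacing (mm)."""

    data: np.ndarray
    spacing: Tuple[float, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError(
                f"spacing has {len(self.spacing)} entries for a "
                f"{self.data.ndim}-D volume"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def voxel_volume(self) -> float:
        """Volume (or area, in 2D) of one voxel in mm^ndim."""
        return float(np.prod(self.spacing))

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing)

    def like(self, data: np.ndarray) -> "ImageVolume":
        """New volume with the same spacing."""
        return ImageVolume(np.asarray(data), self.spacing)


def cfft(img: np.ndarray) -> np.ndarray:
    """Centered orthonormal DFT (image origin and k-space origin at grid center)."""
    return fftshift(fftn(ifftshift(img), norm="ortho"))


def icfft(ksp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cfft`."""
    return fftshift(ifftn(ifftshift(ksp), norm="ortho"))


def grid_coords(shape: Tuple[int, ...]) -> np.ndarray:
    """Integer voxel index grid, shape ``(*shape, ndim)``."""
    axes = [np.arange(n, dtype=float) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def pullback_warp(
    arr: np.ndarray,
    disp: np.ndarray,
    order: int = 1,
    mode: str = "constant",
    cval: float = 0.0,
) -> np.ndarray:
    """Warp ``arr`` by a displacement field: ``out(x) = arr(x + disp(x))``.

    ``disp`` is in voxels with components on the last axis. Linear
    interpolation by default; complex arrays are warped per part.
    """
    disp = np.asarray(disp, dtype=float)
    if disp.shape[:-1] != arr.shape or disp.shape[-1] != arr.ndim:
        raise ValueError("displacement field does not match array shape")
    coords = grid_coords(arr.shape) + disp
    coords = np.moveaxis(coords, -1, 0)
    if np.iscomplexobj(arr):
        re = map_coordinates(arr.real, coords, order=order, mode=mode, cval=cval)
        im = map_coordinates(arr.imag, coords, order=order, mode=mode, cval=cval)
        return re + 1j * im
    return map_coordinates(arr, coords, order=order, mode=mode, cval=cval)


def rng_from_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("an explicit seed is required (no hidden global state)")
    return np.random.default_rng(seed)


def nrmse(x: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square error normalized by the dynamic range of ``ref``."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    rng = float(ref.max() - ref.min())
    if rng == 0:
        raise ValueError("reference has zero dynamic range")
    return float(np.sqrt(np.mean((x - ref) ** 2)) / rng)


def rmse(x: np.ndarray, ref: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.abs(np.asarray(x) - np.asarray(ref)) ** 2)))
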