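"""Volume containers and grid operations.

The pipeline consumes two co-registered 3-D probability volumes per scan
(ICH and drain, values in [0, 1]) plus optional binary ground-truth masks,
all in NIfTI-1 format with possibly anisotropic voxels.  Everything
geometric downstream (distances, moments, profiles) is computed in world
millimetres through the affine, so anisotropy is handled once, here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "ProbabilityVolume",
    "BinaryMask",
    "read_probability_volume",
    "read_binary_mask",
    "write_volume",
    "resample_isotropic",
    "threshold",
]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
        raise ValueError("affine must be a finite 4x4 matrix")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("degenerate affine (zero volume element)")
    return affine


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass
class ProbabilityVolume:
    """3-D scalar grid of per-voxel probabilities with world geometry.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Probabilities, dimensionless, clipped to [0, 1].
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm map (RAS convention).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.affine = _check_affine(self.affine)
        lo, hi = self.data.min(), self.data.max()
        if lo < -1e-6 or hi > 1 + 1e-6:
            logger.warning(
                "probability values outside [0,1] (min=%g, max=%g); clipping",
                lo, hi,
            )
        np.clip(self.data, 0.0, 1.0, out=self.data)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def world_coords(self, index_grid: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm."""
        idx = np.asarray(index_grid, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class BinaryMask:
    """3-D boolean grid sharing the geometry conventions of its volume."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def world_coords(self, index_grid: np.ndarray) -> np.ndarray:
        idx = np.asarray(index_grid, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def _load_3d(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # tolerate trailing singleton dims ((x, y, z, 1) is common)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    if img.affine is None:
        raise ValueError(f"missing affine in {path}")
    return np.asarray(data, dtype=np.float64), np.asarray(img.affine, dtype=float)


def read_probability_volume(path) -> ProbabilityVolume:
    """Read a NIfTI probability map; values are clipped to [0, 1].

    Clipping beyond a tolerance of 1e-3 is logged as a warning.
    Raises ``ValueError`` for non-3D images or degenerate affines.
    """
    data, affine = _load_3d(path)
    return ProbabilityVolume(data, affine)


def read_binary_mask(path, thresh: float = 0.5) -> BinaryMask:
    """Read a NIfTI label/mask image and binarize at ``thresh``."""
    data, affine = _load_3d(path)
    return BinaryMask(data >= thresh, affine)


def write_volume(vol: ProbabilityVolume | BinaryMask, path) -> None:
    """Write a volume/mask to NIfTI, preserving its affine."""
    data = vol.data.astype(np.float32) if isinstance(vol, ProbabilityVolume) \
        else vol.data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def _interp_axis(data: np.ndarray, coords: np.ndarray, axis: int,
                 order: int) -> np.ndarray:
    """1-D linear/nearest interpolation of ``data`` along ``axis`` at
    fractional index positions ``coords`` (edge-clamped)."""
    n = data.shape[axis]
    if order == 0:
        idx = np.clip(np.round(coords).astype(int), 0, n - 1)
        return np.take(data, idx, axis=axis)
    lo = np.clip(np.floor(coords).astype(int), 0, n - 1)
    hi = np.minimum(lo + 1, n - 1)
    frac = np.clip(coords - lo, 0.0, 1.0)
    shape = [1, 1, 1]
    shape[axis] = len(coords)
    frac = frac.reshape(shape)
    return (np.take(data, lo, axis=axis) * (1.0 - frac)
            + np.take(data, hi, axis=axis) * frac)


def _resample(data: np.ndarray, affine: np.ndarray, target_mm: float,
              order: int) -> tuple[np.ndarray, np.ndarray]:
    # the output grid is a tensor product of per-axis index positions,
    # so trilinear (or nearest) interpolation factorizes into three 1-D
    # passes — much cheaper than a dense coordinate map
    spacing = _spacing_from_affine(affine)
    out = data.astype(np.float64)
    for axis in range(3):
        n_new = int(np.ceil((data.shape[axis] - 1) * spacing[axis] / target_mm)) + 1
        coords = np.arange(n_new) * (target_mm / spacing[axis])
        if n_new == data.shape[axis] and np.allclose(coords, np.arange(n_new)):
            continue
        out = _interp_axis(out, coords, axis, order)
    scale = np.diag(list(target_mm / spacing) + [1.0])
    return out, affine @ scale


def resample_isotropic(vol: ProbabilityVolume | BinaryMask, target_mm: float,
                       interp: str = "linear"):
    """Resample a volume to ``target_mm`` isotropic spacing.

    Parameters
    ----------
    vol : ProbabilityVolume or BinaryMask
    target_mm : float
        Target voxel edge length in mm (> 0).
    interp : {"linear", "nearest"}
        Linear for probability maps, nearest for label masks.

    The world extent is preserved to within one voxel: the output grid
    keeps voxel (0,0,0) at the same world position and covers the input
    field of view.  Linear interpolation cannot leave [0, 1].
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interp {interp!r}")
    order = 1 if interp == "linear" else 0
    if isinstance(vol, BinaryMask):
        out, new_affine = _resample(vol.data.astype(float), vol.affine,
                                    target_mm, order)
        return BinaryMask(out >= 0.5, new_affine)
    out, new_affine = _resample(vol.data, vol.affine, target_mm, order)
    return ProbabilityVolume(out, new_affine)


def threshold(vol: ProbabilityVolume, t: float) -> BinaryMask:
    """Binarize a probability volume at ``t`` (inclusive: true where p >= t).

    Inclusive comparison keeps the upper sweep value 0.99 usable when the
    segmentation saturates near 0.99.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    return BinaryMask(vol.data >= t, vol.affine)
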