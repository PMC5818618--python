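"""NIfTI volume/mask I/O and the voxel-set abstraction used by feature code.

Volumes are 3D scalar grids in Hounsfield units (HU) with per-axis voxel
spacing in mm taken from the NIfTI header. Masks are binary grids on the same
geometry. Feature extraction operates on native (possibly anisotropic) grids;
no resampling is performed, and spacing enters wherever physical units matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "RoiMask", "read_volume", "read_mask", "write_volume", "roi_voxels"]

#: spacing agreement tolerance between a mask and its volume, in mm
SPACING_TOL_MM = 1e-4


@dataclass
class ImageVolume:
    """A 3D scalar image in HU with voxel spacing (dx, dy, dz) in mm.

    Axes are ordered (x, y, z) with 0-based indices; the world origin is kept
    only for round-tripping and plays no role in feature computation.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class RoiMask:
    """Binary region-of-interest mask sharing its volume's grid geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) != 0)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path.name}, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing {zooms} in {path.name}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI-1 CT volume; HU values and header spacing are preserved."""
    data, spacing, origin = _load_nifti(path)
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def read_mask(path: str | Path, volume: ImageVolume) -> RoiMask:
    """Read a mask and validate its geometry against ``volume``.

    Any nonzero voxel is foreground. Shape must match exactly; spacing must
    agree within ``SPACING_TOL_MM``.
    """
    data, spacing, origin = _load_nifti(path)
    if data.shape != volume.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match volume shape {volume.shape}"
        )
    if any(abs(a - b) > SPACING_TOL_MM for a, b in zip(spacing, volume.spacing)):
        raise ValueError(
            f"mask spacing {spacing} does not match volume spacing {volume.spacing}"
        )
    return RoiMask(data=data, spacing=volume.spacing, origin=volume.origin)


def write_volume(obj: ImageVolume | RoiMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1 with a diagonal affine from spacing."""
    affine = np.diag(list(obj.spacing) + [1.0])
    affine[:3, 3] = obj.origin
    data = obj.data.astype(np.float64) if isinstance(obj, ImageVolume) else obj.data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(obj.spacing)
    nib.save(img, str(path))


def roi_voxels(volume: ImageVolume, mask: RoiMask) -> list[tuple[tuple[int, int, int], float]]:
    """Foreground voxels as ((i, j, k), HU) in lexicographic index order."""
    if mask.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    if mask.n_voxels == 0:
        raise ValueError("empty ROI")
    idx = np.argwhere(mask.data)  # argwhere is C-ordered, i.e. lexicographic
    vals = volume.data[mask.data]
    return [(tuple(int(v) for v in ijk), float(hu)) for ijk, hu in zip(idx, vals)]


def roi_values(volume: ImageVolume, mask: RoiMask) -> np.ndarray:
    """HU values of the foreground voxels (lexicographic order), as an array."""
    if mask.n_voxels == 0:
        raise ValueError("empty ROI")
    return volume.data[mask.data]
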