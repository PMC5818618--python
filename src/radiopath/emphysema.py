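"""Lung segmentation and emphysema quantification on inspiratory CT.

Emphysema is defined as lung voxels with attenuation of -950 HU or less
(inclusive threshold). Normal lung volume is total (or per-side) lung volume
minus the corresponding emphysema volume, so the two always sum exactly to
the lung volume. Eleven parenchymal features are produced per scan:
total/right/left lung volume, total/right/left emphysema volume, overall and
per-side emphysema index, normal lung volume and normal lung percentage.

The segmenter is a phantom-grade threshold procedure (air-density voxels not
connected to the image border, two largest 26-connected components split
left/right by centroid x). Real-chest robustness — airway and vessel removal,
separation of touching lungs — is deliberately out of scope: the feature
definitions, not the segmenter, are the content here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import ImageVolume, RoiMask

__all__ = ["LungMasks", "segment_lungs", "emphysema_features", "EMPHYSEMA_FEATURE_NAMES"]

#: HU at or below which a lung voxel counts as emphysema (inclusive)
EMPHYSEMA_HU = -950.0
#: HU below which a voxel is a lung-candidate during segmentation
LUNG_HU = -300.0

EMPHYSEMA_FEATURE_NAMES: tuple[str, ...] = (
    "total_lung_volume_ml",
    "right_lung_volume_ml",
    "left_lung_volume_ml",
    "total_emphysema_volume_ml",
    "right_emphysema_volume_ml",
    "left_emphysema_volume_ml",
    "emphysema_index_pct",
    "right_emphysema_index_pct",
    "left_emphysema_index_pct",
    "normal_lung_volume_ml",
    "normal_lung_pct",
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LungMasks:
    """Disjoint left/right lung masks on the volume's grid."""

    left: RoiMask
    right: RoiMask


def segment_lungs(volume: ImageVolume) -> LungMasks:
    """Threshold + connected-component lung segmentation.

    Voxels below -300 HU that are not connected to the volume border are lung
    candidates; the two largest 26-connected components become the lungs,
    assigned left/right by centroid x-coordinate (left = smaller x).
    """
    air = volume.data < LUNG_HU
    labeled, n = ndimage.label(air, structure=_STRUCT_26)
    if n < 2:
        raise ValueError("lung segmentation failed: fewer than two lung components")
    border_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labeled, sl, axis=axis)
            border_labels.update(np.unique(face[face > 0]).tolist())
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
    interior = [(int(sz), lab) for lab, sz in zip(range(1, n + 1), sizes) if lab not in border_labels]
    if len(interior) < 2:
        raise ValueError("lung segmentation failed: fewer than two lung components")
    interior.sort(reverse=True)
    (sz_a, lab_a), (sz_b, lab_b) = interior[:2]
    mask_a, mask_b = labeled == lab_a, labeled == lab_b
    cx_a = ndimage.center_of_mass(mask_a)[0]
    cx_b = ndimage.center_of_mass(mask_b)[0]
    left_m, right_m = (mask_a, mask_b) if cx_a < cx_b else (mask_b, mask_a)
    return LungMasks(
        left=RoiMask(left_m, volume.spacing, volume.origin),
        right=RoiMask(right_m, volume.spacing, volume.origin),
    )


def emphysema_features(volume: ImageVolume, lungs: LungMasks) -> dict[str, float]:
    """The 11 parenchymal features in ml and percent."""
    vox_ml = volume.voxel_volume_mm3 / 1000.0

    def side(mask: RoiMask) -> tuple[float, float]:
        n = mask.n_voxels
        if n == 0:
            raise ValueError("empty lung mask")
        hu = volume.data[mask.data]
        emph = int((hu <= EMPHYSEMA_HU).sum())
        return n * vox_ml, emph * vox_ml

    left_vol, left_emph = side(lungs.left)
    right_vol, right_emph = side(lungs.right)
    total_vol = left_vol + right_vol
    total_emph = left_emph + right_emph
    normal_vol = total_vol - total_emph
    return {
        "total_lung_volume_ml": total_vol,
        "right_lung_volume_ml": right_vol,
        "left_lung_volume_ml": left_vol,
        "total_emphysema_volume_ml": total_emph,
        "right_emphysema_volume_ml": right_emph,
        "left_emphysema_volume_ml": left_emph,
        "emphysema_index_pct": 100.0 * total_emph / total_vol,
        "right_emphysema_index_pct": 100.0 * right_emph / right_vol,
        "left_emphysema_index_pct": 100.0 * left_emph / left_vol,
        "normal_lung_volume_ml": normal_vol,
        "normal_lung_pct": 100.0 * normal_vol / total_vol,
    }
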