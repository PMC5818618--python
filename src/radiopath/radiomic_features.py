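"""Quantitative CT tumor features: 52 features in six categories.

The feature set covers six categories — global, histogram-based, lung
cancer-specific, shape, local (gray-level co-occurrence matrix, GLCM) and
regional (gray-level size-zone matrix, GLSZM). The exact 52-name roster is
frozen in :data:`FEATURE_CATEGORIES`; it assembles every feature named in the
source analyses (volume, mass, energy, range, minimum, HU percentiles,
kurtosis, IQR, MPP, maximum 3D diameter, spherical disproportion, surface
area, cluster prominence/shade, maximum probability, size-zone variability,
intensity variability) and completes each category with the standard
first-order / Haralick / size-zone statistics of the same taxonomy.

Conventions
-----------
* Texture matrices use equal-width discretization over the ROI's own HU
  range (default 32 bins), 13 symmetric 3D directions at distance 1 for the
  GLCM, and 26-connectivity for GLSZM zones.
* Histogram ``energy`` is the uniformity form sum(p_i^2) over the discretized
  histogram (1 for a homogeneous ROI); the sum-of-squared-intensities variant
  is available via :class:`ExtractionConfig`.
* Undefined values (MPP with no positive voxels, skewness/kurtosis or GLCM
  correlation of a constant ROI) are reported as NaN missing markers, never
  silently as 0.
* Surface area counts exposed voxel faces weighted by physical face area;
  this is exact for box phantoms and carries a documented staircase bias for
  curved surfaces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .image_io import ImageVolume, RoiMask, roi_values

__all__ = [
    "ExtractionConfig",
    "FeatureVector",
    "GlcMatrix",
    "GlszMatrix",
    "FEATURE_CATEGORIES",
    "TUMOR_FEATURE_NAMES",
    "discretize",
    "global_features",
    "histogram_features",
    "mpp",
    "lung_cancer_specific_features",
    "shape_features",
    "glcm",
    "glcm_features",
    "glszm",
    "glszm_features",
    "extract_all",
]

MISSING = float("nan")

# The 13 unique 3D direction vectors at Chebyshev distance 1 (half of the 26
# neighbors; the other half are their negations, covered by symmetrization).
GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3) if off > (0, 0, 0)
)

_GLOBAL = ["volume_ml", "mass_g"]
_HISTOGRAM = [
    "mean", "sd", "minimum", "maximum", "range", "energy", "entropy",
    "kurtosis", "skewness", "iqr", "hu_p2_5", "hu_p25", "median", "hu_p75",
    "hu_p97_5",
]
_LUNG_CANCER_SPECIFIC = [
    "mpp", "pct_positive_voxels", "pct_air_voxels", "pct_soft_tissue_voxels",
    "solid_volume_ml",
]
_SHAPE = [
    "surface_area_mm2", "max_3d_diameter_mm", "spherical_disproportion",
    "sphericity", "surface_to_volume_ratio", "compactness1", "compactness2",
]
_LOCAL = [
    "autocorrelation", "cluster_prominence", "cluster_shade", "contrast",
    "correlation", "difference_entropy", "dissimilarity", "glcm_energy",
    "glcm_entropy", "homogeneity", "inverse_difference",
    "maximum_probability", "sum_average", "sum_entropy", "sum_variance",
]
_REGIONAL = [
    "small_zone_emphasis", "large_zone_emphasis",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "size_zone_variability", "intensity_variability", "zone_percentage",
    "zone_entropy",
]

#: frozen feature-name → category map; exactly 52 entries in six categories
FEATURE_CATEGORIES: dict[str, str] = {
    **{n: "global" for n in _GLOBAL},
    **{n: "histogram" for n in _HISTOGRAM},
    **{n: "lung_cancer_specific" for n in _LUNG_CANCER_SPECIFIC},
    **{n: "shape" for n in _SHAPE},
    **{n: "local" for n in _LOCAL},
    **{n: "regional" for n in _REGIONAL},
}
TUMOR_FEATURE_NAMES: tuple[str, ...] = tuple(FEATURE_CATEGORIES)
assert len(TUMOR_FEATURE_NAMES) == 52


@dataclass
class ExtractionConfig:
    """Tunable options for tumor feature extraction.

    n_bins
        Bin count for ROI-relative equal-width discretization used by the
        histogram energy/entropy and by the GLCM/GLSZM (default 32).
    energy_variant
        ``"uniformity"`` (sum of squared histogram probabilities, default) or
        ``"sum_squares"`` (sum of squared HU values).
    """

    n_bins: int = 32
    energy_variant: str = "uniformity"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.energy_variant not in ("uniformity", "sum_squares"):
            raise ValueError(f"unknown energy variant {self.energy_variant!r}")


@dataclass
class FeatureVector:
    """Named feature values with their category tags; NaN marks missing."""

    values: dict[str, float]
    categories: dict[str, str] = field(default_factory=dict)

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cat in self.categories.values():
            out[cat] = out.get(cat, 0) + 1
        return out


@dataclass
class GlcMatrix:
    """Offset-averaged symmetric gray-level co-occurrence matrix."""

    counts: np.ndarray
    n_levels: int
    offsets: tuple[tuple[int, int, int], ...]
    normalized: bool


@dataclass
class GlszMatrix:
    """Gray-level size-zone matrix: counts[g-1, s-1] zones of level g, size s."""

    counts: np.ndarray
    n_levels: int
    connectivity: int = 26

    @property
    def n_zones(self) -> int:
        return int(self.counts.sum())


def discretize(hu_values: np.ndarray, n_bins: int) -> np.ndarray:
    """Map values to integer levels 1..n_bins via equal-width bins.

    Bins span [min, max] of the input; the maximum maps to ``n_bins``; a
    constant input maps everything to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = np.asarray(hu_values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot discretize an empty value set")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones(v.shape, dtype=np.int64)
    levels = np.floor((v - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    return np.clip(levels, 1, n_bins)


def global_features(volume: ImageVolume, mask: RoiMask) -> dict[str, float]:
    """Tumor volume (ml) and mass (g) from voxel count and HU-derived density.

    Density per voxel is (HU + 1000)/1000 g/cm^3 (water = 0 HU → 1 g/cm^3),
    clipped below at zero.
    """
    hu = roi_values(volume, mask)
    voxel_ml = volume.voxel_volume_mm3 / 1000.0
    volume_ml = hu.size * voxel_ml
    density = np.clip((hu + 1000.0) / 1000.0, 0.0, None)  # g/cm^3
    mass_g = float(density.sum() * voxel_ml)  # 1 ml = 1 cm^3
    return {"volume_ml": float(volume_ml), "mass_g": mass_g}


def histogram_features(hu_values: np.ndarray, config: ExtractionConfig | None = None) -> dict[str, float]:
    """First-order statistics of the ROI intensity distribution."""
    config = config or ExtractionConfig()
    v = np.asarray(hu_values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty ROI")
    constant = v.max() == v.min()

    levels = discretize(v, config.n_bins)
    p = np.bincount(levels, minlength=config.n_bins + 1)[1:] / v.size
    p_nz = p[p > 0]
    if config.energy_variant == "uniformity":
        energy = float(np.sum(p * p))
    else:
        energy = float(np.sum(v * v))
    entropy = float(-(p_nz * np.log2(p_nz)).sum())

    q2_5, q25, q50, q75, q97_5 = np.percentile(v, [2.5, 25, 50, 75, 97.5])
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "range": float(v.max() - v.min()),
        "energy": energy,
        "entropy": entropy,
        "kurtosis": MISSING if constant else float(_kurtosis(v, fisher=True, bias=True)),
        "skewness": MISSING if constant else float(_skew(v, bias=True)),
        "iqr": float(q75 - q25),
        "hu_p2_5": float(q2_5),
        "hu_p25": float(q25),
        "median": float(q50),
        "hu_p75": float(q75),
        "hu_p97_5": float(q97_5),
    }


def mpp(hu_values: np.ndarray) -> float:
    """Mean value of positive pixels: mean HU over voxels strictly > 0 HU.

    Returns NaN (missing) when the ROI has no positive voxel.
    """
    v = np.asarray(hu_values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty ROI")
    pos = v[v > 0]
    return float(pos.mean()) if pos.size else MISSING


def lung_cancer_specific_features(
    hu_values: np.ndarray, voxel_volume_mm3: float
) -> dict[str, float]:
    """MPP and composition fractions of the tumor ROI.

    Air-like voxels are <= -400 HU; soft tissue is (-100, 100] HU; the solid
    volume is the physical volume of voxels above -400 HU. All fractions are
    defined for any non-empty ROI; only MPP can be missing.
    """
    v = np.asarray(hu_values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty ROI")
    n = v.size
    return {
        "mpp": mpp(v),
        "pct_positive_voxels": 100.0 * float((v > 0).sum()) / n,
        "pct_air_voxels": 100.0 * float((v <= -400).sum()) / n,
        "pct_soft_tissue_voxels": 100.0 * float(((v > -100) & (v <= 100)).sum()) / n,
        "solid_volume_ml": float((v > -400).sum()) * voxel_volume_mm3 / 1000.0,
    }


def _exposed_face_area(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    dx, dy, dz = spacing
    face_area = (dy * dz, dx * dz, dx * dy)
    m = mask.astype(bool)
    total = 0.0
    for axis in range(3):
        # compare against shifted copies; outside the grid counts as background
        fwd = np.pad(m, [(0, 1) if a == axis else (0, 0) for a in range(3)])[
            tuple(slice(1, None) if a == axis else slice(None) for a in range(3))
        ]
        bwd = np.pad(m, [(1, 0) if a == axis else (0, 0) for a in range(3)])[
            tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))
        ]
        exposed = (m & ~fwd).sum() + (m & ~bwd).sum()
        total += float(exposed) * face_area[axis]
    return total


def _max_diameter_mm(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    coords = np.argwhere(mask).astype(np.float64) * np.asarray(spacing)
    if len(coords) == 1:
        return 0.0
    if len(coords) > 400:
        # the farthest pair lies on the convex hull of the voxel centers
        try:
            hull = ConvexHull(coords)
            coords = coords[hull.vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(coords).max())


def shape_features(mask: RoiMask, spacing: tuple[float, float, float] | None = None) -> dict[str, float]:
    """Morphology of the tumor mask in physical units.

    Surface area sums exposed voxel faces (a face is exposed when its
    6-neighbor is background or outside the grid), each weighted by its
    physical area. Spherical disproportion is A / (4*pi*r^2) with r the
    radius of the equal-volume sphere; sphericity is its reciprocal.
    """
    spacing = spacing or mask.spacing
    m = mask.data
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty ROI")
    dx, dy, dz = spacing
    vol_mm3 = n * dx * dy * dz
    area_mm2 = _exposed_face_area(m, spacing)
    r_equiv = (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphere_area = 4.0 * np.pi * r_equiv**2
    disproportion = area_mm2 / sphere_area
    return {
        "surface_area_mm2": area_mm2,
        "max_3d_diameter_mm": _max_diameter_mm(m, spacing),
        "spherical_disproportion": disproportion,
        "sphericity": 1.0 / disproportion,
        "surface_to_volume_ratio": area_mm2 / vol_mm3,
        "compactness1": vol_mm3 / (np.sqrt(np.pi) * area_mm2**1.5),
        "compactness2": 36.0 * np.pi * vol_mm3**2 / area_mm2**3,
    }


def glcm(
    levels_volume: np.ndarray,
    mask: np.ndarray,
    offsets: tuple[tuple[int, int, int], ...] = GLCM_OFFSETS,
    n_levels: int = 32,
) -> GlcMatrix:
    """Co-occurrence matrix over in-mask voxel pairs.

    Each offset's count matrix is symmetrized (the offset and its negation),
    normalized to sum 1, then the per-offset probability matrices are
    averaged. Offsets yielding no valid pair are dropped from the average.
    """
    lv = np.asarray(levels_volume, dtype=np.int64)
    m = np.asarray(mask, dtype=bool)
    per_offset: list[np.ndarray] = []
    for off in offsets:
        src = tuple(slice(max(-o, 0), lv.shape[a] - max(o, 0)) for a, o in enumerate(off))
        dst = tuple(slice(max(o, 0), lv.shape[a] + min(o, 0)) for a, o in enumerate(off))
        valid = m[src] & m[dst]
        if not valid.any():
            continue
        i = lv[src][valid] - 1
        j = lv[dst][valid] - 1
        counts = np.zeros((n_levels, n_levels), dtype=np.float64)
        np.add.at(counts, (i, j), 1.0)
        counts = counts + counts.T  # symmetrize: offset + negation
        per_offset.append(counts / counts.sum())
    if not per_offset:
        raise ValueError("no co-occurrences: ROI has fewer than 2 adjacent voxels")
    p = np.mean(per_offset, axis=0)
    return GlcMatrix(counts=p, n_levels=n_levels, offsets=tuple(offsets), normalized=True)


def glcm_features(matrix: GlcMatrix) -> dict[str, float]:
    """Haralick-style statistics of a normalized symmetric GLCM."""
    if not matrix.normalized or abs(matrix.counts.sum() - 1.0) > 1e-6:
        raise ValueError("GLCM must be normalized")
    p = matrix.counts
    n = matrix.n_levels
    levels = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((levels * px).sum())
    var_x = float(((levels - mu_x) ** 2 * px).sum())
    sd_x = np.sqrt(var_x)
    # symmetric matrix → marginal y statistics equal marginal x statistics
    autocorr = float((ii * jj * p).sum())
    correlation = MISSING if sd_x == 0 else (autocorr - mu_x * mu_x) / var_x

    k_sum = np.arange(2, 2 * n + 1, dtype=np.float64)
    p_sum = np.zeros(k_sum.size)
    k_diff = np.arange(0, n, dtype=np.float64)
    p_diff = np.zeros(k_diff.size)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    sum_avg = float((k_sum * p_sum).sum())
    nz_s, nz_d = p_sum[p_sum > 0], p_diff[p_diff > 0]
    p_nz = p[p > 0]

    return {
        "autocorrelation": autocorr,
        "cluster_prominence": float(((ii + jj - 2 * mu_x) ** 4 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu_x) ** 3 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": correlation,
        "difference_entropy": float(-(nz_d * np.log2(nz_d)).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "glcm_energy": float((p * p).sum()),
        "glcm_entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "maximum_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": float(-(nz_s * np.log2(nz_s)).sum()),
        "sum_variance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
    }


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm(levels_volume: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> GlszMatrix:
    """Size-zone matrix: 26-connected zones of equal level within the mask."""
    lv = np.asarray(levels_volume, dtype=np.int64)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty ROI")
    max_size = int(m.sum())
    counts = np.zeros((n_levels, max_size), dtype=np.float64)
    for g in np.unique(lv[m]):
        labeled, n_zones = ndimage.label((lv == g) & m, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n_zones + 1))
        for s in sizes.astype(int):
            counts[g - 1, s - 1] += 1
    return GlszMatrix(counts=counts, n_levels=n_levels)


def glszm_features(matrix: GlszMatrix) -> dict[str, float]:
    """Regional texture statistics of a size-zone matrix."""
    c = matrix.counts
    n_zones = c.sum()
    if n_zones < 1:
        raise ValueError("size-zone matrix has no zones")
    g = np.arange(1, c.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, c.shape[1] + 1, dtype=np.float64)[None, :]
    by_size = c.sum(axis=0)
    by_level = c.sum(axis=1)
    n_voxels = float((c * s).sum())
    p = c[c > 0] / n_zones
    return {
        "small_zone_emphasis": float((c / s**2).sum() / n_zones),
        "large_zone_emphasis": float((c * s**2).sum() / n_zones),
        "low_gray_level_zone_emphasis": float((c / g**2).sum() / n_zones),
        "high_gray_level_zone_emphasis": float((c * g**2).sum() / n_zones),
        "size_zone_variability": float((by_size**2).sum() / n_zones),
        "intensity_variability": float((by_level**2).sum() / n_zones),
        "zone_percentage": float(n_zones / n_voxels),
        "zone_entropy": float(-(p * np.log2(p)).sum()),
    }


def extract_all(
    volume: ImageVolume, mask: RoiMask, config: ExtractionConfig | None = None
) -> FeatureVector:
    """Compute the full 52-feature tumor vector for one volume/mask pair."""
    config = config or ExtractionConfig()
    if mask.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    if mask.n_voxels == 0:
        raise ValueError("empty ROI")
    hu = roi_values(volume, mask)
    values: dict[str, float] = {}

    def _run(name: str, fn, *args, **kwargs):
        try:
            values.update(fn(*args, **kwargs))
        except Exception as exc:
            raise RuntimeError(f"feature group {name!r} failed: {exc}") from exc

    _run("global", global_features, volume, mask)
    _run("histogram", histogram_features, hu, config)
    _run("lung_cancer_specific", lung_cancer_specific_features, hu, volume.voxel_volume_mm3)
    _run("shape", shape_features, mask)

    lv = np.zeros(volume.shape, dtype=np.int64)
    lv[mask.data] = discretize(hu, config.n_bins)
    try:
        gm = glcm(lv, mask.data, n_levels=config.n_bins)
        values.update(glcm_features(gm))
    except ValueError as exc:  # single-voxel ROI: no pairs
        if "no co-occurrences" not in str(exc):
            raise RuntimeError(f"feature group 'local' failed: {exc}") from exc
        values.update({name: MISSING for name in _LOCAL})
    _run("regional", lambda: glszm_features(glszm(lv, mask.data, n_levels=config.n_bins)))

    assert set(values) == set(TUMOR_FEATURE_NAMES)
    return FeatureVector(values={k: values[k] for k in TUMOR_FEATURE_NAMES},
                         categories=dict(FEATURE_CATEGORIES))
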