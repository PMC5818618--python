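"""Synthetic phantoms and cohorts with known ground truth.

No imaging or sequencing data are distributed with the analysis this package
implements, so every pipeline stage is exercised on synthetic inputs whose
generating truth is known:

* textured ellipsoidal tumor phantoms in HU on a dark (lung-density)
  background, for the 52-feature extractor;
* two-lung phantoms with a controllable fraction of voxels at −1000 HU, for
  the −950 HU emphysema rule;
* cohorts whose feature vectors drive pathway-alteration labels through a
  known logistic model and survival through a known Weibull
  proportional-hazards model, with a mutation table emitted so that the
  pathway-mapping rule reproduces the generating labels exactly.

Default cohort conditions mirror the 57-patient surgical SQCC cohort the
pipeline was designed around: prevalences 36.8/80.7/56.1/24.6/49.1% for the
five pathways, Table-1-style clinical margins, about one third of patients
with a recurrence event. All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ALL_FEATURE_CATEGORIES, CLINICAL_FEATURE_NAMES
from .emphysema import EMPHYSEMA_FEATURE_NAMES
from .genomics import PATHWAYS, MutationTable, PathwayMap, default_pathway_map
from .image_io import ImageVolume, RoiMask
from .radiomic_features import TUMOR_FEATURE_NAMES

__all__ = [
    "PhantomSpec",
    "LungPhantomSpec",
    "CohortSpec",
    "make_tumor_phantom",
    "make_lung_phantom",
    "lung_phantom_truth",
    "simulate_cohort",
    "demo_clinical_table",
    "demo_mutation_table",
]


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    semi_axes_mm: tuple[float, float, float],
) -> np.ndarray:
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semi_axes_mm))
    return q <= 1.0


@dataclass
class PhantomSpec:
    """Ellipsoidal tumor phantom: geometry, HU texture and determinism seed."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes_mm: tuple[float, float, float] = (12.0, 10.0, 8.0)
    center_mm: tuple[float, float, float] | None = None  # default: grid center
    base_hu: float = 30.0
    texture_sd: float = 40.0
    core_fraction: float = 0.0  # fraction of the semi-axes forming a low-HU core
    background_hu: float = -800.0
    seed: int = 0

    def resolved_center(self) -> tuple[float, float, float]:
        if self.center_mm is not None:
            return self.center_mm
        return tuple((n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing))


def make_tumor_phantom(spec: PhantomSpec) -> tuple[ImageVolume, RoiMask]:
    """Textured ellipsoid tumor in HU plus its ground-truth mask.

    HU inside the tumor is ``base_hu`` + Gaussian noise of SD ``texture_sd``;
    an optional concentric core (``core_fraction`` of the semi-axes) sits
    30 HU below the base. Deterministic per seed.
    """
    center = spec.resolved_center()
    for c, a, n, s in zip(center, spec.semi_axes_mm, spec.shape, spec.spacing):
        if c - a < 0 or c + a > (n - 1) * s:
            raise ValueError("tumor ellipsoid exceeds the grid")
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.shape, spec.spacing, center, spec.semi_axes_mm)
    data = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    data[mask] = spec.base_hu
    if spec.core_fraction > 0:
        core_axes = tuple(a * spec.core_fraction for a in spec.semi_axes_mm)
        core = _ellipsoid_mask(spec.shape, spec.spacing, center, core_axes)
        data[core & mask] = spec.base_hu - 30.0
    if spec.texture_sd > 0:
        data[mask] += rng.normal(0.0, spec.texture_sd, size=int(mask.sum()))
    vol = ImageVolume(data=data, spacing=spec.spacing)
    return vol, RoiMask(data=mask, spacing=spec.spacing)


@dataclass
class LungPhantomSpec:
    """Two-lung phantom: lung ellipsoids at −850 HU inside a 40 HU body."""

    shape: tuple[int, int, int] = (64, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_semi_axes_mm: tuple[float, float, float] = (10.0, 12.0, 16.0)
    lung_hu: float = -850.0
    body_hu: float = 40.0
    emphysema_hu: float = -1000.0
    seed: int = 0

    def lung_centers(self) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
        nx, ny, nz = self.shape
        dx, dy, dz = self.spacing
        cy, cz = (ny - 1) * dy / 2.0, (nz - 1) * dz / 2.0
        return ((nx - 1) * dx * 0.28, cy, cz), ((nx - 1) * dx * 0.72, cy, cz)


def lung_phantom_truth(spec: LungPhantomSpec) -> tuple[RoiMask, RoiMask]:
    """Ground-truth (left, right) lung masks of the phantom geometry."""
    left_c, right_c = spec.lung_centers()
    left = _ellipsoid_mask(spec.shape, spec.spacing, left_c, spec.lung_semi_axes_mm)
    right = _ellipsoid_mask(spec.shape, spec.spacing, right_c, spec.lung_semi_axes_mm)
    return RoiMask(left, spec.spacing), RoiMask(right, spec.spacing)


def make_lung_phantom(emphysema_fraction: float, spec: LungPhantomSpec | None = None) -> ImageVolume:
    """Lung phantom with the requested fraction of lung voxels at −1000 HU.

    Exactly ``round(fraction * n)`` voxels per lung are set to the emphysema
    HU, sampled without replacement, so the downstream emphysema index
    reproduces the requested fraction up to rounding.
    """
    if not 0.0 <= emphysema_fraction <= 1.0:
        raise ValueError("emphysema_fraction must be in [0, 1]")
    spec = spec or LungPhantomSpec()
    rng = np.random.default_rng(spec.seed)
    data = np.full(spec.shape, spec.body_hu, dtype=np.float64)
    for lung in lung_phantom_truth(spec):
        idx = np.flatnonzero(lung.data.ravel())
        data.ravel()[idx] = spec.lung_hu
        k = round(emphysema_fraction * idx.size)
        if k:
            chosen = rng.choice(idx, size=k, replace=False)
            data.ravel()[chosen] = spec.emphysema_hu
    return ImageVolume(data=data, spacing=spec.spacing)


# --------------------------------------------------------------------------
# Cohort simulation

_IMAGING_FEATURES: tuple[str, ...] = TUMOR_FEATURE_NAMES + EMPHYSEMA_FEATURE_NAMES

#: logistic models emulating the reported per-SD univariate effect sizes and
#: prevalences of the five pathways (intercept = logit of the prevalence)
_DEFAULT_PATHWAY_MODELS: dict[str, tuple[float, dict[str, float]]] = {
    "redox_stress": (math.log(0.368 / 0.632), {
        "volume_ml": math.log(1.64), "energy": math.log(0.15),
        "max_3d_diameter_mm": math.log(0.88), "cluster_prominence": math.log(1.28),
        "size_zone_variability": math.log(2.16),
    }),
    "apoptosis": (math.log(0.807 / 0.193), {
        "mass_g": 1.2, "range": math.log(0.08),
        "max_3d_diameter_mm": math.log(2.06), "cluster_shade": math.log(0.69),
        "intensity_variability": math.log(0.35),
    }),
    "proliferation": (math.log(0.561 / 0.439), {
        "hu_p97_5": math.log(1.83), "mpp": math.log(1.33),
        "cluster_prominence": math.log(1.77), "right_lung_volume_ml": math.log(0.35),
    }),
    "differentiation": (math.log(0.246 / 0.754), {
        "pack_years": 0.25, "minimum": math.log(1.21),
        "spherical_disproportion": math.log(0.68), "intensity_variability": math.log(0.73),
    }),
    "chromatin_remodelers": (math.log(0.491 / 0.509), {
        "pack_years": 0.25, "energy": math.log(1.73),
        "maximum_probability": math.log(0.54),
    }),
}

#: Weibull proportional-hazards models: (shape, scale_months, per-SD log HRs)
_DEFAULT_SURVIVAL_MODELS: dict[str, tuple[float, float, dict[str, float]]] = {
    "dfs": (1.2, 120.0, {
        "n_descriptor": 0.6, "kurtosis": 0.6,
        "surface_area_mm2": 0.6, "spherical_disproportion": -0.6,
    }),
    "os": (1.2, 140.0, {
        "age": 0.3, "t_descriptor": 0.5, "iqr": -0.6,
        "hu_p25": -0.6, "hu_p97_5": 0.6,
    }),
}


@dataclass
class CohortSpec:
    """Generating model for a synthetic radiogenomic cohort.

    ``pathway_models`` maps pathway → (intercept, {feature: logistic coef});
    coefficients apply to the z-scale of each feature. ``survival_models``
    maps endpoint → (Weibull shape, scale in months, {feature: log HR}).
    ``within_category_corr`` adds equicorrelation among the imaging features
    of a category. Mutations are emitted from each pathway's exclusive genes
    so the mapping rule reproduces the generating labels exactly.
    """

    n: int = 57
    pathway_models: dict[str, tuple[float, dict[str, float]]] = field(
        default_factory=lambda: {k: (b, dict(c)) for k, (b, c) in _DEFAULT_PATHWAY_MODELS.items()}
    )
    survival_models: dict[str, tuple[float, float, dict[str, float]]] = field(
        default_factory=lambda: {k: (s, sc, dict(c)) for k, (s, sc, c) in _DEFAULT_SURVIVAL_MODELS.items()}
    )
    censoring_rate: float = 1.0 / 80.0  # exponential, per month
    within_category_corr: float = 0.0
    pathway_map: PathwayMap = field(default_factory=default_pathway_map)
    thick_slice_fraction: float = 15.0 / 57.0  # emphysema volumetry not possible
    seed: int = 0

    def __post_init__(self) -> None:
        known = set(ALL_FEATURE_CATEGORIES)
        for pw, (_, coefs) in self.pathway_models.items():
            bad = set(coefs) - known
            if bad:
                raise ValueError(f"pathway {pw!r} references unknown features {sorted(bad)}")
        for ep, (_, _, coefs) in self.survival_models.items():
            bad = set(coefs) - known
            if bad:
                raise ValueError(f"endpoint {ep!r} references unknown features {sorted(bad)}")
        if not 0.0 <= self.within_category_corr < 1.0:
            raise ValueError("within_category_corr must be in [0, 1)")


def _simulate_clinical(rng: np.random.Generator, n: int) -> pd.DataFrame:
    smoking = rng.choice([0, 1, 2], size=n, p=[3 / 57, 29 / 57, 25 / 57])
    pack_years = np.where(smoking == 0, 0.0, rng.gamma(4.0, 10.0, size=n))
    return pd.DataFrame({
        "age": rng.normal(65.5, 6.7, size=n),
        "sex": (rng.random(n) < 54 / 57).astype(int),
        "smoking_status": smoking,
        "pack_years": pack_years,
        "t_descriptor": rng.choice([1, 2, 3, 4], size=n, p=[10 / 57, 37 / 57, 8 / 57, 2 / 57]),
        "n_descriptor": rng.choice([1, 2, 3], size=n, p=[41 / 57, 9 / 57, 7 / 57]),
        "m_descriptor": rng.choice([0, 1], size=n, p=[55 / 57, 2 / 57]),
        "stage": rng.choice([1, 2, 3, 4], size=n, p=[22 / 57, 25 / 57, 8 / 57, 2 / 57]),
        "adjuvant_therapy": (rng.random(n) < 13 / 57).astype(int),
        "palliative_therapy": (rng.random(n) < 10 / 57).astype(int),
    })


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, MutationTable, dict]:
    """Draw a cohort table, a matching mutation table and the ground truth.

    Imaging features are standard normal (optionally equicorrelated within a
    category); clinical margins follow the emulated cohort. Pathway labels
    are Bernoulli(logistic(eta)); for each altered pathway one gene exclusive
    to that pathway is emitted as a missense mutation. Survival times follow
    the Weibull proportional-hazards models with exponential censoring.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    clinical = _simulate_clinical(rng, n)

    feats = {}
    rho = spec.within_category_corr
    by_cat: dict[str, list[str]] = {}
    for f in _IMAGING_FEATURES:
        by_cat.setdefault(ALL_FEATURE_CATEGORIES[f], []).append(f)
    for cat, names in by_cat.items():
        if rho > 0 and len(names) > 1:
            shared = rng.normal(size=n)
            for f in names:
                feats[f] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=n)
        else:
            for f in names:
                feats[f] = rng.normal(size=n)
    cohort = pd.concat([clinical, pd.DataFrame(feats)], axis=1)
    cohort.index = pd.Index([f"P{i + 1:03d}" for i in range(n)], name="patient_id")

    def zcols(coefs: dict[str, float]) -> np.ndarray:
        eta = np.zeros(n)
        for f, c in coefs.items():
            x = cohort[f].to_numpy(dtype=np.float64)
            sd = x.std(ddof=1)
            z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
            eta += c * z
        return eta

    truth: dict = {"pathway_models": spec.pathway_models, "survival_models": spec.survival_models}
    labels = {}
    for pw in PATHWAYS:
        intercept, coefs = spec.pathway_models[pw]
        eta = intercept + zcols(coefs)
        labels[pw] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        cohort[f"pathway_{pw}"] = labels[pw]

    # emit mutations reproducing the labels exactly under the >=1-gene rule
    exclusive: dict[str, list[str]] = {}
    for pw in PATHWAYS:
        others = set().union(*(spec.pathway_map.map[q] for q in PATHWAYS if q != pw))
        excl = sorted(spec.pathway_map.map[pw] - others)
        if not excl:
            raise ValueError(f"pathway {pw!r} has no exclusive gene; round-trip impossible")
        exclusive[pw] = excl
    records = []
    for i, pat in enumerate(cohort.index):
        for pw in PATHWAYS:
            if labels[pw][i]:
                gene = exclusive[pw][int(rng.integers(len(exclusive[pw])))]
                records.append((pat, gene, "Missense_Mutation"))
    muts = MutationTable(records=pd.DataFrame(records, columns=["patient_id", "gene", "variant_class"]))

    for ep, (shape, scale, coefs) in spec.survival_models.items():
        eta = zcols(coefs)
        u = rng.random(n)
        t_event = scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
        time = np.minimum(t_event, t_cens)
        cohort[f"time_{ep}"] = np.maximum(time, 1e-3)
        cohort[f"event_{ep}"] = (t_event <= t_cens).astype(int)
        truth[f"true_event_times_{ep}"] = t_event

    # mark patients whose CT slices were too thick for lung volumetry
    n_thick = round(spec.thick_slice_fraction * n)
    thick = np.zeros(n, dtype=bool)
    thick[rng.choice(n, size=n_thick, replace=False)] = True
    cohort["emphysema_eligible"] = (~thick).astype(int)
    cohort.loc[thick, list(EMPHYSEMA_FEATURE_NAMES)] = np.nan

    truth["labels"] = {pw: labels[pw].copy() for pw in PATHWAYS}
    return cohort, muts, truth


# --------------------------------------------------------------------------
# Deterministic worked-example tables (printed cohort margins as inputs)


def demo_clinical_table(n: int = 57) -> pd.DataFrame:
    """Deterministic clinical table reproducing the emulated cohort's margins.

    57 patients: 54 men; 3 never / 29 former / 25 current smokers; stages
    22/25/8/2; T 10/37/8/2; N 41/9/7; M 55/2; 19 recurrences; 18 deaths;
    15 patients ineligible for emphysema volumetry (slices > 2.5 mm).
    """

    def fill(counts: dict[int, int]) -> np.ndarray:
        out = np.concatenate([np.full(c, v, dtype=int) for v, c in counts.items()])
        assert out.size == n
        return out

    df = pd.DataFrame(index=pd.Index([f"P{i + 1:03d}" for i in range(n)], name="patient_id"))
    df["age"] = np.round(np.linspace(43.0, 78.0, n), 1)
    df["sex"] = fill({1: 54, 0: 3})
    df["smoking_status"] = fill({0: 3, 1: 29, 2: 25})
    df["pack_years"] = np.where(df["smoking_status"] == 0, 0.0, np.round(np.linspace(5, 80, n), 1))
    df["t_descriptor"] = fill({1: 10, 2: 37, 3: 8, 4: 2})
    df["n_descriptor"] = fill({1: 41, 2: 9, 3: 7})
    df["m_descriptor"] = fill({0: 55, 1: 2})
    df["stage"] = fill({1: 22, 2: 25, 3: 8, 4: 2})
    df["adjuvant_therapy"] = fill({1: 13, 0: 44})
    df["palliative_therapy"] = fill({1: 10, 0: 47})
    df["event_dfs"] = fill({1: 19, 0: 38})
    df["event_os"] = fill({1: 18, 0: 39})
    df["time_dfs"] = np.round(np.linspace(6.0, 83.0, n), 1)
    df["time_os"] = np.round(np.linspace(8.0, 95.0, n), 1)
    df["emphysema_eligible"] = fill({0: 15, 1: 42})
    return df


def demo_mutation_table(n: int = 57) -> MutationTable:
    """Deterministic mutation table whose pathway mapping yields the emulated
    alteration counts 21/46/32/14/28 of 57.

    Each altered patient receives one missense mutation in a representative
    gene of the pathway; patient subsets are rotated so alteration patterns
    overlap across pathways.
    """
    counts = {"redox_stress": 21, "apoptosis": 46, "proliferation": 32,
              "differentiation": 14, "chromatin_remodelers": 28}
    gene = {"redox_stress": "KEAP1", "apoptosis": "TP53", "proliferation": "PIK3CA",
            "differentiation": "SOX2", "chromatin_remodelers": "MLL2"}
    records = []
    for k, (pw, c) in enumerate(counts.items()):
        for i in range(c):
            pat = f"P{(i + 7 * k) % n + 1:03d}"
            records.append((pat, gene[pw], "Missense_Mutation"))
    return MutationTable(records=pd.DataFrame(records, columns=["patient_id", "gene", "variant_class"]))
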