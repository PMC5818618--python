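"""Cohort-table conventions: the 73 clinicoradiological features in 8 categories.

A cohort table is a pandas DataFrame with one row per patient, indexed by
``patient_id``, whose columns are the 10 clinical features, the 52 tumor
features, the 11 emphysema features (missing where volumetry was not
possible), five binary pathway columns (``pathway_<name>``), and the survival
columns ``time_dfs, event_dfs, time_os, event_os`` in months.

Clinical encoding: ``sex`` is 1 for male; ``smoking_status`` is ordinal
0/1/2 (never/former/current); T/N/M descriptors and stage are integers;
therapy flags are 0/1. Continuous features are z-standardized inside each
model fit, never in the stored table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emphysema import EMPHYSEMA_FEATURE_NAMES
from .radiomic_features import FEATURE_CATEGORIES

__all__ = [
    "CLINICAL_FEATURE_NAMES",
    "CATEGORY_ORDER",
    "ALL_FEATURE_CATEGORIES",
    "feature_categories",
    "cohort_summary",
    "zscore",
]

CLINICAL_FEATURE_NAMES: tuple[str, ...] = (
    "age",
    "sex",
    "smoking_status",
    "pack_years",
    "t_descriptor",
    "n_descriptor",
    "m_descriptor",
    "stage",
    "adjuvant_therapy",
    "palliative_therapy",
)

CATEGORY_ORDER: tuple[str, ...] = (
    "clinical",
    "global",
    "histogram",
    "lung_cancer_specific",
    "shape",
    "local",
    "regional",
    "emphysema",
)

#: the full 73-feature → category map (10 clinical + 52 tumor + 11 emphysema)
ALL_FEATURE_CATEGORIES: dict[str, str] = {
    **{n: "clinical" for n in CLINICAL_FEATURE_NAMES},
    **FEATURE_CATEGORIES,
    **{n: "emphysema" for n in EMPHYSEMA_FEATURE_NAMES},
}
assert len(ALL_FEATURE_CATEGORIES) == 73


def feature_categories(cohort: pd.DataFrame | None = None) -> dict[str, str]:
    """Category map restricted to the columns actually present in ``cohort``."""
    if cohort is None:
        return dict(ALL_FEATURE_CATEGORIES)
    return {f: c for f, c in ALL_FEATURE_CATEGORIES.items() if f in cohort.columns}


def cohort_summary(clinical: pd.DataFrame) -> dict:
    """Bookkeeping counts of a clinical table: outcomes and sub-cohorts.

    Percentages are reported to one decimal. The emphysema sub-cohort counts
    patients whose CT slices permitted lung volumetry
    (``emphysema_eligible == 1``).
    """
    n = len(clinical)
    if n == 0:
        raise ValueError("empty clinical table")
    out: dict = {"n_patients": n}
    for col, key in (("event_dfs", "recurrence"), ("event_os", "death")):
        if col in clinical.columns:
            c = int(clinical[col].fillna(0).sum())
            out[key] = {"count": c, "percentage": round(100.0 * c / n, 1)}
    if "emphysema_eligible" in clinical.columns:
        out["emphysema_subcohort"] = int(clinical["emphysema_eligible"].fillna(0).sum())
    return out


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to zero mean / unit SD; a constant vector returns zeros."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd
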