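"""End-to-end orchestration: extract → merge → associate → survive.

Each run is driven by a :class:`RunConfig` (loadable from YAML), logs at
per-patient granularity during extraction and per-model granularity during
statistics, and writes a manifest (config hash, seed, library versions) next
to its outputs so a run can be reproduced exactly.

Patients are joined across the feature, clinical and mutation tables by
exact string ID; unmatched patients are reported, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import PathwayAssociationModel, smoking_association
from .cohort import ALL_FEATURE_CATEGORIES, feature_categories
from .emphysema import emphysema_features, segment_lungs
from .genomics import PATHWAYS, default_pathway_map, map_pathways, read_mutations, PathwayMap
from .image_io import read_mask, read_volume
from .radiomic_features import ExtractionConfig, extract_all
from .survival import SurvivalAssociationModel

__all__ = ["RunConfig", "run_extract", "run_associate", "run_survival", "build_cohort"]

log = logging.getLogger("radiopath")


@dataclass
class RunConfig:
    """Paths and options for a pipeline run.

    ``volumes_dir``/``masks_dir`` hold per-patient NIfTI files named
    ``<patient_id>.nii`` or ``.nii.gz``; ``lungs_dir`` (optional) holds chest
    volumes for emphysema analysis. Statistical options: the univariate
    screening threshold (0.2), the significance level (0.05) and the minimum
    altered-gene count for a pathway call (1).
    """

    out_dir: str = "radiopath_out"
    volumes_dir: str | None = None
    masks_dir: str | None = None
    lungs_dir: str | None = None
    features_csv: str | None = None
    clinical_csv: str | None = None
    mutations_tsv: str | None = None
    pathway_map_yaml: str | None = None
    n_bins: int = 32
    energy_variant: str = "uniformity"
    selection_threshold: float = 0.2
    significance: float = 0.05
    min_genes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.selection_threshold < 1 or not 0 < self.significance < 1:
            raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(config: RunConfig, stage: str) -> None:
    import lifelines, nibabel, scipy, sklearn, statsmodels  # noqa: PLC0415

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "radiopath": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nibabel.__version__,
            "statsmodels": statsmodels.__version__,
            "lifelines": lifelines.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _patient_files(directory: str) -> dict[str, Path]:
    files: dict[str, Path] = {}
    for p in sorted(Path(directory).iterdir()):
        if p.name.endswith((".nii", ".nii.gz")):
            files[p.name.removesuffix(".nii.gz").removesuffix(".nii")] = p
    return files


def run_extract(config: RunConfig) -> pd.DataFrame:
    """Extract tumor (and optional emphysema) features for every patient.

    Returns and writes a tidy table (patient_id, feature, category, value).
    Per-patient failures are logged and skipped; zero successes is an error.
    """
    if not config.volumes_dir or not config.masks_dir:
        raise ValueError("run_extract needs volumes_dir and masks_dir")
    ext = ExtractionConfig(n_bins=config.n_bins, energy_variant=config.energy_variant)
    volumes = _patient_files(config.volumes_dir)
    masks = _patient_files(config.masks_dir)
    lungs = _patient_files(config.lungs_dir) if config.lungs_dir else {}
    rows: list[tuple[str, str, str, float]] = []
    n_ok = 0
    for pid, vpath in volumes.items():
        if pid not in masks:
            log.warning("patient %s: no mask file, skipped", pid)
            continue
        try:
            vol = read_volume(vpath)
            mask = read_mask(masks[pid], vol)
            fv = extract_all(vol, mask, ext)
            rows.extend((pid, f, fv.categories[f], v) for f, v in fv.values.items())
            if pid in lungs:
                lung_vol = read_volume(lungs[pid])
                emph = emphysema_features(lung_vol, segment_lungs(lung_vol))
                rows.extend((pid, f, "emphysema", v) for f, v in emph.items())
            n_ok += 1
            log.info("patient %s: extracted", pid)
        except Exception as exc:
            log.error("patient %s: extraction failed: %s", pid, exc)
    if n_ok == 0:
        raise RuntimeError("no patient processed successfully")
    df = pd.DataFrame(rows, columns=["patient_id", "feature", "category", "value"])
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "features.csv", index=False, lineterminator="\n")
    _write_manifest(config, "extract")
    return df


def build_cohort(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Join features, clinical data and pathway calls into one cohort table."""
    if not config.clinical_csv:
        raise ValueError("clinical_csv is required")
    clinical = pd.read_csv(config.clinical_csv, index_col="patient_id")
    clinical.index = clinical.index.astype(str)
    cohort = clinical.copy()

    report: dict = {}
    feats_path = config.features_csv or str(Path(config.out_dir) / "features.csv")
    if Path(feats_path).exists():
        tidy = pd.read_csv(feats_path)
        wide = tidy.pivot_table(index="patient_id", columns="feature", values="value", aggfunc="first")
        wide.index = wide.index.astype(str)
        unmatched = sorted(set(wide.index) ^ set(clinical.index))
        if unmatched:
            log.warning("patients not present in both tables: %s", unmatched)
            report["unmatched_patients"] = unmatched
        overlap = [c for c in wide.columns if c in cohort.columns]
        if overlap:
            log.info("extracted features replace clinical-table columns: %s", overlap)
            cohort = cohort.drop(columns=overlap)
        cohort = cohort.join(wide, how="inner")

    if config.mutations_tsv:
        muts = read_mutations(config.mutations_tsv)
        pmap = (PathwayMap.from_file(config.pathway_map_yaml)
                if config.pathway_map_yaml else default_pathway_map())
        mat = map_pathways(muts, pmap, list(cohort.index), min_genes=config.min_genes)
        for pw in PATHWAYS:
            cohort[f"pathway_{pw}"] = mat.alterations[pw]
        report["alteration_matrix"] = mat
    return cohort, report


def run_associate(config: RunConfig) -> dict:
    """Pathway-association stage: five models + alteration and smoking summaries."""
    from .genomics import alteration_summary  # noqa: PLC0415

    cohort, extra = build_cohort(config)
    if "alteration_matrix" not in extra:
        raise ValueError("run_associate needs mutations_tsv (pathway labels)")
    cats = feature_categories(cohort)
    report: dict = {
        "alteration_summary": alteration_summary(extra["alteration_matrix"]),
        "pathways": {},
        "smoking": {},
    }
    tables = []
    for pw in PATHWAYS:
        y = cohort[f"pathway_{pw}"]
        if y.nunique() < 2:
            log.warning("pathway %s: single-class labels, no model", pw)
            report["pathways"][pw] = {"error": "single-class labels"}
            continue
        res = PathwayAssociationModel(
            cohort, pw, categories=cats, selection_threshold=config.selection_threshold
        ).fit()
        report["pathways"][pw] = res.to_dict()
        tables.append(res.summary())
        log.info("pathway %s: AUC %s", pw, f"{res.auc:.3f}" if res.auc else "n/a")
        if {"smoking_status", "pack_years"} <= set(cohort.columns):
            report["smoking"][pw] = smoking_association(
                cohort["smoking_status"].to_numpy(),
                cohort["pack_years"].to_numpy(),
                y.to_numpy(),
            )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    serializable = {k: v for k, v in report.items() if k != "alteration_matrix"}
    (out / "association.json").write_text(json.dumps(serializable, indent=2, default=float))
    (out / "association_table.txt").write_text("\n\n".join(tables) + "\n")
    _write_manifest(config, "associate")
    return report


def run_survival(config: RunConfig) -> dict:
    """Survival stage: DFS and OS category-wise Cox models."""
    cohort, _ = build_cohort(config)
    cats = feature_categories(cohort)
    report: dict = {}
    tables = []
    for ep in ("dfs", "os"):
        if f"time_{ep}" not in cohort.columns:
            log.warning("endpoint %s: no survival columns, skipped", ep)
            continue
        if cohort[f"event_{ep}"].fillna(0).sum() < 2:
            log.warning("endpoint %s: fewer than 2 events, skipped", ep)
            report[ep] = {"skipped": "insufficient events"}
            continue
        res = SurvivalAssociationModel(
            cohort, ep, categories=cats, selection_threshold=config.selection_threshold
        ).fit()
        report[ep] = res.to_dict()
        tables.append(res.summary())
        log.info("endpoint %s: AUC %s", ep, f"{res.auc:.3f}" if res.auc else "n/a")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "survival.json").write_text(json.dumps(report, indent=2, default=float))
    if tables:
        (out / "survival_table.txt").write_text("\n\n".join(tables) + "\n")
    _write_manifest(config, "survive")
    return report
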