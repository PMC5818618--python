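"""Somatic mutation table → five-pathway alteration matrix.

Somatic mutations in lung squamous cell carcinoma are sparse at the gene
level, so association analysis operates on five functional signaling-pathway
categories: redox stress, apoptosis, proliferation, differentiation and
chromatin remodelers. A pathway is called altered in a patient when at least
one of its member genes carries a non-silent somatic mutation (the stricter
">= 2 genes" rule is available via ``min_genes``).

The shipped default gene map assigns the recurrently mutated SQCC genes
(TP53, RB1, PTEN, NFE2L2, KEAP1, MLL2, PIK3CA) plus the canonical squamous
differentiation regulators (TP63, SOX2, NOTCH1) to their standard pathways.
It is an explicit placeholder: supply the full pathway→gene membership of the
cohort under study via YAML/JSON for a faithful analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PATHWAYS",
    "MutationTable",
    "PathwayMap",
    "PathwayAlterationMatrix",
    "default_pathway_map",
    "read_mutations",
    "map_pathways",
    "alteration_summary",
]

PATHWAYS: tuple[str, ...] = (
    "redox_stress",
    "apoptosis",
    "proliferation",
    "differentiation",
    "chromatin_remodelers",
)

# column aliases accepted for MAF-compatible input
_PATIENT_ALIASES = ("patient_id", "Tumor_Sample_Barcode")
_GENE_ALIASES = ("gene", "Hugo_Symbol")
_CLASS_ALIASES = ("variant_class", "Variant_Classification")

_DEFAULT_MAP: dict[str, list[str]] = {
    "redox_stress": ["NFE2L2", "KEAP1"],
    "apoptosis": ["TP53"],
    "proliferation": ["PIK3CA", "PTEN", "RB1"],
    "differentiation": ["TP63", "SOX2", "NOTCH1"],
    "chromatin_remodelers": ["MLL2"],
}


@dataclass
class MutationTable:
    """Per-patient non-silent somatic mutation records."""

    records: pd.DataFrame  # columns: patient_id, gene, variant_class

    @property
    def patients(self) -> list[str]:
        return sorted(self.records["patient_id"].unique())


@dataclass
class PathwayMap:
    """Pathway name → member gene symbols; exactly the five SQCC pathways."""

    map: dict[str, set[str]]

    def __post_init__(self) -> None:
        missing = set(PATHWAYS) - set(self.map)
        if missing:
            raise ValueError(f"pathway map missing pathways: {sorted(missing)}")
        self.map = {p: set(self.map[p]) for p in PATHWAYS}
        for p, genes in self.map.items():
            if not genes:
                raise ValueError(f"pathway {p!r} has an empty gene set")

    @classmethod
    def from_file(cls, path: str | Path) -> "PathwayMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)  # YAML is a JSON superset
        return cls(map={k: set(v) for k, v in raw.items()})


@dataclass
class PathwayAlterationMatrix:
    """Binary patients × pathways matrix plus per-pathway altered-gene counts."""

    alterations: pd.DataFrame  # index: patient_id; columns: PATHWAYS; 0/1
    gene_counts: pd.DataFrame  # same shape; number of distinct altered genes

    @property
    def patients(self) -> list[str]:
        return list(self.alterations.index)


def default_pathway_map() -> PathwayMap:
    return PathwayMap(map={k: set(v) for k, v in _DEFAULT_MAP.items()})


def read_mutations(path: str | Path) -> MutationTable:
    """Read a mutation TSV (plain or MAF-aliased headers); Silent rows drop."""
    df = pd.read_csv(path, sep="\t", dtype=str)

    def pick(aliases: tuple[str, ...]) -> str:
        for a in aliases:
            if a in df.columns:
                return a
        raise ValueError(f"mutation table lacks a column among {aliases}")

    out = pd.DataFrame(
        {
            "patient_id": df[pick(_PATIENT_ALIASES)],
            "gene": df[pick(_GENE_ALIASES)],
            "variant_class": df[pick(_CLASS_ALIASES)],
        }
    )
    if out["gene"].isna().any() or (out["gene"].str.len() == 0).any():
        raise ValueError("mutation table contains empty gene symbols")
    out = out[out["variant_class"].str.lower() != "silent"].reset_index(drop=True)
    return MutationTable(records=out)


def map_pathways(
    muts: MutationTable,
    pmap: PathwayMap,
    patients: list[str],
    min_genes: int = 1,
) -> PathwayAlterationMatrix:
    """Collapse mutations to pathway-level alteration calls.

    ``patients`` must cover every patient to report, including mutation-free
    ones; a mutation for an unlisted patient is an error. A pathway is
    altered when at least ``min_genes`` of its member genes are hit.
    """
    patients = list(patients)
    unknown = set(muts.records["patient_id"]) - set(patients)
    if unknown:
        raise ValueError(f"mutations for patients absent from the cohort list: {sorted(unknown)}")
    # duplicate (patient, gene) records collapse to one altered gene
    hits = muts.records.drop_duplicates(["patient_id", "gene"])
    by_patient = hits.groupby("patient_id")["gene"].agg(set).to_dict()
    counts = pd.DataFrame(0, index=pd.Index(patients, name="patient_id"), columns=list(PATHWAYS))
    for pat in patients:
        genes = by_patient.get(pat, set())
        for pw in PATHWAYS:
            counts.loc[pat, pw] = len(genes & pmap.map[pw])
    alt = (counts >= min_genes).astype(int)
    return PathwayAlterationMatrix(alterations=alt, gene_counts=counts)


def alteration_summary(mat: PathwayAlterationMatrix) -> dict:
    """Per-pathway counts/percentages and the per-patient alteration histogram.

    Percentages are 100*altered/total, reported to one decimal.
    """
    n = len(mat.patients)
    if n == 0:
        raise ValueError("no patients")
    counts = mat.alterations.sum(axis=0)
    per_pathway = {
        pw: {"count": int(counts[pw]), "percentage": round(100.0 * counts[pw] / n, 1)}
        for pw in PATHWAYS
    }
    per_patient = mat.alterations.sum(axis=1)
    hist = per_patient.value_counts().sort_index()
    return {
        "n_patients": n,
        "per_pathway": per_pathway,
        "altered_pathways_per_patient": {int(k): int(v) for k, v in hist.items()},
    }
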