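"""Per-sample genomic feature engineering.

Builds the feature vectors the models consume: binary per-gene variant flags
(mutation / amplification / deep deletion), tumor mutation burden (TMB,
mutations per megabase of panel exon territory), fraction of genome altered
(FGA, size-weighted over panel genes), chromosome-arm alteration flags, and
oncogenic-pathway aberration flags.  A copy-number *alteration* throughout
means a discrete call of -2 (deep deletion) or +2 (amplification); shallow
+/-1 calls count as unaltered, following the cBioPortal discrete-call
convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .io import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "GenePanel",
    "PathwayDefinition",
    "load_panel",
    "load_pathways",
    "load_clinical_schema",
    "compute_tmb",
    "compute_fga",
    "compute_arm_alterations",
    "compute_pathway_aberrations",
    "build_feature_matrix",
]

ALTERED_CALLS = (-2, 2)
#: high-TMB landmark used as a pseudo-variant in the screens (mut/Mb)
TMB_HIGH_CUTOFF = 20.0
#: FGA indicator cutoff used by the organotropic stratifier
FGA_BIN_CUTOFF = 0.05


@dataclass
class GenePanel:
    """Gene annotation: chromosome, arm, exon size and genomic footprint."""

    table: pd.DataFrame  # columns: gene, chromosome, arm, exon_size_bp, genomic_size_bp

    def __post_init__(self) -> None:
        req = ["gene", "chromosome", "arm", "exon_size_bp", "genomic_size_bp"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        if self.table["gene"].duplicated().any():
            raise ValueError("panel gene symbols must be unique")
        if (self.table["exon_size_bp"] <= 0).any() or (self.table["genomic_size_bp"] <= 0).any():
            raise ValueError("panel sizes must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    @property
    def total_exon_bp(self) -> float:
        return float(self.table["exon_size_bp"].sum())

    @property
    def total_genomic_bp(self) -> float:
        return float(self.table["genomic_size_bp"].sum())

    def arms(self) -> dict[str, list[str]]:
        return {a: list(g["gene"]) for a, g in self.table.groupby("arm")}


@dataclass
class PathwayDefinition:
    """Named oncogenic pathways as gene sets."""

    pathways: Mapping[str, frozenset]

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "PathwayDefinition":
        return cls({name: frozenset(genes) for name, genes in d.items()})

    def check_against_panel(self, panel: GenePanel) -> None:
        panel_genes = set(panel.genes)
        for name, members in self.pathways.items():
            extra = members - panel_genes
            if extra:
                logger.warning("pathway %s has %d genes outside the panel", name, len(extra))


def load_panel(path: str | Path) -> GenePanel:
    df = pd.read_csv(path, sep="\t")
    return GenePanel(df)


def load_pathways(path: str | Path) -> PathwayDefinition:
    with open(path) as fh:
        return PathwayDefinition.from_dict(json.load(fh))


def load_clinical_schema(path: str | Path) -> dict[str, str]:
    """covariate name -> type ("numeric" or "categorical")."""
    with open(path) as fh:
        schema = yaml.safe_load(fh) or {}
    bad = {k: v for k, v in schema.items() if v not in ("numeric", "categorical")}
    if bad:
        raise ValueError(f"clinical schema types must be numeric/categorical: {bad}")
    return schema


def compute_tmb(n_mutations: int, panel: GenePanel) -> float:
    """Mutations per megabase: count / total panel exon bp * 1e6."""
    total = panel.total_exon_bp
    if total <= 0:
        raise ValueError("panel total exon size must be positive")
    return float(n_mutations) / total * 1e6


def compute_fga(sample_cnas: pd.DataFrame, panel: GenePanel) -> float:
    """Size-weighted fraction of panel genes carrying a deep CNA.

    Sum of genomic footprints of altered genes (call in {-2, 2}) over the
    summed footprint of all panel genes.  Duplicate calls for a gene count
    once (set semantics).
    """
    sizes = dict(zip(panel.table["gene"], panel.table["genomic_size_bp"]))
    altered = sample_cnas.loc[sample_cnas["call"].isin(ALTERED_CALLS), "gene"]
    unknown = set(altered) - set(sizes)
    if unknown:
        logger.warning("FGA: excluding CNAs on genes outside the panel: %s", sorted(unknown))
    num = sum(sizes[g] for g in set(altered) & set(sizes))
    return num / panel.total_genomic_bp


def compute_arm_alterations(sample_cnas: pd.DataFrame, panel: GenePanel) -> dict[str, int]:
    """Per-arm flag: 1 iff strictly more than 50% of the arm's panel genes
    carry a deep CNA (a tie at exactly half is unaltered)."""
    altered = set(sample_cnas.loc[sample_cnas["call"].isin(ALTERED_CALLS), "gene"])
    flags = {}
    for arm, genes in panel.arms().items():
        if not genes:
            continue
        frac = sum(g in altered for g in genes) / len(genes)
        flags[arm] = int(frac > 0.5)
    return flags


def compute_pathway_aberrations(
    mutated_genes: Iterable[str], altered_genes: Iterable[str], pathways: PathwayDefinition
) -> dict[str, int]:
    """Pathway flag: 1 iff any member gene is mutated or deeply altered."""
    hit = set(mutated_genes) | set(altered_genes)
    return {name: int(bool(members & hit)) for name, members in pathways.pathways.items()}


def feature_columns(panel: GenePanel, pathways: PathwayDefinition) -> list[str]:
    """The fixed, documented column order of the feature matrix."""
    cols: list[str] = []
    for g in panel.genes:
        cols.extend([f"{g}_mut", f"{g}_amp", f"{g}_del"])
    cols.append("tmb")
    cols.append("fga")
    cols.extend(f"arm_{a}" for a in sorted(panel.arms()))
    cols.extend(f"pathway_{p}" for p in sorted(pathways.pathways))
    return cols


def build_feature_matrix(
    cohort: Cohort,
    panel: GenePanel,
    pathways: PathwayDefinition,
    clinical_schema: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Assemble one feature row per sample, indexed by sample_id.

    Binary variant flags come from mutation/CNA presence; TMB, FGA, arm and
    pathway flags are appended; clinical covariates are encoded per schema
    (numeric pass through; categoricals one-hot with an explicit missing
    level).  Missing numeric covariates stay NaN — never silently zero.
    """
    panel_genes = set(panel.genes)
    ids = cohort.sample_ids
    idx = pd.Index(ids, name="sample_id")
    cols = feature_columns(panel, pathways)
    arr = np.zeros((len(ids), len(cols)))
    colindex = pd.Index(cols)

    muts = cohort.mutations[cohort.mutations.gene.isin(panel_genes)]
    cnas = cohort.cnas[cohort.cnas.gene.isin(panel_genes)]
    amp = cnas[cnas.call == 2]
    dele = cnas[cnas.call == -2]
    for frame, suffix in ((muts, "_mut"), (amp, "_amp"), (dele, "_del")):
        if len(frame) == 0:
            continue
        pairs = frame[["sample_id", "gene"]].drop_duplicates()
        arr[
            idx.get_indexer(pairs["sample_id"]),
            colindex.get_indexer(pairs["gene"] + suffix),
        ] = 1.0
    X = pd.DataFrame(arr, index=idx, columns=cols)

    mut_counts = cohort.mutations.groupby("sample_id").size()
    X["tmb"] = [compute_tmb(int(mut_counts.get(s, 0)), panel) for s in ids]

    sizes = dict(zip(panel.table["gene"], panel.table["genomic_size_bp"]))
    alt = cnas[cnas.call.isin(ALTERED_CALLS)][["sample_id", "gene"]].drop_duplicates()
    alt_bp = alt.assign(bp=alt["gene"].map(sizes)).groupby("sample_id")["bp"].sum()
    X["fga"] = [float(alt_bp.get(s, 0.0)) / panel.total_genomic_bp for s in ids]

    arms = panel.arms()
    alt_sets = alt.groupby("sample_id")["gene"].agg(set)
    for arm, genes in sorted(arms.items()):
        n_arm = len(genes)
        gset = set(genes)
        X[f"arm_{arm}"] = [
            int(len(alt_sets.get(s, set()) & gset) / n_arm > 0.5) for s in ids
        ]

    mut_sets = muts.groupby("sample_id")["gene"].agg(set)
    for p in sorted(pathways.pathways):
        members = pathways.pathways[p]
        X[f"pathway_{p}"] = [
            int(bool(members & (mut_sets.get(s, set()) | alt_sets.get(s, set())))) for s in ids
        ]

    if clinical_schema:
        clin = cohort.samples.set_index("sample_id").reindex(idx)
        for name, kind in clinical_schema.items():
            if name not in clin.columns:
                logger.warning("clinical covariate %r absent from cohort; dropped", name)
                continue
            if kind == "numeric":
                X[f"clin_{name}"] = pd.to_numeric(clin[name], errors="coerce")
            else:
                levels = clin[name].astype("object").where(clin[name].notna(), "missing")
                for lev in sorted(map(str, levels.unique())):
                    X[f"clin_{name}={lev}"] = (levels.astype(str) == lev).astype(float)
        extra = [
            c for c in cohort.samples.columns
            if c not in clinical_schema
            and c not in (
                "sample_id", "sample_type", "cancer_type", "biopsy_site",
                "metastatic_site", "survival_months", "event",
            )
        ]
        if extra:
            logger.warning("clinical covariates outside schema ignored: %s", extra)
    return X


def add_pseudo_variants(X: pd.DataFrame) -> pd.DataFrame:
    """Binary engineered features that enter the screens as pseudo-variants:
    a high-TMB indicator (> 20 mut/Mb) and an FGA-over-5% indicator."""
    out = X.copy()
    out["tmb_high"] = (out["tmb"] > TMB_HIGH_CUTOFF).astype(float)
    out["fga_gt_5pct"] = (out["fga"] > FGA_BIN_CUTOFF).astype(float)
    return out


def binary_feature_columns(X: pd.DataFrame) -> list[str]:
    """Columns that are 0/1 flags (variants, arms, pathways, indicators)."""
    cols = []
    for c in X.columns:
        v = X[c].dropna().unique()
        if len(v) and np.isin(v, (0.0, 1.0)).all() and c not in ("tmb", "fga"):
            cols.append(c)
    return cols
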