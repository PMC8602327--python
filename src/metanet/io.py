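"""Reading, harmonizing and filtering panel-sequencing cohorts.

Input dialects follow cBioPortal exports: a minimal MAF mutation table, a
gene-level discrete copy-number table (long or wide), and a clinical/sample
table.  Raw tissue strings are mapped to canonical anatomic organs through a
static two-column table rather than a live ontology service, so loading is
reproducible offline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "IntegrityError",
    "MutationCall",
    "CopyNumberCall",
    "SampleRecord",
    "Cohort",
    "OrganMap",
    "default_organ_map",
    "load_organ_map",
    "load_cohort",
    "write_cohort",
    "filter_sites",
    "intersect_panel",
    "summarize_cohort",
]

PRIMARY = "primary"
METASTATIC = "metastatic"

#: canonical organ vocabulary used by the shipped mapping
DEFAULT_PRIMARY_SITES = (
    "bladder", "breast", "colon", "esophagus", "gallbladder", "head_and_neck",
    "kidney", "liver", "lung", "ovary", "pancreas", "prostate", "skin",
    "stomach", "thyroid", "uterus",
)
#: the five explicitly named destination organs; user-extensible
DEFAULT_METASTATIC_SITES = ("lymph_node", "liver", "bone", "lung", "brain")

MAF_COLUMNS = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "HGVSp_Short": "protein_change",
    "Chromosome": "chromosome",
    "Start_Position": "position",
}
CLINICAL_REQUIRED = ("sample_id", "sample_type", "cancer_type")
CNA_CODES = {-2, -1, 0, 1, 2}


class FormatError(ValueError):
    """A required column or value is missing or malformed."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


@dataclass(frozen=True)
class MutationCall:
    sample_id: str
    gene: str
    protein_change: Optional[str] = None
    chromosome: Optional[str] = None
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.position is not None and self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")


@dataclass(frozen=True)
class CopyNumberCall:
    sample_id: str
    gene: str
    call: int

    def __post_init__(self) -> None:
        if self.call not in CNA_CODES:
            raise ValueError(f"copy-number call {self.call} not in {sorted(CNA_CODES)}")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    sample_type: str
    cancer_type: str
    biopsy_site: Optional[str] = None
    metastatic_site: Optional[str] = None
    clinical: Mapping[str, object] = field(default_factory=dict)
    survival_months: Optional[float] = None
    event_flag: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sample_type not in (PRIMARY, METASTATIC):
            raise ValueError(f"sample_type must be primary/metastatic, got {self.sample_type!r}")
        if (self.metastatic_site is not None) != (self.sample_type == METASTATIC):
            raise ValueError("metastatic_site present iff sample is metastatic")
        if (self.survival_months is None) != (self.event_flag is None):
            raise ValueError("survival_months present iff event_flag present")
        if self.survival_months is not None and self.survival_months < 0:
            raise ValueError("survival_months must be nonnegative")


@dataclass
class OrganMap:
    """Static raw-tissue -> canonical-organ mapping with allowed-site lists."""

    entries: Mapping[str, str]
    allowed_primary_sites: Sequence[str] = DEFAULT_PRIMARY_SITES
    allowed_metastatic_sites: Sequence[str] = DEFAULT_METASTATIC_SITES

    def canonical(self, raw: Optional[str]) -> Optional[str]:
        """Map a raw tissue label; unknown tissues become ``"other"``."""
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
            return None
        raw = str(raw)
        if raw in self.entries:
            return self.entries[raw]
        folded = {k.strip().lower(): v for k, v in self.entries.items()}
        if raw.strip().lower() in folded:
            return folded[raw.strip().lower()]
        low = raw.strip().lower().replace(" ", "_")
        allowed = set(self.allowed_primary_sites) | set(self.allowed_metastatic_sites)
        return low if low in allowed else "other"


def load_organ_map(
    path: str | Path,
    allowed_primary_sites: Sequence[str] = DEFAULT_PRIMARY_SITES,
    allowed_metastatic_sites: Sequence[str] = DEFAULT_METASTATIC_SITES,
) -> OrganMap:
    """Read a two-column TSV (raw_tissue, canonical_organ)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise FormatError("organ map needs two columns: raw_tissue, canonical_organ")
    entries = dict(zip(df[cols[0]], df[cols[1]]))
    return OrganMap(entries, tuple(allowed_primary_sites), tuple(allowed_metastatic_sites))


def default_organ_map() -> OrganMap:
    """The shipped mapping covering the 16 origin and 5 destination organs."""
    with resources.files("metanet.data").joinpath("organ_map.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    entries = dict(zip(df["raw_tissue"], df["canonical_organ"]))
    return OrganMap(entries)


@dataclass
class Cohort:
    """A harmonized cohort: sample table plus variant call tables.

    ``samples`` carries one row per sample (canonical organ annotation,
    survival and free clinical covariates); ``mutations`` and ``cnas`` carry
    one row per call and reference ``samples.sample_id``.
    """

    samples: pd.DataFrame
    mutations: pd.DataFrame
    cnas: pd.DataFrame
    cohort_name: str = "cohort"

    def __post_init__(self) -> None:
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise IntegrityError(f"duplicate sample_id in clinical table: {dups}")
        known = set(ids)
        for name, table in (("mutation", self.mutations), ("cna", self.cnas)):
            if len(table):
                orphans = sorted(set(table["sample_id"]) - known)
                if orphans:
                    raise IntegrityError(
                        f"{name} rows reference samples absent from clinical: {orphans}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def genes(self) -> list[str]:
        g = set(self.mutations["gene"]) | set(self.cnas["gene"])
        return sorted(g)

    def subset(self, sample_ids: Iterable[str]) -> "Cohort":
        keep = set(sample_ids)
        return Cohort(
            samples=self.samples[self.samples.sample_id.isin(keep)].reset_index(drop=True),
            mutations=self.mutations[self.mutations.sample_id.isin(keep)].reset_index(drop=True),
            cnas=self.cnas[self.cnas.sample_id.isin(keep)].reset_index(drop=True),
            cohort_name=self.cohort_name,
        )


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {missing}")


def _read_mutations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["Tumor_Sample_Barcode", "Hugo_Symbol"], "mutation table")
    out = pd.DataFrame({"sample_id": df["Tumor_Sample_Barcode"], "gene": df["Hugo_Symbol"]})
    for src, dst in MAF_COLUMNS.items():
        if dst in ("sample_id", "gene"):
            continue
        out[dst] = df[src] if src in df.columns else pd.NA
    if "position" in out:
        out["position"] = pd.to_numeric(out["position"], errors="coerce").astype("Int64")
        bad = out["position"].dropna() < 1
        if bad.any():
            raise FormatError("Start_Position must be 1-based (>= 1)")
    if (out["gene"].isna() | (out["gene"] == "")).any():
        raise FormatError("mutation table contains empty Hugo_Symbol")
    return out


def _read_cna(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in df.columns}
    if {"sample_id", "gene", "call"} <= set(lower):
        out = pd.DataFrame(
            {
                "sample_id": df[lower["sample_id"]],
                "gene": df[lower["gene"]],
                "call": pd.to_numeric(df[lower["call"]], errors="raise").astype(int),
            }
        )
    elif "Hugo_Symbol" in df.columns:
        # wide matrix: one row per gene, one column per sample
        long = df.melt(id_vars=["Hugo_Symbol"], var_name="sample_id", value_name="call")
        long = long.dropna(subset=["call"])
        out = pd.DataFrame(
            {
                "sample_id": long["sample_id"],
                "gene": long["Hugo_Symbol"],
                "call": pd.to_numeric(long["call"], errors="raise").astype(int),
            }
        )
    else:
        raise FormatError(
            "cna table must be long (sample_id, gene, call) or wide (Hugo_Symbol x samples)"
        )
    bad = ~out["call"].isin(sorted(CNA_CODES))
    if bad.any():
        raise FormatError(f"cna calls outside {sorted(CNA_CODES)}: {sorted(out['call'][bad].unique())}")
    return out.reset_index(drop=True)


def _read_clinical(path: str | Path, organ_map: OrganMap) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, CLINICAL_REQUIRED, "clinical table")
    df = df.copy()
    if df["sample_id"].duplicated().any():
        dups = sorted(df["sample_id"][df["sample_id"].duplicated()].unique())
        raise IntegrityError(f"duplicate sample_id in clinical table: {dups}")
    bad_type = ~df["sample_type"].isin([PRIMARY, METASTATIC])
    if bad_type.any():
        raise FormatError(
            f"sample_type must be primary/metastatic; offending values: "
            f"{sorted(df['sample_type'][bad_type].unique())}"
        )
    for col in ("cancer_type", "biopsy_site", "metastatic_site"):
        if col in df.columns:
            df[col] = df[col].map(organ_map.canonical)
        else:
            df[col] = None
    df.loc[df["sample_type"] == PRIMARY, "metastatic_site"] = None
    for col in ("survival_months", "event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "survival_months" in df.columns and (df["survival_months"].dropna() < 0).any():
        raise FormatError("survival_months must be nonnegative")
    return df.reset_index(drop=True)


def load_cohort(
    mutations_path: str | Path,
    cna_path: str | Path,
    clinical_path: str | Path,
    organ_map: Optional[OrganMap] = None,
    cohort_name: str = "cohort",
) -> Cohort:
    """Load and harmonize the three cBioPortal-style tables into a Cohort.

    Tissue strings are mapped through ``organ_map`` (the shipped default when
    omitted).  Mutation or CNA rows naming a sample absent from the clinical
    table raise :class:`IntegrityError` listing the orphan ids.
    """
    organ_map = organ_map or default_organ_map()
    samples = _read_clinical(clinical_path, organ_map)
    mutations = _read_mutations(mutations_path)
    cnas = _read_cna(cna_path)
    cohort = Cohort(samples=samples, mutations=mutations, cnas=cnas, cohort_name=cohort_name)
    logger.info(
        "loaded cohort %s: %d samples, %d mutations, %d cnas",
        cohort_name, len(samples), len(mutations), len(cnas),
    )
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical TSVs (mutations.tsv, cna.tsv, clinical.tsv).

    Loading canonical TSVs and writing them back reproduces them
    byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    mut = cohort.mutations.rename(columns={v: k for k, v in MAF_COLUMNS.items()})
    paths["mutations"] = out / "mutations.tsv"
    mut.to_csv(paths["mutations"], sep="\t", index=False)
    paths["cna"] = out / "cna.tsv"
    cohort.cnas.to_csv(paths["cna"], sep="\t", index=False)
    paths["clinical"] = out / "clinical.tsv"
    clin = cohort.samples.copy()
    for col in ("survival_months", "event"):
        if col in clin.columns:
            clin[col] = clin[col].map(lambda v: "" if pd.isna(v) else f"{v:g}")
    clin.to_csv(paths["clinical"], sep="\t", index=False)
    return paths


def filter_sites(cohort: Cohort, organ_map: Optional[OrganMap] = None) -> Cohort:
    """Drop samples from disallowed origin or destination organs.

    A sample is kept iff its ``cancer_type`` is an allowed origin and, for
    metastatic samples, its ``metastatic_site`` is an allowed destination.
    Mirrors the exclusion of minor/unexplicit tissues before analysis.
    """
    organ_map = organ_map or default_organ_map()
    s = cohort.samples
    ok_origin = s["cancer_type"].isin(organ_map.allowed_primary_sites)
    is_met = s["sample_type"] == METASTATIC
    ok_dest = ~is_met | s["metastatic_site"].isin(organ_map.allowed_metastatic_sites)
    keep = ok_origin & ok_dest
    dropped = int((~keep).sum())
    logger.info("filter_sites: kept %d, dropped %d samples", int(keep.sum()), dropped)
    if keep.sum() == 0:
        logger.warning("filter_sites removed every sample")
    return cohort.subset(s.loc[keep, "sample_id"])


def intersect_panel(cohort_a_genes: Iterable[str], cohort_b_genes: Iterable[str]) -> list[str]:
    """Sorted intersection of two gene lists (the shared panel)."""
    a, b = set(cohort_a_genes), set(cohort_b_genes)
    if not a or not b:
        raise ValueError("both gene lists must be non-empty")
    return sorted(a & b)


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Sample counts per (cancer_type, sample_type, metastatic_site)."""
    if len(cohort.samples) == 0:
        return pd.DataFrame(columns=["cancer_type", "sample_type", "metastatic_site", "n"])
    s = cohort.samples.copy()
    s["metastatic_site"] = s["metastatic_site"].fillna("")
    out = (
        s.groupby(["cancer_type", "sample_type", "metastatic_site"], dropna=False)
        .size()
        .reset_index(name="n")
        .sort_values(["cancer_type", "sample_type", "metastatic_site"])
        .reset_index(drop=True)
    )
    return out


def export_sankey(cohort: Cohort, path: str | Path) -> None:
    """Write (origin, destination, count) triples as JSON for diagramming."""
    mets = cohort.samples[cohort.samples.sample_type == METASTATIC]
    triples = (
        mets.groupby(["cancer_type", "metastatic_site"]).size().reset_index(name="count")
    )
    records = triples.rename(
        columns={"cancer_type": "origin", "metastatic_site": "destination"}
    ).to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=1))
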