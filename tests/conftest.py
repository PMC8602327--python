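import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from metanet.features import GenePanel, PathwayDefinition
from metanet.io import Cohort, OrganMap
from metanet.simulate import end_to_end_fixture


@pytest.fixture(scope="session")
def small_world():
    """Small simulated cohort (n = 300) with planted effects and truth."""
    return end_to_end_fixture("small")


@pytest.fixture()
def toy_panel():
    return GenePanel(pd.DataFrame({
        "gene": ["A", "B", "C", "D"],
        "chromosome": ["1", "1", "13", "13"],
        "arm": ["1p", "1p", "13q", "13q"],
        "exon_size_bp": [300_000, 300_000, 300_000, 300_000],
        "genomic_size_bp": [100_000, 100_000, 100_000, 100_000],
    }))


@pytest.fixture()
def toy_pathways():
    return PathwayDefinition.from_dict({"PI3K": ["A", "B"], "WNT": ["C"]})


@pytest.fixture()
def toy_cohort():
    samples = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "sample_type": ["primary", "metastatic", "primary"],
        "cancer_type": ["breast", "breast", "prostate"],
        "biopsy_site": ["breast", "liver", "prostate"],
        "metastatic_site": [None, "liver", None],
        "survival_months": [12.0, 5.0, 30.0],
        "event": [1, 1, 0],
    })
    mutations = pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "gene": ["A", "C"],
        "protein_change": ["D538G", None],
        "chromosome": ["1", "13"],
        "position": [1000, 2000],
    })
    cnas = pd.DataFrame({"sample_id": ["s2"], "gene": ["B"], "call": [2]})
    return Cohort(samples=samples, mutations=mutations, cnas=cnas, cohort_name="toy")


@pytest.fixture()
def toy_files(tmp_path, toy_cohort):
    """The toy cohort written as canonical cBioPortal-style TSVs."""
    mut = toy_cohort.mutations.rename(columns={
        "sample_id": "Tumor_Sample_Barcode", "gene": "Hugo_Symbol",
        "protein_change": "HGVSp_Short", "chromosome": "Chromosome",
        "position": "Start_Position",
    })
    mut.to_csv(tmp_path / "mutations.tsv", sep="\t", index=False)
    toy_cohort.cnas.to_csv(tmp_path / "cna.tsv", sep="\t", index=False)
    toy_cohort.samples.to_csv(tmp_path / "clinical.tsv", sep="\t", index=False)
    return tmp_path


@pytest.fixture()
def identity_map():
    organs = ["breast", "prostate", "lung", "colon", "liver", "bone", "brain",
              "lymph_node", "eye"]
    return OrganMap(entries={o: o for o in organs})
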