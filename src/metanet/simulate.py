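"""Synthetic panel-sequencing cohorts with known planted structure.

The generator emulates the statistical skeleton of real primary/metastatic
panel cohorts: per-variant Bernoulli carrier fractions, a planted
primary-vs-metastasis log-odds shift for chosen variants, multiplicative
organotropic odds effects per destination organ, an optional planted
"metastasis-featuring" subgroup of primaries, and right-censored exponential
survival tied to latent risk.  Every draw flows from one seeded generator so
a config is a fully stated world: same seed, byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .features import GenePanel, PathwayDefinition
from .io import Cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "generate_panel",
    "generate_cohort",
    "generate_ordinal_data",
    "end_to_end_fixture",
]

PATHWAY_NAMES = (
    "Cell_Cycle", "Hippo", "Myc", "Notch", "Nrf2",
    "PI3K", "RTK_RAS", "TGF_Beta", "TP53", "WNT",
)
DEFAULT_ARMS = ("1p", "1q", "3q", "8p", "8q", "13q", "17p", "17q")


@dataclass
class SimulationConfig:
    """Stated world for one synthetic cancer-type cohort.

    Effects are expressed exactly as the screens measure them: met_effects
    are additive log-odds shifts for metastatic (and planted MFP) samples;
    organo_effects multiply the carrier odds at one destination so the
    organotropic odds ratio equals the configured multiplier in expectation.
    """

    seed: int
    cancer_type: str = "breast"
    n_primary: int = 1000
    n_met: int = 1000
    panel_size: int = 60
    site_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"bone": 0.25, "brain": 0.25, "liver": 0.25, "lung": 0.25}
    )
    baseline_range: tuple[float, float] = (0.02, 0.30)
    baseline_overrides: Mapping[str, float] = field(default_factory=dict)
    met_effects: Mapping[str, float] = field(default_factory=dict)
    organo_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    mfp_fraction: float = 0.0
    baseline_hazard: float = 0.02  # events per month
    risk_log_hazard: float = 0.0   # gamma: log-hazard per unit latent risk
    mfp_hazard_ratio: float = 3.0  # applied to planted MFP primaries
    censor_window_months: float = 80.0
    shallow_cna_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        tot = sum(self.site_distribution.values())
        if not np.isclose(tot, 1.0):
            raise ValueError("site_distribution must sum to 1")
        lo, hi = self.baseline_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("baseline fractions must lie strictly inside (0, 1)")
        for v, sites in self.organo_effects.items():
            for s, m in sites.items():
                if m <= 0:
                    raise ValueError(f"organotropic multiplier for {v}@{s} must be > 0")


@dataclass
class TruthTable:
    """Planted ground truth accompanying a generated cohort."""

    variants: pd.DataFrame  # variant, baseline, met_log_odds, direction, top_site
    samples: pd.DataFrame   # sample_id, latent_risk, planted_mfp

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "variants": self.variants.to_dict(orient="records"),
            "samples": self.samples.to_dict(orient="records"),
        }, indent=1))


def generate_panel(config: SimulationConfig) -> tuple[GenePanel, PathwayDefinition]:
    """Synthetic gene panel: log-normal gene sizes, round-robin arm labels,
    ten disjoint random pathways."""
    if config.panel_size < 10:
        raise ValueError("panel size must be >= 10")
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:03d}" for i in range(config.panel_size)]
    exon = np.exp(rng.normal(np.log(5_000), 0.5, size=config.panel_size))
    genomic = exon * rng.uniform(5, 30, size=config.panel_size)
    arms = [DEFAULT_ARMS[i % len(DEFAULT_ARMS)] for i in range(config.panel_size)]
    chroms = [a.rstrip("pq") for a in arms]
    panel = GenePanel(pd.DataFrame({
        "gene": genes,
        "chromosome": chroms,
        "arm": arms,
        "exon_size_bp": np.round(exon).astype(int) + 1,
        "genomic_size_bp": np.round(genomic).astype(int) + 1,
    }))
    shuffled = list(rng.permutation(genes))
    per = max(1, len(genes) // len(PATHWAY_NAMES))
    pathways = {
        name: shuffled[i * per: (i + 1) * per]
        for i, name in enumerate(PATHWAY_NAMES)
    }
    return panel, PathwayDefinition.from_dict(pathways)


def _variant_names(panel: GenePanel, rng: np.random.Generator) -> pd.DataFrame:
    """Every gene gets a _mut variant; a third each get _amp / _del."""
    rows = []
    for i, g in enumerate(panel.genes):
        rows.append((g, "mut"))
        if i % 3 == 1:
            rows.append((g, "amp"))
        elif i % 3 == 2:
            rows.append((g, "del"))
    return pd.DataFrame(rows, columns=["gene", "kind"])


def generate_cohort(
    config: SimulationConfig, panel: Optional[GenePanel] = None
) -> tuple[Cohort, TruthTable]:
    """Draw a cohort under the configured world.

    Carrier indicator for sample s and variant v is Bernoulli with
    logit = logit(baseline_v) + met_log_odds_v * [s met-like]
          + log(multiplier_{v, site(s)}) * [s metastatic],
    where met-like means metastatic or a planted MFP primary.
    """
    rng = np.random.default_rng(config.seed)
    if panel is None:
        panel, _ = generate_panel(config)

    variants = _variant_names(panel, rng)
    nv = len(variants)
    lo, hi = config.baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=nv))
    vnames = (variants["gene"] + "_" + variants["kind"]).to_numpy()
    for j, v in enumerate(vnames):
        if v in config.baseline_overrides:
            baselines[j] = config.baseline_overrides[v]
    met_lo = np.array([config.met_effects.get(v, 0.0) for v in vnames])

    n = config.n_primary + config.n_met
    sample_ids = [f"{config.cancer_type[:2].upper()}-P{i:05d}" for i in range(config.n_primary)] + [
        f"{config.cancer_type[:2].upper()}-M{i:05d}" for i in range(config.n_met)
    ]
    is_met = np.array([False] * config.n_primary + [True] * config.n_met)
    sites = np.array(list(config.site_distribution))
    site_p = np.array([config.site_distribution[s] for s in sites])
    dest = np.full(n, "", dtype=object)
    dest[is_met] = rng.choice(sites, size=config.n_met, p=site_p)
    planted_mfp = np.zeros(n, dtype=bool)
    if config.mfp_fraction > 0:
        planted_mfp[: config.n_primary] = rng.random(config.n_primary) < config.mfp_fraction
    met_like = is_met | planted_mfp

    logits = np.tile(logit(baselines), (n, 1))
    logits += np.outer(met_like, met_lo)
    for j, v in enumerate(vnames):
        site_mult = config.organo_effects.get(v)
        if site_mult:
            for s, m in site_mult.items():
                logits[(dest == s), j] += np.log(m)
    if np.abs(logits).max() > 30:
        raise ValueError("infeasible configuration: carrier logit overflow")
    carrier = rng.random((n, nv)) < expit(logits)

    mut_rows, cna_rows = [], []
    chrom = dict(zip(panel.table["gene"], panel.table["chromosome"]))
    gene_pos = {g: (i + 1) * 1_000_000 for i, g in enumerate(panel.genes)}
    for i in range(n):
        for j in np.where(carrier[i])[0]:
            g, kind = variants.iloc[j]["gene"], variants.iloc[j]["kind"]
            if kind == "mut":
                offset = int(rng.integers(0, 5_000))
                mut_rows.append((sample_ids[i], g, f"p.X{offset % 700}Y",
                                 chrom[g], gene_pos[g] + offset))
            else:
                cna_rows.append((sample_ids[i], g, 2 if kind == "amp" else -2))
    if config.shallow_cna_rate > 0:
        shallow = rng.random((n, len(panel.genes))) < config.shallow_cna_rate
        signs = rng.choice([-1, 1], size=shallow.shape)
        for i, j in zip(*np.where(shallow)):
            cna_rows.append((sample_ids[i], panel.genes[j], int(signs[i, j])))

    latent_risk = carrier @ np.clip(met_lo, 0.0, None)
    log_h = (
        np.log(config.baseline_hazard)
        + config.risk_log_hazard * latent_risk
        + np.log(config.mfp_hazard_ratio) * planted_mfp
    )
    event_t = rng.exponential(1.0, size=n) / np.exp(log_h)
    censor_t = rng.uniform(0, config.censor_window_months, size=n)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "sample_type": np.where(is_met, "metastatic", "primary"),
        "cancer_type": config.cancer_type,
        "biopsy_site": np.where(is_met, dest, config.cancer_type),
        "metastatic_site": [d if d else None for d in dest],
        "survival_months": np.round(time, 3),
        "event": event,
    })
    mutations = pd.DataFrame(
        mut_rows, columns=["sample_id", "gene", "protein_change", "chromosome", "position"]
    )
    cnas = pd.DataFrame(cna_rows, columns=["sample_id", "gene", "call"])
    cohort = Cohort(samples=samples, mutations=mutations, cnas=cnas,
                    cohort_name=f"sim-{config.cancer_type}-{config.seed}")

    direction = np.where(met_lo > 0, "metastasis", np.where(met_lo < 0, "primary", "none"))
    top_site = [
        max(config.organo_effects[v], key=config.organo_effects[v].get)
        if v in config.organo_effects else ""
        for v in vnames
    ]
    truth = TruthTable(
        variants=pd.DataFrame({
            "variant": vnames, "baseline": baselines, "met_log_odds": met_lo,
            "direction": direction, "top_site": top_site,
        }),
        samples=pd.DataFrame({
            "sample_id": sample_ids, "latent_risk": latent_risk,
            "planted_mfp": planted_mfp, "metastatic": is_met,
        }),
    )
    logger.info("generated cohort %s: %d samples, %d variants", cohort.cohort_name, n, nv)
    return cohort, truth


def generate_stratified_survival(
    hazards: Sequence[float],
    n_per_group: int,
    seed: int,
    censor_window_months: float = 80.0,
) -> pd.DataFrame:
    """Exponential survival for ordered risk groups with uniform censoring.

    Returns a frame with columns group (0..G-1), time (months), event.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for g, h in enumerate(hazards):
        if h <= 0:
            raise ValueError("hazards must be positive")
        event_t = rng.exponential(1.0 / h, size=n_per_group)
        censor_t = rng.uniform(0, censor_window_months, size=n_per_group)
        frames.append(pd.DataFrame({
            "group": g,
            "time": np.minimum(event_t, censor_t),
            "event": (event_t <= censor_t).astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


def generate_ordinal_data(
    beta: Sequence[float],
    theta: Sequence[float],
    n: int,
    seed: int,
    binary_features: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cumulative-logit ordinal responses with known coefficients.

    P(y <= k | x) = logistic(theta_k - x.beta).  Features are standard
    normal (or Bernoulli(0.3) flags when ``binary_features``).
    """
    beta = np.asarray(beta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.diff(theta) > 0).all():
        raise ValueError("theta must be strictly increasing")
    rng = np.random.default_rng(seed)
    if binary_features:
        X = (rng.random((n, beta.size)) < 0.3).astype(float)
    else:
        X = rng.normal(size=(n, beta.size))
    eta = X @ beta
    cum = expit(theta[None, :] - eta[:, None])  # P(y <= k), k = 0..K-2
    u = rng.random(n)
    y = (u[:, None] > cum).sum(axis=1)
    cols = [f"x{i}" for i in range(beta.size)]
    return pd.DataFrame(X, columns=cols), y


def end_to_end_fixture(
    size: str = "small", out_dir: Optional[str | Path] = None, seed: int = 20210
) -> dict:
    """A ready-made cohort with planted effects for pipeline tests.

    ``small`` (n = 300) loads in seconds; ``medium`` (n = 3,000) is sized for
    screen-recovery checks.  Returns panel, pathways, cohort and truth; when
    ``out_dir`` is given also writes the standard TSV/JSON files.
    """
    if size not in ("small", "medium"):
        raise ValueError("size must be small or medium")
    n = 150 if size == "small" else 1500
    config = SimulationConfig(
        seed=seed,
        cancer_type="breast",
        n_primary=n,
        n_met=n,
        panel_size=40,
        met_effects={"G001_mut": 2.0, "G004_amp": 1.5, "G010_mut": -1.5},
        organo_effects={"G002_mut": {"liver": 4.0}},
        mfp_fraction=0.2,
    )
    panel, pathways = generate_panel(config)
    cohort, truth = generate_cohort(config, panel)
    out = {"config": config, "panel": panel, "pathways": pathways,
           "cohort": cohort, "truth": truth}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out_dir)
        panel.table.to_csv(out_dir / "panel.tsv", sep="\t", index=False)
        (out_dir / "pathways.json").write_text(
            json.dumps({k: sorted(v) for k, v in pathways.pathways.items()}, indent=1)
        )
        truth.to_json(out_dir / "truth.json")
        cfg = dataclasses.asdict(config)
        (out_dir / "sim_config.json").write_text(json.dumps(cfg, indent=1, default=str))
    return out
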