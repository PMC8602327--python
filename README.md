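# metanet

Genomic stratification of metastatic risk and organotropism from
panel-sequencing cohorts.

Metastasis drives most cancer deaths, yet at diagnosis a primary tumor's
spatiotemporal behavior — whether it will spread, and where — is largely
unpredictable from TNM staging alone. Large clinical panel-sequencing cohorts
contain thousands of unpaired primary and metastatic tumor genomes; this
package learns the genomic differences between the two states and turns them
into patient-level risk scores. It is written for computational oncologists
and biostatisticians working with cBioPortal-style mutation / copy-number /
clinical tables.

Two models sit at the core:

**Model 1 — Metascore.** A gradient-boosted tree ensemble is trained to
distinguish metastatic from primary samples of one cancer type on engineered
features (per-gene mutation/amplification/deletion flags, TMB, FGA,
chromosome-arm and oncogenic-pathway flags, clinical covariates). Stratified
5-fold cross-validation with an inner 4-fold grid search scores every sample
exactly once; the predicted probability of the metastatic class is the
*Metascore* M ∈ [0, 1]. Primary tumors with M above a threshold are
*Metastasis-Featuring Primaries* (MFP), the rest *Conventional Primaries*
(CP). The threshold is the median of three candidates: the survival split
minimizing the log-rank p, the top-10% rank cut, and the intersection of a
two-component Gaussian mixture. Per-feature contributions are exact
tree-Shapley attributions φ_j on the log-odds margin, with
base + Σ_j φ_j = raw score.

**Model 2 — organotropic stratification.** Ordered labels (primary = 0, bone
metastasis = 1, liver metastasis = 2) are tied to a latent organotropic score
x·β through a cumulative-logit proportional-odds model,
P(y ≤ k | x) = σ(θ_k − x·β) with θ₁ < θ₂. Features are variants nominally
significant in either enrichment screen. Predicted classes stratify primary
tumors into CP / Bone-MFP / Liver-MFP.

Around the models: a pooled two-proportion z-screen for primary-vs-metastasis
enrichment (metastasis-enriched ⇔ log₂FC > 1 and BH q < 0.05); a 2×K
chi-squared screen for organotropic variants (metastatic fraction > 1%,
q < 0.1) with per-site organotropic odds ratios
OGTOR = (a/b)/(c/d) (Haldane–Anscombe corrected) and barycentric
triangle/tetrahedron projection; destination-fraction tables with PCN/MSN
Pearson-correlation networks; Kaplan–Meier, log-rank, and normalized
restricted mean survival ∫₀^τ S(t)dt / τ (τ = 40 months by default); and a
fully seeded synthetic-cohort generator with planted effects for testing all
of the above.

## Worked example

```python
import pandas as pd
from metanet.simulate import SimulationConfig, generate_panel, generate_cohort
from metanet.features import build_feature_matrix, add_pseudo_variants
from metanet.enrichment import primary_vs_met_screen
from metanet import metascore as m1

sig = {f"G{i:03d}_mut": (2.5 if i % 2 == 0 else -2.5) for i in range(16)}
cfg = SimulationConfig(seed=1, n_primary=600, n_met=600, panel_size=40,
                       met_effects=sig,
                       baseline_overrides={v: 0.25 for v in sig},
                       mfp_fraction=0.2, mfp_hazard_ratio=3.0)
panel, pathways = generate_panel(cfg)
cohort, truth = generate_cohort(cfg, panel)
X = add_pseudo_variants(build_feature_matrix(cohort, panel, pathways))
labels = cohort.samples.set_index("sample_id").loc[X.index, "sample_type"]

result, metrics = m1.cv_metascores(X, labels.to_numpy(), k=5, seed=1,
                                   hyper_grid={"max_depth": (3,),
                                               "learning_rate": (0.1,)})
print(f"CV AUROC {metrics.auroc:.3f}")
```

Running the same world through the full pipeline
(`python scripts/acceptance.py --seed 1 --out results/acceptance.json`)
prints:

```
cohort: 1200 samples after site filtering
screens: 16 enriched variants, 1 organotropic hits
model 1: CV AUROC 0.897, consensus threshold 0.629, 94 MFP / 506 CP,
         MFP-vs-CP log-rank p 8.39e-19
attribution check: |base + sum(phi) - raw| = 1.78e-15
model 2: 34 selected features, held-out accuracy 0.709, MAE 0.390
survival: primary normalized RMST 0.640 (tau = 40 months)
```

Reading this: the enrichment screen recovers all 16 planted signature
variants; cross-validated discrimination of metastases from primaries is
AUROC 0.897; the consensus threshold labels 94 of 600 primaries MFP, and
those patients' disease-free survival separates from CP at log-rank
p ≈ 8×10⁻¹⁹ (the planted hazard ratio is 3). The attribution line verifies
the Shapley additivity identity to machine precision, and the
proportional-odds model classifies held-out primary/bone/liver labels with
70.9% exact-match accuracy. A normalized RMST of 0.640 means primary
patients retain on average 64% of the 40-month follow-up window event-free.

## Acceptance script

`scripts/acceptance.py --seed <int> --out <path>` regenerates a seeded
synthetic cohort and recomputes every pipeline stage from scratch — site
filtering, feature engineering, both screens, spreading tables, Model 1 with
consensus thresholding and attributions, Model 2, and survival summaries —
printing the run summary and writing the results JSON to `--out`.

## Command line

A thin `metanet` CLI wraps the library:
`metanet simulate | load | features | enrich | spreading | model1 | model2 | survival`.
See `metanet <cmd> --help`.

## Layout

- `metanet.io` — cohort loading/harmonization (MAF-minimal mutations,
  long/wide CNA calls, clinical table, organ mapping, site filtering)
- `metanet.features` — TMB, FGA, arm flags, pathway flags, feature matrix
- `metanet.stats` — shared test primitives (pooled z, chi-squared, BH,
  rank-sum, Cochran–Armitage trend, Pearson)
- `metanet.enrichment` — primary-vs-met screen, organotropic screen, OGTOR,
  drug-specificity ranking
- `metanet.spreading` — destination fractions, PCN/MSN networks, simplex
  projection, cross-cohort concordance
- `metanet.metascore` — Model 1 (`MetascoreClassifier`, CV, thresholds, MFP)
- `metanet.attribution` — exact tree-Shapley attributions
- `metanet.organotropic` — Model 2 (`ProportionalOddsClassifier`)
- `metanet.survival` — KM, log-rank, normalized RMST
- `metanet.simulate` — seeded synthetic cohorts with planted truth

Methodological details and design rationale: `docs/methods.md`.
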