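# Methods

This note records the models, conventions, numerical choices and known
limitations of the package, in the spirit of a statistical software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort harmonization

Input tables follow cBioPortal export dialects: a minimal MAF
(`Tumor_Sample_Barcode`, `Hugo_Symbol`, optionally `HGVSp_Short`,
`Chromosome`, 1-based `Start_Position`), gene-level discrete copy-number
calls in {−2, −1, 0, 1, 2} (long format, or a wide gene × sample matrix that
is melted on read), and a clinical table with sample type, organ of origin,
biopsy/metastatic site and optional survival columns. Raw tissue labels are
mapped to canonical anatomic organs through a static two-column table (a
default covering 16 origin organs and the 5 explicitly named destination
organs ships as package data); unknown tissues map to `"other"` and are
removed by `filter_sites` rather than raising, mirroring the exclusion of
minor and ambiguous tissues from the source cohorts. Referential integrity
is strict: variant rows naming unknown samples, and duplicated sample ids,
are errors, not warnings.

## Feature engineering

- **Copy-number alteration** means a deep call (−2 or +2); shallow ±1 calls
  are treated as unaltered throughout, matching the discrete-call convention
  of the cohorts the dialects come from.
- **TMB** = mutation count / total panel exon size × 10⁶ (mutations per
  megabase). All mutations in the table count: panel MAFs are pre-filtered
  somatic calls. The high-TMB indicator used as a pseudo-variant cuts at
  20 mut/Mb.
- **FGA** = Σ genomic footprint of deeply altered genes / Σ footprint of all
  panel genes. Whether "size" should be exonic or genomic footprint is
  ambiguous in the field; we use the genomic footprint column and keep the
  exon column available. Duplicate CNA rows count once (set semantics).
- **Arm flags**: an arm is altered iff strictly more than 50% of its panel
  genes carry a deep call; a tie at exactly half stays unaltered ("over
  50%").
- **Pathway flags**: a pathway is aberrant iff any member gene is mutated or
  deeply altered (ten oncogenic pathways by default).
- Clinical covariates are schema-driven: numeric ones pass through with NaN
  for missing (never silently zero — the tree learner routes missing values
  by its default-direction mechanism), categoricals are one-hot with an
  explicit missing level.

## Enrichment screens

The primary-vs-metastasis screen tests each binary variant/feature with the
pooled two-proportion z-test **without continuity correction** (with Yates
correction the screen's published worked example would give p ≈ 0.99 rather
than the printed 0.89, so the uncorrected form is the one in use).
Metastasis-enriched ⇔ log₂(f_met/f_pri) > 1 and BH q < 0.05;
primary-enriched mirrors it. BH correction is applied within each cancer
type (the stratum at which significant-variant counts are reported).

The organotropic screen considers metastases of one cancer type at bone,
brain, liver and lung, excluding regional relapse (destination equal to the
origin organ). Variants with overall metastatic fraction > 1% are tested
with a 2×K Pearson chi-squared against the pooled ("average") fraction —
expected counts are site total × pooled fraction, df = K−1 — with BH q < 0.1
flagging significance. "Average fraction" is operationalized as the pooled
fraction, which makes the test the standard independence chi-squared.
Each record carries per-site OGTORs — odds of the variant at one site over
its odds at the other sites — with the Haldane–Anscombe +0.5 applied to all
four cells whenever any cell is zero, keeping ORs finite for simplex
projection (OGTOR(in↔out) = 1/OGTOR holds exactly, corrected cells
included). Engineered binary features (pathway flags, TMB > 20 mut/Mb, FGA
> 5%) enter both screens as pseudo-variants.

The drug-specificity screen standardizes the drugs × cell-lines AUC matrix
drug-wise (rank statistic: mean standardized AUC in the target group), then
cell-wise on top, and tests each drug one-sided for lower AUC in the target
group (classic two-sample t, BH corrected, ascending-p order).

## Model 1: Metascore

`HistGradientBoostingClassifier` (binary log-loss, native missing-value
routing) stands in for the original gradient-boosting implementation; the
attribution contract is preserved by an exact path-dependent tree-Shapley
implementation over its fitted tree arrays (see below). Cross-validation is
stratified 5-fold; within each outer training set a 4-fold grid search over
depth {3, 4, 6} × learning rate {0.05, 0.1} (≤ 500 trees, early stopping)
selects hyperparameters by mean log-loss. Every sample is scored by the one
model that held it out; AUROC is computed rank-based (Mann–Whitney with
midrank ties), which equals U/(n₊n₋) exactly.

Thresholding the Metascore of primaries supports both the fixed 0.5 cutoff
and the three-method consensus (default):

- *lowest-p*: every observed score is a candidate split; log-rank p between
  the two groups is minimized subject to both groups ≥ max(10, 5% of n) —
  the floor prevents degenerate extreme splits;
- *top-fraction*: the descending-rank cut at 10%, ties shrinking the
  high-risk group;
- *mixture*: a two-component 1-D Gaussian mixture (EM, deterministic
  initialization at the 25th/75th percentiles, tol 1e-6, ≤ 500 iterations);
  the threshold is the root of the weighted density difference between the
  component means, falling back to the midpoint when no root exists.

The final threshold is the median of the available candidates (≥ 2
required). Ties at the threshold go to CP — the conservative direction,
avoiding inflation of the high-risk group.

## Tree-Shapley attribution

The `shap` package is not a dependency; `metanet.attribution` implements the
path-dependent tree-Shapley recursion directly on the fitted tree arrays
(cover counts, split thresholds, default-direction bits). A missing feature
value simply follows each split's missing branch, like any other decision.
Attributions are on the log-odds margin where additivity is exact:
base value (baseline prediction + per-tree cover-weighted expectations) plus
summed attributions equals the raw score; the suite asserts this to 1e-6 and
checks each tree against a brute-force Shapley enumeration oracle to 1e-9.
Complexity is O(leaves × depth²) per tree per sample, adequate at panel
scale.

## Model 2: proportional odds

The ordinal model is fit by direct maximum likelihood (L-BFGS-B with
analytic gradients, convergence at gradient norm 1e-6, ≤ 1000 iterations).
Thresholds are parameterized as θ₁ plus cumulative exponentials, so
θ₁ < θ₂ is structural, not enforced post hoc — the "self-adaptive
thresholding" view of ordinal regression. The logit link is the default
(giving the proportional-odds model); probit is available. The fit is
cross-checked against an independent ordered-logit implementation in the
test suite (agreement to 1e-3 at n = 1,500). Training uses a stratified
50/50 split; accuracy on the held-out half is raw exact-match (unweighted),
with the 3×3 confusion matrix and mean absolute ordinal error alongside.
The class → stratum naming (0 → CP, 1 → Bone-MFP, 2 → Liver-MFP) follows the
prostate application and is configurable for other organ triples; samples
outside {primary, bone, liver} are dropped before fitting.

## Survival

Kaplan–Meier estimation, the (unstratified, hypergeometric-variance)
log-rank test and restricted mean survival are delegated to lifelines behind
the module surface. Normalized RMST is the exact step-function integral
∫₀^τ S(t)dt / τ with τ = 40 months by default — chosen because mean
survival under a fixed follow-up is computable in long-surviving cancers
where the median never crosses. When τ exceeds the last observed time, S is
extended as a constant and the result flagged. The 95% interval is a seeded
nonparametric bootstrap (1,000 subject resamples by default) — the display
interval's construction is otherwise unspecified in the sources this mirrors.

## Synthetic cohorts

The generator states a world and draws from it with a single seeded
generator (same seed ⇒ byte-identical tables): per-variant Bernoulli carrier
fractions (log-uniform on [0.02, 0.30] unless overridden); an additive
met log-odds per variant for metastatic samples; multiplicative organotropic
odds per (variant, destination) — so the measured OGTOR equals the
configured multiplier in expectation; an optional planted MFP subgroup of
primaries that receives the met effects; exponential survival with
log-linear hazard in latent risk and a ×3 hazard for planted MFPs; uniform
right censoring on (0, 80) months.

Two conventions matter for interpreting green tests:

- **Signature carrier fractions are stated, not drawn.** Planted signature
  variants are given fixed recurrent carrier fractions (20–25%), because a
  "signature" variant drawn at a 2% baseline carries almost no per-sample
  information and the recovery checks would then measure the draw, not the
  method.
- **The MFP world is bimodal by construction.** The planted subgroup carries
  a 16-variant signature at log-odds ±2.5, strong enough that the Metascore
  distribution of primaries is bimodal. The consensus threshold methods
  (mixture intersection, lowest-p) presuppose such bimodality — with weak,
  sparse signatures the primary-score distribution is unimodal and no
  threshold method can bracket the planted boundary.

What the generator does **not** emulate: mutational signatures, clonal
structure, linkage between variants, cohort-specific allele-frequency
spectra, informative censoring, or batch effects between cohorts. A green
recovery test therefore establishes correctness of the estimators under the
stated sampling model, not performance on real cohorts.

## Numerical conventions and edge cases

- Normal approximations throughout the test primitives; no exact
  small-sample modes (exact enumeration appears only as a test oracle). The
  rank-sum test uses midranks with tie correction and no continuity
  correction.
- BH adjustment preserves input order and is exactly the step-up; note the
  step-up is *not* idempotent in general (e.g. [0.25, 1] → [0.5, 1] →
  [1, 1]), so only dominance/order properties are asserted.
- log₂ fold change with a zero fraction is ±∞ (direction rules still apply);
  0/0 is defined as 0.
- Chi-squared screens skip degenerate tables (variant absent or universal at
  every site) rather than erroring mid-screen.
- All simulation, CV, EM and bootstrap randomness flows from explicit seeds;
  there is no global random state.

## Known limitations

- Headline numbers from the motivating cohorts (AUROC 0.82/0.80, MFP counts,
  the 93-variant organotropic catalogue, 64.3% ordinal accuracy, 33/24/13
  month mean survivals) are not reproducible here: they require
  controlled-access clinical cohorts. The package reproduces the *methods*
  and validates them on stated synthetic worlds plus the one in-print
  worked example (the pancreatic liver-metastasis proportion test).
- Fusion/rearrangement features are accepted (suffix `_fus`) but no fusion
  dialect parser is provided.
- Network "clustering" of the spreading graphs is limited to connected
  components of kept positive edges; no community detection is attempted.
- The drug screen assumes a complete AUC matrix; missing values are not
  modeled beyond row/column standardization with zero fill for degenerate
  rows.
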