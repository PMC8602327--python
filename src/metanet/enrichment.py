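"""Variant-level enrichment screens.

Three screens are implemented, all operating on binary variant/feature flags
and returning tidy DataFrames (one row per variant = one record):

* primary-vs-metastasis: pooled two-proportion z-test per variant within a
  cancer type; metastasis-enriched means log2(f_met / f_primary) > 1 with
  BH q < 0.05, primary-enriched is the mirror image.
* organotropic: for metastases of one cancer type spread across K
  destination organs, a 2 x K chi-squared test of the variant's site
  fractions against the pooled (average) metastatic fraction; variants with
  overall metastatic fraction > 1% are tested, q < 0.1 flags significance,
  and each record carries the per-site organotropic odds ratio (OGTOR)
  vector and the top site.
* drug specificity: two-stage standardization of a drugs x cell-lines AUC
  matrix (drug-wise, then cell-wise) followed by per-drug one-sided t-tests
  for lower AUC (higher sensitivity) in a target cell-line group, BH
  corrected and sorted by ascending p.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import binary_feature_columns
from .io import Cohort, METASTATIC
from .stats import bh_adjust, chi_square_independence, two_proportion_test

logger = logging.getLogger(__name__)

__all__ = [
    "primary_vs_met_screen",
    "organotropic_screen",
    "compute_ogtor",
    "drug_specificity_screen",
    "DEFAULT_SITES",
]

DEFAULT_SITES = ("bone", "brain", "liver", "lung")


def _log2_fold_change(f_met: float, f_pri: float) -> float:
    if f_met == 0.0 and f_pri == 0.0:
        return 0.0
    if f_pri == 0.0:
        return np.inf
    if f_met == 0.0:
        return -np.inf
    return float(np.log2(f_met / f_pri))


def primary_vs_met_screen(
    features: pd.DataFrame,
    samples: pd.DataFrame,
    cancer_type: Optional[str] = None,
    variant_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-variant primary-vs-metastasis enrichment within one cancer type.

    ``features`` is the sample x feature flag matrix (indexed by sample_id);
    ``samples`` the cohort sample table.  Returns one row per variant with
    fractions, z, p, BH q (within the cancer type) and a direction in
    {metastasis_enriched, primary_enriched, none}.
    """
    meta = samples.set_index("sample_id").reindex(features.index)
    if cancer_type is not None:
        mask = (meta["cancer_type"] == cancer_type).to_numpy()
    else:
        mask = np.ones(len(meta), dtype=bool)
    sub = features.loc[mask]
    types = meta.loc[mask, "sample_type"]
    is_met = (types == METASTATIC).to_numpy()
    n_met, n_pri = int(is_met.sum()), int((~is_met).sum())
    if n_met == 0 or n_pri == 0:
        raise ValueError(
            f"cancer type {cancer_type!r} needs both primary and metastatic samples "
            f"(got {n_pri} primary, {n_met} metastatic)"
        )
    cols = variant_columns if variant_columns is not None else binary_feature_columns(sub)
    rows = []
    for v in cols:
        flags = sub[v].fillna(0).to_numpy()
        k_met = int(flags[is_met].sum())
        k_pri = int(flags[~is_met].sum())
        res = two_proportion_test(k_met, n_met, k_pri, n_pri)
        f_met, f_pri = k_met / n_met, k_pri / n_pri
        rows.append((cancer_type, v, f_pri, f_met,
                     _log2_fold_change(f_met, f_pri), res.statistic, res.p_value))
    out = pd.DataFrame(rows, columns=[
        "cancer_type", "variant", "fraction_primary", "fraction_metastasis",
        "log2_fold_change", "z", "p_value",
    ])
    out["q_value"] = bh_adjust(out["p_value"])
    out["direction"] = "none"
    sig = out["q_value"] < 0.05
    out.loc[sig & (out["log2_fold_change"] > 1), "direction"] = "metastasis_enriched"
    out.loc[sig & (out["log2_fold_change"] < -1), "direction"] = "primary_enriched"
    return out


def compute_ogtor(a: float, b: float, c: float, d: float) -> float:
    """Organotropic odds ratio (a/b) / (c/d) for the 2x2 table

    [[in-site mutant a, in-site wildtype b],
     [out-site mutant c, out-site wildtype d]],

    with the Haldane-Anscombe +0.5 applied to all four cells whenever any
    cell is zero, keeping the ratio finite.
    """
    if a + b <= 0 or c + d <= 0:
        raise ValueError("both the in-site and out-site groups must be non-empty")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d)


def organotropic_screen(
    cohort: Cohort,
    features: pd.DataFrame,
    cancer_type: str,
    sites: Sequence[str] = DEFAULT_SITES,
    min_fraction: float = 0.01,
    q_threshold: float = 0.1,
    variant_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Screen variants for uneven distribution across destination organs.

    Considers metastases of ``cancer_type`` located at ``sites``, excluding
    regional relapse (destination equal to the organ of origin, e.g.
    liver-to-liver).  Variants with overall metastatic fraction above
    ``min_fraction`` are tested with a 2 x K chi-squared against the pooled
    fraction; q < ``q_threshold`` flags significance.  Each row carries
    per-site counts, the OGTOR vector and the top (max-fraction) site.
    """
    s = cohort.samples
    mets = s[(s.sample_type == METASTATIC) & (s.cancer_type == cancer_type)]
    mets = mets[mets.metastatic_site.isin(sites)]
    mets = mets[mets.metastatic_site != mets.cancer_type]  # regional relapse out
    counts = mets.groupby("metastatic_site").size()
    present = [x for x in sites if counts.get(x, 0) > 0]
    if len(present) < 2:
        raise ValueError(
            f"need metastases at >= 2 sites for {cancer_type!r}; have {list(counts.index)}"
        )
    sub = features.reindex(mets.sample_id)
    site_of = mets.set_index("sample_id")["metastatic_site"]
    totals = {x: int(counts[x]) for x in present}
    n_all = sum(totals.values())
    cols = variant_columns if variant_columns is not None else binary_feature_columns(sub)

    rows = []
    for v in cols:
        flags = sub[v].fillna(0)
        k_all = int(flags.sum())
        frac_all = k_all / n_all
        if frac_all <= min_fraction:
            continue
        k_site = {x: int(flags[(site_of == x).to_numpy()].sum()) for x in present}
        table = np.array([[k_site[x] for x in present],
                          [totals[x] - k_site[x] for x in present]], dtype=float)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue  # degenerate: variant absent or universal
        res = chi_square_independence(table)
        ogtor = {}
        for x in present:
            a, b = k_site[x], totals[x] - k_site[x]
            c, d = k_all - k_site[x], (n_all - totals[x]) - (k_all - k_site[x])
            ogtor[x] = compute_ogtor(a, b, c, d)
        fracs = {x: k_site[x] / totals[x] for x in present}
        top_site = max(fracs, key=fracs.get)
        rows.append({
            "cancer_type": cancer_type, "variant": v, "fraction_overall": frac_all,
            "chi2": res.statistic, "df": res.df, "p_value": res.p_value,
            **{f"n_{x}": totals[x] for x in present},
            **{f"k_{x}": k_site[x] for x in present},
            **{f"ogtor_{x}": ogtor[x] for x in present},
            "top_site": top_site,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"])
        out["significant"] = out["q_value"] < q_threshold
        out = out.sort_values("p_value").reset_index(drop=True)
    return out


def drug_specificity_screen(
    auc_matrix: pd.DataFrame, target_group: Iterable[str]
) -> pd.DataFrame:
    """Rank drugs by specific efficacy in a target cell-line group.

    Stage 1 standardizes each drug row of the AUC matrix to mean 0 / sd 1
    (lower AUC = more growth inhibition); drugs are ranked by the mean
    standardized AUC within the target group.  Stage 2 additionally
    standardizes each cell-line column, then tests each drug with a
    one-sided two-sample t-test (target lower than the rest), BH-corrected.
    Returned sorted by ascending p.
    """
    target = [c for c in target_group if c in auc_matrix.columns]
    if len(target) < 2:
        raise ValueError("target group must contain >= 2 cell lines of the matrix")
    rest = [c for c in auc_matrix.columns if c not in set(target)]
    if len(rest) < 2:
        raise ValueError("need >= 2 non-target cell lines")

    row_sd = auc_matrix.std(axis=1, ddof=1).replace(0, np.nan)
    drugwise = auc_matrix.sub(auc_matrix.mean(axis=1), axis=0).div(row_sd, axis=0)
    drugwise = drugwise.fillna(0.0)

    col_sd = drugwise.std(axis=0, ddof=1).replace(0, np.nan)
    cellwise = drugwise.sub(drugwise.mean(axis=0), axis=1).div(col_sd, axis=1)
    cellwise = cellwise.fillna(0.0)

    rows = []
    for drug in auc_matrix.index:
        x = cellwise.loc[drug, target].to_numpy(dtype=float)
        y = cellwise.loc[drug, rest].to_numpy(dtype=float)
        if np.std(x) == 0 and np.std(y) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(x, y, alternative="less")
        rows.append((drug, float(drugwise.loc[drug, target].mean()), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["drug", "mean_std_auc_target", "t", "p_value"])
    out["q_value"] = bh_adjust(out["p_value"])
    return out.sort_values("p_value").reset_index(drop=True)
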