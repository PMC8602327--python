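"""Enrichment screens: rule application, OGTOR arithmetic, planted recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metanet.enrichment import (
    compute_ogtor,
    drug_specificity_screen,
    organotropic_screen,
    primary_vs_met_screen,
)
from metanet.features import add_pseudo_variants, build_feature_matrix
from metanet.simulate import SimulationConfig, generate_cohort, generate_panel


def _features_and_samples(n_pri=60, n_met=60, seed=5, **kw):
    cfg = SimulationConfig(seed=seed, n_primary=n_pri, n_met=n_met, panel_size=20, **kw)
    panel, pathways = generate_panel(cfg)
    cohort, truth = generate_cohort(cfg, panel)
    X = add_pseudo_variants(build_feature_matrix(cohort, panel, pathways))
    return cohort, X, truth


class TestPrimaryVsMet:
    def test_direction_rule_on_constructed_fractions(self):
        # 20% in mets vs 5% in primaries: log2FC = 2 and q tiny -> enriched
        n = 400
        flags = np.r_[np.zeros(n), np.zeros(n)]
        flags[:int(0.05 * n)] = 1          # primaries at 5%
        flags[n:n + int(0.20 * n)] = 1     # metastases at 20%
        X = pd.DataFrame({"V_mut": flags},
                         index=pd.Index([f"s{i}" for i in range(2 * n)], name="sample_id"))
        samples = pd.DataFrame({
            "sample_id": X.index,
            "sample_type": ["primary"] * n + ["metastatic"] * n,
            "cancer_type": "breast",
        })
        rec = primary_vs_met_screen(X, samples, "breast").iloc[0]
        assert rec["log2_fold_change"] == pytest.approx(2.0)
        assert rec["direction"] == "metastasis_enriched"

    def test_equal_fractions_direction_none(self):
        cohort, X, _ = _features_and_samples()
        out = primary_vs_met_screen(X, cohort.samples, "breast")
        flat = out[np.isclose(out.fraction_primary, out.fraction_metastasis)]
        assert (flat["direction"] == "none").all()

    def test_direction_implies_significance(self):
        cohort, X, _ = _features_and_samples(
            n_pri=400, n_met=400,
            met_effects={"G001_mut": 2.0, "G003_mut": -2.0},
        )
        out = primary_vs_met_screen(X, cohort.samples, "breast")
        called = out[out.direction != "none"]
        assert (called["q_value"] < 0.05).all()
        assert (called["log2_fold_change"].abs() > 1).all()

    def test_planted_variant_recovered(self):
        hits = 0
        for seed in range(8):
            cohort, X, _ = _features_and_samples(
                n_pri=1000, n_met=1000, seed=100 + seed,
                met_effects={"G001_mut": 2.0},
                baseline_overrides={"G001_mut": 0.1},
            )
            out = primary_vs_met_screen(X, cohort.samples, "breast").set_index("variant")
            if out.loc["G001_mut", "direction"] == "metastasis_enriched":
                hits += 1
        assert hits >= 7

    def test_single_class_rejected(self):
        cohort, X, _ = _features_and_samples()
        pri_only = cohort.samples[cohort.samples.sample_type == "primary"]
        with pytest.raises(ValueError):
            primary_vs_met_screen(X.loc[pri_only.sample_id], pri_only, "breast")


class TestOgtor:
    def test_arithmetic(self):
        assert compute_ogtor(10, 10, 5, 20) == pytest.approx(4.0)
        assert compute_ogtor(10, 10, 20, 20) == pytest.approx(1.0)

    def test_zero_cell_correction(self):
        # (5.5/5.5) / (0.5/10.5) = 21
        assert compute_ogtor(5, 5, 0, 10) == pytest.approx(21.0)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=100, deadline=None)
    def test_swap_reciprocal(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        assert compute_ogtor(a, b, c, d) == pytest.approx(
            1.0 / compute_ogtor(c, d, a, b), rel=1e-12)
        assert compute_ogtor(a, b, c, d) > 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compute_ogtor(0, 0, 1, 2)


class TestOrganotropicScreen:
    def test_planted_liver_variant_top_site(self):
        cohort, X, _ = _features_and_samples(
            n_pri=10, n_met=600, seed=9,
            organo_effects={"G002_mut": {"liver": 4.0}},
            baseline_overrides={"G002_mut": 0.1},
        )
        out = organotropic_screen(cohort, X, "breast")
        rec = out.set_index("variant").loc["G002_mut"]
        assert rec["top_site"] == "liver"
        assert rec["q_value"] < 0.1

    def test_rare_variant_excluded(self):
        cohort, X, _ = _features_and_samples(
            n_pri=10, n_met=600, seed=9, baseline_overrides={"G005_mut": 0.004})
        out = organotropic_screen(cohort, X, "breast")
        assert "G005_mut" not in set(out["variant"])

    def test_regional_relapse_excluded(self):
        cohort, X, _ = _features_and_samples(n_pri=10, n_met=300, seed=3)
        cohort.samples["cancer_type"] = "liver"  # liver-to-liver relapse must drop
        out = organotropic_screen(cohort, X, "liver")
        assert not any(c == "n_liver" for c in out.columns if len(out))

    def test_fewer_than_two_sites_rejected(self):
        cohort, X, _ = _features_and_samples(
            n_pri=10, n_met=50, seed=4,
            site_distribution={"bone": 1.0})
        with pytest.raises(ValueError):
            organotropic_screen(cohort, X, "breast")

    def test_permuted_site_null_rarely_flags(self):
        # site labels shuffled -> no organotropism; flag rate stays low
        rates = []
        rng = np.random.default_rng(0)
        for seed in range(10):
            cohort, X, _ = _features_and_samples(n_pri=10, n_met=400, seed=200 + seed)
            mets = cohort.samples.sample_type == "metastatic"
            perm = rng.permutation(cohort.samples.loc[mets, "metastatic_site"].to_numpy())
            cohort.samples.loc[mets, "metastatic_site"] = perm
            out = organotropic_screen(cohort, X, "breast")
            rates.append(out["significant"].mean() if len(out) else 0.0)
        assert np.mean(rates) <= 0.12


class TestDrugScreen:
    def _matrix(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        drugs = [f"d{i}" for i in range(30)]
        lines = [f"c{i}" for i in range(120)]
        auc = pd.DataFrame(rng.normal(0.6, 0.1, size=(30, 120)), index=drugs, columns=lines)
        target = lines[:20]
        auc.loc["d0", target] += shift
        return auc, target

    def test_identical_aucs_all_null(self):
        auc = pd.DataFrame(0.5, index=[f"d{i}" for i in range(5)],
                           columns=[f"c{i}" for i in range(30)])
        out = drug_specificity_screen(auc, [f"c{i}" for i in range(5)])
        assert (out["p_value"] == 1.0).all()

    def test_planted_sensitive_drug_ranks_first(self):
        auc, target = self._matrix(seed=1, shift=-0.2)  # -2 sd in the target group
        out = drug_specificity_screen(auc, target)
        assert out.iloc[0]["drug"] == "d0"
        assert out.iloc[0]["q_value"] < 0.01

    def test_drugwise_standardization_moments(self):
        auc, target = self._matrix(seed=2)
        row_sd = auc.std(axis=1, ddof=1)
        std = auc.sub(auc.mean(axis=1), axis=0).div(row_sd, axis=0)
        assert np.allclose(std.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(std.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_small_target_group_rejected(self):
        auc, _ = self._matrix()
        with pytest.raises(ValueError):
            drug_specificity_screen(auc, ["c0"])
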