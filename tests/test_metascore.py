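"""Model 1: CV scoring, AUROC, thresholding and MFP/CP stratification."""

import numpy as np
import pandas as pd
import pytest

from metanet.metascore import (
    MetascoreClassifier,
    compute_auroc,
    consensus_threshold,
    cv_metascores,
    score_external,
    stratified_kfold_split,
    stratify_mfp,
    threshold_gmm,
    threshold_lowest_p,
    threshold_top_fraction,
)
from metanet.simulate import generate_stratified_survival

FAST_GRID = {"max_depth": (3,), "learning_rate": (0.1,)}


def _toy_features(n=400, p=12, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < 0.25).astype(float)
    logit = X[:, :4].sum(axis=1) * 1.5 - 1.5 if signal else np.zeros(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    return pd.DataFrame(X, index=idx, columns=[f"v{j}" for j in range(p)]), y


class TestStratifiedKfold:
    def test_fold_class_balance(self):
        y = np.r_[np.zeros(100, int), np.ones(50, int)]
        folds = stratified_kfold_split(y, k=5, seed=1)
        for f in range(5):
            sel = folds == f
            assert sel.sum() == 30
            assert (y[sel] == 1).sum() == 10

    def test_deterministic_and_conserving(self):
        y = np.r_[np.zeros(40, int), np.ones(23, int)]
        f1 = stratified_kfold_split(y, k=5, seed=9)
        f2 = stratified_kfold_split(y, k=5, seed=9)
        assert np.array_equal(f1, f2)
        assert np.bincount(f1).sum() == y.size

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold_split(np.r_[np.zeros(10, int), np.ones(3, int)], k=5)


class TestAuroc:
    def test_perfect_and_uninformative(self):
        assert compute_auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]).auroc == 1.0
        assert compute_auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]).auroc == 0.5

    def test_pair_enumeration_example(self):
        # pos {0.9, 0.4}, neg {0.5, 0.1}: 3 of 4 pairs concordant
        assert compute_auroc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]).auroc == 0.75

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(10, 50))
            s = np.round(rng.random(n), 2)  # ties likely
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            pos, neg = s[y == 1], s[y == 0]
            brute = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            brute /= len(pos) * len(neg)
            assert compute_auroc(s, y).auroc == pytest.approx(brute, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auroc([0.1, 0.2], [1, 1])


class TestCvMetascores:
    def test_each_sample_scored_once_and_separable_signal(self):
        X, y = _toy_features(seed=1)
        result, metrics = cv_metascores(X, y, k=5, seed=2, hyper_grid=FAST_GRID)
        assert len(result) == len(X)
        assert result["sample_id"].is_unique
        assert sorted(result["fold"].unique()) == [0, 1, 2, 3, 4]
        assert metrics.auroc > 0.65

    def test_reproducible_given_seed(self):
        X, y = _toy_features(seed=2)
        r1, _ = cv_metascores(X, y, k=5, seed=3, hyper_grid=FAST_GRID)
        r2, _ = cv_metascores(X, y, k=5, seed=3, hyper_grid=FAST_GRID)
        pd.testing.assert_frame_equal(r1, r2)

    def test_string_labels_positive_class(self):
        X, y = _toy_features(seed=3)
        labels = np.where(y == 1, "metastatic", "primary")
        result, metrics = cv_metascores(X, labels, k=5, seed=0, hyper_grid=FAST_GRID)
        high = result.nlargest(50, "metascore")["label"]
        assert (high == "metastatic").mean() > 0.5


class TestThresholds:
    def test_lowest_p_finds_planted_split(self):
        rng = np.random.default_rng(6)
        n = 300
        scores = rng.uniform(0, 1, n)
        high = scores > 0.6
        t = np.where(high, rng.exponential(5, n), rng.exponential(40, n))
        surv = pd.DataFrame({"time": t, "event": np.ones(n, int)})
        thr = threshold_lowest_p(scores, surv)
        assert 0.5 < thr < 0.7

    def test_lowest_p_respects_min_group(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0, 1, 100)
        surv = pd.DataFrame({"time": rng.exponential(20, 100),
                             "event": np.ones(100, int)})
        thr = threshold_lowest_p(scores, surv)
        assert 10 <= (scores > thr).sum() <= 90

    def test_top_fraction_rank_cut(self):
        scores = np.arange(1, 101) / 100.0
        thr = threshold_top_fraction(scores, 0.10)
        assert (scores > thr).sum() == 10
        thr_half = threshold_top_fraction(np.arange(20) / 20.0, 0.5)
        assert (np.arange(20) / 20.0 > thr_half).sum() == 10

    def test_top_fraction_all_tied_empty_group(self):
        scores = np.full(50, 0.3)
        thr = threshold_top_fraction(scores, 0.10)
        assert (scores > thr).sum() == 0

    def test_gmm_symmetric_mixture_midpoint(self):
        rng = np.random.default_rng(8)
        s = np.r_[rng.normal(0.1, 0.05, 500), rng.normal(0.9, 0.05, 500)]
        thr = threshold_gmm(s)
        assert thr == pytest.approx(0.5, abs=0.03)

    def test_gmm_unbalanced_mixture_shifts_toward_minor(self):
        # root of w1 N(x; .1, .05) = w2 N(x; .9, .05) with w1/w2 = 9:
        # x = 0.5 + sigma^2 ln(w1/w2) / (m2 - m1) ~= 0.5069
        rng = np.random.default_rng(9)
        s = np.r_[rng.normal(0.1, 0.05, 4500), rng.normal(0.9, 0.05, 500)]
        thr = threshold_gmm(s)
        assert thr == pytest.approx(0.5069, abs=0.01)
        assert thr > 0.5

    def test_gmm_unimodal_fallback(self):
        rng = np.random.default_rng(10)
        thr = threshold_gmm(rng.normal(0.5, 0.02, 200))
        assert 0.4 < thr < 0.6

    def test_consensus_median_and_range(self):
        rng = np.random.default_rng(11)
        n = 400
        scores = np.r_[rng.uniform(0, 0.4, 320), rng.uniform(0.6, 1.0, 80)]
        high = scores > 0.5
        t = np.where(high, rng.exponential(5, n), rng.exponential(40, n))
        surv = pd.DataFrame({"time": t, "event": np.ones(n, int)})
        res = consensus_threshold(scores, surv)
        assert len(res.candidates) == 3
        assert min(res.candidates.values()) <= res.final <= max(res.candidates.values())
        assert res.final == pytest.approx(
            float(np.median(list(res.candidates.values()))))


class TestStratify:
    def test_mfp_rule_and_tie_policy(self):
        cls = stratify_mfp([0.7, 0.3, 0.5], threshold=0.5)
        assert list(cls) == ["MFP", "CP", "CP"]  # ties go to CP


class TestExternalScoring:
    def test_identical_sample_identical_score_and_column_permutation(self):
        X, y = _toy_features(seed=12)
        clf = MetascoreClassifier(max_iter=30).fit(X, y)
        ext = X.iloc[:20]
        s1 = score_external(clf, ext)["metascore"]
        s2 = score_external(clf, ext[list(ext.columns[::-1])])["metascore"]
        np.testing.assert_allclose(s1, s2)
        np.testing.assert_allclose(s1, clf.metascore(ext))

    def test_missing_columns_listed(self):
        X, y = _toy_features(seed=13)
        clf = MetascoreClassifier(max_iter=10).fit(X, y)
        with pytest.raises(ValueError, match="v11"):
            clf.metascore(X.drop(columns=["v11"]))

    def test_external_auroc_close_to_cv(self):
        X, y = _toy_features(n=1000, seed=14)
        Xe, ye = _toy_features(n=600, seed=15)
        _, cv_metrics = cv_metascores(X, y, k=5, seed=1, hyper_grid=FAST_GRID)
        clf = MetascoreClassifier().fit(X, y)
        ext_auroc = compute_auroc(clf.metascore(Xe), ye).auroc
        assert abs(ext_auroc - cv_metrics.auroc) < 0.07


def test_survival_ordering_generator_sanity():
    df = generate_stratified_survival([0.02, 0.08], 300, seed=0)
    g0 = df[df.group == 0]
    g1 = df[df.group == 1]
    assert g0.time.mean() > g1.time.mean()
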