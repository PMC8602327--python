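"""Model 1: the metastasis-vs-primary classifier and MFP stratification.

A gradient-boosted decision-tree ensemble learns to tell metastatic from
primary samples on the engineered feature matrix.  Its predicted probability
of the metastatic class is the *Metascore*.  In cross-validation mode every
sample is scored exactly once by a model that never saw it, via stratified
5-fold splitting with hyperparameters chosen on an inner 4-fold grid search.
Primary samples whose Metascore exceeds a threshold are called
Metastasis-Featuring Primary (MFP); the rest are Conventional Primary (CP).
Three candidate thresholds are supported — the survival split with the
lowest log-rank p, the top-10% rank cut, and the intersection of a
two-component Gaussian mixture — with the consensus being their median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import log_loss
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .attribution import AttributionRecord, attribute_features
from .survival import logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "MetascoreClassifier",
    "CvMetrics",
    "ThresholdResult",
    "stratified_kfold_split",
    "cv_metascores",
    "compute_auroc",
    "threshold_lowest_p",
    "threshold_top_fraction",
    "threshold_gmm",
    "consensus_threshold",
    "stratify_mfp",
    "score_external",
    "DEFAULT_HYPER_GRID",
]

POSITIVE_LABEL = "metastatic"
DEFAULT_HYPER_GRID = {"max_depth": (3, 4, 6), "learning_rate": (0.05, 0.1)}


@dataclass
class CvMetrics:
    """AUROC with the ROC polyline and (in CV mode) per-fold AUROCs."""

    auroc: float
    roc: pd.DataFrame
    per_fold: list = field(default_factory=list)


@dataclass
class ThresholdResult:
    candidates: Mapping[str, float]
    final: float
    method: str = "consensus"


class MetascoreClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted tree classifier for metastatic-vs-primary profiles.

    A thin, schema-aware estimator around
    :class:`~sklearn.ensemble.HistGradientBoostingClassifier` with binary
    log-loss, up to ``max_iter`` trees and early stopping.  Missing clinical
    values (NaN) are routed by each split's default direction — never
    imputed.  ``predict_proba(...)[:, 1]`` is the Metascore.

    Parameters
    ----------
    max_depth : int
        Tree depth.
    learning_rate : float
        Shrinkage per boosting step.
    max_iter : int
        Maximum number of trees (early stopping usually uses fewer).
    random_state : int
        Seed for subsampling and the early-stopping validation split.
    """

    def __init__(
        self,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        max_iter: int = 500,
        early_stopping: bool = True,
        random_state: int = 0,
    ):
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.early_stopping = early_stopping
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._coerce(X, y, fit=True)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError(f"need both classes in training data, got {classes}")
        self.model_ = HistGradientBoostingClassifier(
            loss="log_loss",
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            max_iter=self.max_iter,
            early_stopping=self.early_stopping,
            validation_fraction=0.1,
            n_iter_no_change=10,
            random_state=self.random_state,
        )
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def _coerce(self, X, y=None, fit: bool = False):
        if isinstance(X, pd.DataFrame):
            if fit:
                self.feature_names_ = list(X.columns)
            else:
                missing = [c for c in self.feature_names_ if c not in X.columns]
                if missing:
                    raise ValueError(f"feature matrix missing training columns: {missing}")
                X = X[self.feature_names_]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if fit:
                self.feature_names_ = [f"f{i}" for i in range(X.shape[1])]
        if y is None:
            return X
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            y = (y == POSITIVE_LABEL).astype(int)
        return X, y

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._coerce(X))

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.decision_function(self._coerce(X))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def metascore(self, X) -> np.ndarray:
        """Predicted probability of the metastatic class."""
        return self.predict_proba(X)[:, 1]

    def attribute(self, X: pd.DataFrame) -> list[AttributionRecord]:
        """Exact per-feature attributions on the log-odds margin."""
        check_is_fitted(self, "model_")
        return attribute_features(self, X)


def stratified_kfold_split(labels: Sequence, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per sample with per-fold class ratios within one sample
    of the global ratio; deterministic given the seed."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k={k} members (have {counts.min()})")
    folds = np.empty(y.size, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        folds[test_idx] = f
    return folds


def _grid_combos(hyper_grid: Mapping[str, Sequence]) -> list[dict]:
    keys = list(hyper_grid)
    combos = [{}]
    for key in keys:
        combos = [{**c, key: v} for c in combos for v in hyper_grid[key]]
    return combos


def _select_hyperparams(
    X: pd.DataFrame, y: np.ndarray, combos: list[dict], seed: int, inner_k: int = 4
) -> dict:
    if len(combos) == 1:
        return combos[0]
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    best, best_loss = combos[0], np.inf
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    for combo in combos:
        losses = []
        for tr, te in skf.split(Xv, y):
            clf = MetascoreClassifier(random_state=seed, **combo).fit(Xv[tr], y[tr])
            losses.append(log_loss(y[te], clf.predict_proba(Xv[te])[:, 1], labels=[0, 1]))
        loss = float(np.mean(losses))
        if loss < best_loss:
            best, best_loss = combo, loss
    logger.debug("inner CV selected %s (log-loss %.4f)", best, best_loss)
    return best


def cv_metascores(
    features: pd.DataFrame,
    labels: Sequence,
    k: int = 5,
    seed: int = 0,
    hyper_grid: Optional[Mapping[str, Sequence]] = None,
) -> tuple[pd.DataFrame, CvMetrics]:
    """Cross-validated Metascores: each sample scored by the model of the one
    fold that held it out.

    For each of the ``k`` outer folds, hyperparameters are selected by a
    4-fold inner grid search (binary log-loss) on the remaining data, the
    ensemble is refit and the held-out fold scored.  Returns the per-sample
    table (sample_id, metascore, fold, label) and pooled/per-fold AUROC.
    """
    y_raw = np.asarray(labels)
    y = (y_raw == POSITIVE_LABEL).astype(int) if y_raw.dtype.kind in "OUS" else y_raw.astype(int)
    combos = _grid_combos(hyper_grid if hyper_grid is not None else DEFAULT_HYPER_GRID)
    folds = stratified_kfold_split(y, k=k, seed=seed)
    scores = np.empty(y.size)
    per_fold = []
    for f in range(k):
        te = folds == f
        tr = ~te
        Xtr, ytr = features.iloc[tr], y[tr]
        if np.unique(ytr).size < 2:
            raise ValueError(f"training data of fold {f} contains one class only")
        params = _select_hyperparams(Xtr, ytr, combos, seed=seed + 1)
        clf = MetascoreClassifier(random_state=seed, **params).fit(Xtr, ytr)
        scores[te] = clf.metascore(features.iloc[te])
        per_fold.append(compute_auroc(scores[te], y[te]).auroc)
    result = pd.DataFrame({
        "sample_id": features.index,
        "metascore": scores,
        "fold": folds,
        "label": np.where(y == 1, POSITIVE_LABEL, "primary"),
    })
    metrics = compute_auroc(scores, y)
    metrics.per_fold = per_fold
    return result, metrics


def compute_auroc(scores: Sequence[float], labels: Sequence) -> CvMetrics:
    """Rank-based (Mann-Whitney, midrank ties) AUROC with ROC points."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == POSITIVE_LABEL).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = pd.Series(s).rank(method="average").to_numpy()
    u = order[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auroc = u / (n_pos * n_neg)
    # trapezoidal ROC polyline over distinct thresholds
    desc = np.argsort(-s, kind="mergesort")
    tp = np.cumsum(y[desc] == 1)
    fp = np.cumsum(y[desc] == 0)
    distinct = np.append(np.where(np.diff(s[desc]))[0], s.size - 1)
    roc = pd.DataFrame({
        "fpr": np.concatenate([[0.0], fp[distinct] / n_neg]),
        "tpr": np.concatenate([[0.0], tp[distinct] / n_pos]),
        "threshold": np.concatenate([[np.inf], s[desc][distinct]]),
    })
    return CvMetrics(auroc=float(auroc), roc=roc)


def threshold_lowest_p(
    metascores: Sequence[float],
    survival: pd.DataFrame,
    min_group: Optional[int] = None,
) -> float:
    """The Metascore split minimizing the two-group log-rank p-value.

    Every observed Metascore is a candidate cut (groups: above vs at-or-
    below); candidates leaving either group smaller than
    ``max(10, 5% of n)`` are inadmissible.
    """
    s = np.asarray(metascores, dtype=float)
    t = survival["time"].to_numpy(dtype=float)
    e = survival["event"].to_numpy(dtype=int)
    if s.size != t.size:
        raise ValueError("metascores and survival must align")
    n = s.size
    lo = max(10, int(np.ceil(0.05 * n))) if min_group is None else min_group
    best_thr, best_p = None, np.inf
    for cand in np.unique(s):
        hi_mask = s > cand
        n_hi = int(hi_mask.sum())
        if n_hi < lo or n - n_hi < lo:
            continue
        res = logrank_test((t[hi_mask], e[hi_mask]), (t[~hi_mask], e[~hi_mask]))
        if res.p_value < best_p:
            best_thr, best_p = float(cand), res.p_value
    if best_thr is None:
        raise ValueError("no admissible candidate threshold (groups too small)")
    logger.debug("lowest-p threshold %.4f (p=%.3g)", best_thr, best_p)
    return best_thr


def threshold_top_fraction(metascores: Sequence[float], fraction: float = 0.10) -> float:
    """Descending-rank cut keeping the top ``fraction`` as high risk.

    Ties at the cut shrink the high-risk group (conservative).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    s = np.sort(np.asarray(metascores, dtype=float))[::-1]
    if s.size < 10:
        raise ValueError("need >= 10 samples")
    n_top = int(s.size * fraction)
    thr = float(s[n_top]) if n_top < s.size else float(s[-1])
    if (np.asarray(metascores) > thr).sum() == 0:
        logger.warning("top-fraction threshold leaves the high-risk group empty (ties)")
    return thr


def threshold_gmm(metascores: Sequence[float], seed: int = 0) -> float:
    """Intersection of a two-component 1-D Gaussian mixture fit by EM.

    Deterministic initialization at the 25th/75th percentile, tol 1e-6,
    at most 500 iterations.  The threshold is the root of the weighted
    density difference between the two component means; when no root exists
    (unimodal fit or degenerate variance) the midpoint of the means is used.
    """
    s = np.asarray(metascores, dtype=float).reshape(-1, 1)
    if s.size < 20:
        raise ValueError("need >= 20 samples for the mixture fit")
    q25, q75 = np.percentile(s, [25, 75])
    var = max(float(np.var(s)), 1e-12)
    gmm = GaussianMixture(
        n_components=2,
        means_init=[[q25], [q75]],
        weights_init=[0.5, 0.5],
        precisions_init=[[[1.0 / var]], [[1.0 / var]]],
        tol=1e-6,
        max_iter=500,
        random_state=seed,
    ).fit(s)
    (m1,), (m2,) = gmm.means_
    (w1, w2) = gmm.weights_
    (s1,), (s2,) = np.sqrt(gmm.covariances_[:, 0])
    if m1 > m2:
        m1, m2, w1, w2, s1, s2 = m2, m1, w2, w1, s2, s1
    if s1 < 1e-9 or s2 < 1e-9 or abs(m2 - m1) < 1e-12:
        logger.warning("degenerate mixture; falling back to midpoint of means")
        return float((m1 + m2) / 2.0)

    def diff(x: float) -> float:
        return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

    if diff(m1) * diff(m2) < 0:
        return float(brentq(diff, m1, m2, xtol=1e-10))
    logger.warning("no density intersection between means; using midpoint")
    return float((m1 + m2) / 2.0)


def consensus_threshold(
    metascores: Sequence[float], survival: pd.DataFrame, seed: int = 0
) -> ThresholdResult:
    """Median of the lowest-p, top-10% and mixture-intersection thresholds.

    A failing candidate method is dropped with a warning; at least two must
    succeed.
    """
    candidates: dict[str, float] = {}
    for name, fn in (
        ("lowest_p", lambda: threshold_lowest_p(metascores, survival)),
        ("top_fraction", lambda: threshold_top_fraction(metascores)),
        ("gmm", lambda: threshold_gmm(metascores, seed=seed)),
    ):
        try:
            candidates[name] = fn()
        except ValueError as err:
            logger.warning("threshold method %s failed: %s", name, err)
    if len(candidates) < 2:
        raise ValueError(f"fewer than two threshold methods succeeded: {candidates}")
    final = float(np.median(list(candidates.values())))
    return ThresholdResult(candidates=candidates, final=final)


def stratify_mfp(metascores: Sequence[float], threshold: float) -> np.ndarray:
    """MFP iff Metascore strictly exceeds the threshold, else CP."""
    s = np.asarray(metascores, dtype=float)
    return np.where(s > threshold, "MFP", "CP")


def score_external(
    model: MetascoreClassifier, external_features: pd.DataFrame
) -> pd.DataFrame:
    """Metascores for an external cohort from a refit-on-all model.

    Columns are aligned by name (order-insensitive); missing training
    columns raise with their names.
    """
    scores = model.metascore(external_features)
    return pd.DataFrame({
        "sample_id": external_features.index,
        "metascore": scores,
    })
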