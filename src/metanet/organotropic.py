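"""Model 2: ordinal stratification by metastatic-organ propensity.

Metastatic dissemination is modeled as an ordered progression — e.g. for
prostate cancer: primary (0) < bone metastasis (1) < liver metastasis (2),
matching the observed survival ordering.  A cumulative-link proportional-
odds model ties a single latent *organotropic score* x.beta to the ordered
labels through monotone cut-points theta_1 < theta_2:

    P(y <= k | x) = link(theta_k - x.beta)

so any two samples differ by the same amount in cumulative log-odds at
every level (the proportional-odds property).  Primary tumors are then
stratified by their predicted class into CP / Bone-MFP / Liver-MFP.
Features are chosen from the enrichment screens: variants nominally
significant in either the primary-vs-metastasis proportion test or the
organotropic chi-squared screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "ProportionalOddsClassifier",
    "PomFitResult",
    "DEFAULT_STRATA",
    "select_organotropic_features",
    "fit_pom",
    "predict_pom",
    "evaluate_accuracy",
    "stratify_external",
]

DEFAULT_STRATA = ("CP", "Bone-MFP", "Liver-MFP")


class ProportionalOddsClassifier(BaseEstimator, ClassifierMixin):
    """Cumulative-link ordinal regression with monotone thresholds.

    Maximum-likelihood fit of ``P(y <= k | x) = link(theta_k - x.beta)`` for
    ordered integer labels 0..K-1.  Thresholds are kept strictly increasing
    by an exponential-increment parameterization, so ordering is a property
    of the optimizer's search space, not a post-hoc fix.

    Parameters
    ----------
    link : {"logit", "probit"}
        Cumulative link; the logit link gives the proportional-odds model.
    tol : float
        Gradient-norm convergence criterion.
    max_iter : int
        Iteration cap for the quasi-Newton optimizer.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        beta, the shared slope vector.
    theta_ : ndarray of shape (K - 1,)
        Strictly increasing cut-points.
    """

    def __init__(self, link: str = "logit", tol: float = 1e-6, max_iter: int = 1000):
        self.link = link
        self.tol = tol
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------
    def _cdf(self, z):
        return expit(z) if self.link == "logit" else norm.cdf(z)

    def _pdf(self, z):
        if self.link == "logit":
            p = expit(z)
            return p * (1.0 - p)
        return norm.pdf(z)

    def _unpack(self, params, p, K):
        beta = params[:p]
        theta = np.empty(K - 1)
        theta[0] = params[p]
        if K > 2:
            theta[1:] = params[p] + np.cumsum(np.exp(params[p + 1:]))
        return beta, theta

    def _nll_grad(self, params, X, y, K):
        n, p = X.shape
        beta, theta = self._unpack(params, p, K)
        eta = X @ beta
        z = theta[None, :] - eta[:, None]               # (n, K-1)
        cum = self._cdf(z)
        dens = self._pdf(z)
        upper = np.hstack([cum, np.ones((n, 1))])       # P(y <= k), k = 0..K-1
        lower = np.hstack([np.zeros((n, 1)), cum])
        prob = np.clip(upper - lower, 1e-12, 1.0)
        pk = prob[np.arange(n), y]
        nll = -np.log(pk).sum()

        dens_up = np.hstack([dens, np.zeros((n, 1))])[np.arange(n), y]
        dens_lo = np.hstack([np.zeros((n, 1)), dens])[np.arange(n), y]
        # d nll / d eta = (dens_up - dens_lo) / pk
        deta = (dens_up - dens_lo) / pk
        gbeta = X.T @ deta
        # d nll / d theta_j: -dens/pk where j = y, +dens/pk where j = y - 1
        gtheta = np.zeros(K - 1)
        for j in range(K - 1):
            sel_up = y == j
            gtheta[j] -= (dens[sel_up, j] / pk[sel_up]).sum()
            sel_lo = y == j + 1
            gtheta[j] += (dens[sel_lo, j] / pk[sel_lo]).sum()
        grad = np.empty_like(params)
        grad[:p] = gbeta
        grad[p] = gtheta.sum()
        if K > 2:
            for l in range(1, K - 1):
                grad[p + l] = np.exp(params[p + l]) * gtheta[l:].sum()
        return nll, grad

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_ = [f"f{i}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        K = classes.size
        if K < 2 or not np.array_equal(classes, np.arange(K)):
            raise ValueError(f"labels must be 0..K-1 with every class present, got {classes}")
        p = X.shape[1]
        x0 = np.zeros(p + (K - 1))
        freq = np.bincount(y) / y.size
        cum0 = np.cumsum(freq)[:-1]
        if self.link == "logit":
            t0 = np.log(cum0 / (1 - cum0))
        else:
            t0 = norm.ppf(cum0)
        x0[p] = t0[0]
        if K > 2:
            x0[p + 1:] = np.log(np.clip(np.diff(t0), 1e-3, None))
        res = minimize(
            self._nll_grad, x0, args=(X, y, K), jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.tol, "ftol": 1e-12},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        if not res.success and gnorm > 1e-3:
            raise RuntimeError(
                f"proportional-odds fit did not converge: {res.message} "
                f"(iterations={res.nit}, |grad|={gnorm:.3g})"
            )
        self.coef_, self.theta_ = self._unpack(res.x, p, K)
        self.classes_ = classes
        self.n_features_in_ = p
        self.n_iter_ = res.nit
        self.converged_ = bool(res.success)
        return self

    def _coerce(self, X):
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_ if c not in X.columns]
            if missing:
                raise ValueError(f"feature matrix missing training columns: {missing}")
            X = X[self.feature_names_]
        return np.asarray(X, dtype=float)

    def decision_function(self, X) -> np.ndarray:
        """The latent organotropic score x.beta."""
        check_is_fitted(self, "coef_")
        return self._coerce(X) @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        eta = self.decision_function(X)
        cum = self._cdf(self.theta_[None, :] - eta[:, None])
        n = eta.size
        upper = np.hstack([cum, np.ones((n, 1))])
        lower = np.hstack([np.zeros((n, 1)), cum])
        return upper - lower

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def select_organotropic_features(
    enrichment: pd.DataFrame,
    organotropism: pd.DataFrame,
    alpha: float = 0.05,
) -> list[str]:
    """Variants nominally significant (p < alpha) in either screen.

    Engineered pseudo-variants (pathway flags, FGA bin, high-TMB flag) are
    eligible on the same footing as gene variants.
    """
    keep: set[str] = set()
    if len(enrichment):
        keep |= set(enrichment.loc[enrichment["p_value"] < alpha, "variant"])
    if len(organotropism):
        keep |= set(organotropism.loc[organotropism["p_value"] < alpha, "variant"])
    if not keep:
        raise ValueError(
            f"no variant reaches p < {alpha} in either screen; relax the threshold"
        )
    universe = list(enrichment.get("variant", pd.Series(dtype=str))) + list(
        organotropism.get("variant", pd.Series(dtype=str))
    )
    return sorted(keep & set(universe))


@dataclass
class PomFitResult:
    model: ProportionalOddsClassifier
    train_index: pd.Index
    test_index: pd.Index


def fit_pom(
    features: pd.DataFrame,
    labels: Sequence[int],
    split_seed: int = 0,
    link: str = "logit",
) -> PomFitResult:
    """Fit the proportional-odds model on a stratified half of the samples.

    The other half is reserved for accuracy evaluation.  All classes must be
    present in the training half.
    """
    y = np.asarray(labels, dtype=int)
    idx_train, idx_test = train_test_split(
        np.arange(y.size), test_size=0.5, stratify=y, random_state=split_seed
    )
    if np.unique(y[idx_train]).size != np.unique(y).size:
        raise ValueError("a class is absent from the training half")
    model = ProportionalOddsClassifier(link=link).fit(features.iloc[idx_train], y[idx_train])
    return PomFitResult(
        model=model,
        train_index=features.index[np.sort(idx_train)],
        test_index=features.index[np.sort(idx_test)],
    )


def predict_pom(
    model: ProportionalOddsClassifier,
    features: pd.DataFrame,
    strata: Sequence[str] = DEFAULT_STRATA,
) -> pd.DataFrame:
    """Latent scores, class probabilities and stratum names per sample."""
    proba = model.predict_proba(features)
    pred = np.argmax(proba, axis=1)
    out = pd.DataFrame({
        "sample_id": features.index,
        "organotropic_score": model.decision_function(features),
        "predicted_class": pred,
        "stratum": [strata[k] for k in pred],
    })
    for k in range(proba.shape[1]):
        out[f"p{k}"] = proba[:, k]
    return out


def evaluate_accuracy(
    predictions: pd.DataFrame, true_labels: Sequence[int]
) -> tuple[float, pd.DataFrame, float]:
    """Raw exact-match accuracy, 3x3 confusion matrix, and mean absolute
    ordinal error on held-out labels."""
    y = np.asarray(true_labels, dtype=int)
    yhat = predictions["predicted_class"].to_numpy(dtype=int)
    if y.size != yhat.size:
        raise ValueError("prediction/label length mismatch")
    K = max(y.max(), yhat.max()) + 1
    conf = np.zeros((K, K), dtype=int)
    for a, b in zip(y, yhat):
        conf[a, b] += 1
    confusion = pd.DataFrame(
        conf,
        index=pd.Index(range(K), name="true"),
        columns=pd.Index(range(K), name="predicted"),
    )
    accuracy = float((y == yhat).mean())
    mae = float(np.abs(y - yhat).mean())
    return accuracy, confusion, mae


def stratify_external(
    model: ProportionalOddsClassifier,
    features: pd.DataFrame,
    strata: Sequence[str] = DEFAULT_STRATA,
) -> pd.DataFrame:
    """Stratum assignment for an external primary-only cohort."""
    out = predict_pom(model, features, strata=strata)
    sizes = out["stratum"].value_counts().to_dict()
    logger.info("external stratification group sizes: %s", sizes)
    return out
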