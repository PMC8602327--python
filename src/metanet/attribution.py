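"""Exact additive feature attributions for gradient-boosted trees.

Implements the path-dependent tree-Shapley algorithm: for every sample the
per-feature attributions on the raw (log-odds) margin sum, together with the
base value (the cover-weighted expectation of the ensemble), exactly to the
model's raw score.  Works directly on the fitted tree arrays of sklearn's
``HistGradientBoostingClassifier``, including its default-direction handling
of missing values (a NaN simply follows each split's missing branch, like
any other decision).

The recursion keeps a path of the features encountered so far, each with the
fraction of "zero" (cover-weighted) and "one" (decision-following) paths
that flow through, and a vector of permutation weights; extending and
unwinding that path yields each feature's exact Shapley weight at every
leaf.  Complexity is O(leaves x depth^2) per tree per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["tree_shap_values", "attribute_features", "expected_raw_score", "AttributionRecord"]


@dataclass
class AttributionRecord:
    sample_id: str
    base_value: float
    attributions: dict[str, float]

    @property
    def raw_score(self) -> float:
        return self.base_value + sum(self.attributions.values())


class _Path:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self):
        self.d: list[int] = []   # feature index entering each path element
        self.z: list[float] = []  # fraction of zero (cover) paths
        self.o: list[float] = []  # fraction of one (decision) paths
        self.w: list[float] = []  # permutation weights

    def copy(self) -> "_Path":
        p = _Path()
        p.d = self.d.copy(); p.z = self.z.copy()
        p.o = self.o.copy(); p.w = self.w.copy()
        return p

    def extend(self, pz: float, po: float, pi: int) -> None:
        l = len(self.d)
        self.d.append(pi); self.z.append(pz); self.o.append(po)
        self.w.append(1.0 if l == 0 else 0.0)
        for i in range(l - 1, -1, -1):
            self.w[i + 1] += po * self.w[i] * (i + 1) / (l + 1)
            self.w[i] = pz * self.w[i] * (l - i) / (l + 1)

    def unwind(self, i: int) -> None:
        l = len(self.d) - 1
        n = self.w[l]
        oi, zi = self.o[i], self.z[i]
        for j in range(l - 1, -1, -1):
            if oi != 0:
                t = self.w[j]
                self.w[j] = n * (l + 1) / ((j + 1) * oi)
                n = t - self.w[j] * zi * (l - j) / (l + 1)
            else:
                self.w[j] = self.w[j] * (l + 1) / (zi * (l - j))
        for arrs in (self.d, self.z, self.o):
            del arrs[i]
        del self.w[-1]  # path shortens by one; weights live per position

    def unwound_sum(self, i: int) -> float:
        l = len(self.d) - 1
        n = self.w[l]
        oi, zi = self.o[i], self.z[i]
        total = 0.0
        for j in range(l - 1, -1, -1):
            if oi != 0:
                tmp = n * (l + 1) / ((j + 1) * oi)
                total += tmp
                n = self.w[j] - tmp * zi * (l - j) / (l + 1)
            else:
                total += self.w[j] * (l + 1) / (zi * (l - j))
        return total


def _children(nodes: np.ndarray, j: int, x: np.ndarray) -> tuple[int, int]:
    """(hot, cold) child indices: hot is the branch sample x follows."""
    node = nodes[j]
    xv = x[node["feature_idx"]]
    if np.isnan(xv):
        go_left = bool(node["missing_go_to_left"])
    else:
        go_left = xv <= node["num_threshold"]
    return (int(node["left"]), int(node["right"])) if go_left else (
        int(node["right"]), int(node["left"]))


def _tree_shap_single(nodes: np.ndarray, x: np.ndarray, phi: np.ndarray) -> None:
    def recurse(j: int, path: _Path, pz: float, po: float, pi: int) -> None:
        path = path.copy()
        path.extend(pz, po, pi)
        node = nodes[j]
        if node["is_leaf"]:
            value = float(node["value"])
            for i in range(1, len(path.d)):
                w = path.unwound_sum(i)
                phi[path.d[i]] += w * (path.o[i] - path.z[i]) * value
            return
        hot, cold = _children(nodes, j, x)
        iz, io = 1.0, 1.0
        feat = int(node["feature_idx"])
        k = next((i for i in range(1, len(path.d)) if path.d[i] == feat), None)
        if k is not None:
            iz, io = path.z[k], path.o[k]
            path.unwind(k)
        cover = float(node["count"])
        recurse(hot, path, iz * float(nodes[hot]["count"]) / cover, io, feat)
        recurse(cold, path, iz * float(nodes[cold]["count"]) / cover, 0.0, feat)

    recurse(0, _Path(), 1.0, 1.0, -1)


def _tree_expectation(nodes: np.ndarray, j: int = 0) -> float:
    """Cover-weighted expectation of a tree's output."""
    node = nodes[j]
    if node["is_leaf"]:
        return float(node["value"])
    l, r = int(node["left"]), int(node["right"])
    cl, cr = float(nodes[l]["count"]), float(nodes[r]["count"])
    return (cl * _tree_expectation(nodes, l) + cr * _tree_expectation(nodes, r)) / (cl + cr)


def _iter_trees(model):
    for stage in model._predictors:
        if len(stage) != 1:
            raise ValueError("only binary (single-output) ensembles are supported")
        yield stage[0].nodes


def expected_raw_score(model) -> float:
    """Base value: baseline prediction plus each tree's expectation."""
    base = float(np.ravel(model._baseline_prediction)[0])
    return base + sum(_tree_expectation(nodes) for nodes in _iter_trees(model))


def tree_shap_values(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample, per-feature Shapley attributions on the raw margin.

    Returns ``(phi, base)`` with ``phi`` of shape (n_samples, n_features)
    such that ``base + phi.sum(axis=1)`` equals ``model.decision_function``.
    """
    X = np.asarray(X, dtype=float)
    trees = list(_iter_trees(model))
    phi = np.zeros_like(X, dtype=float)
    for i in range(X.shape[0]):
        for nodes in trees:
            _tree_shap_single(nodes, X[i], phi[i])
    return phi, expected_raw_score(model)


def attribute_features(model, features: pd.DataFrame) -> list[AttributionRecord]:
    """Attribution records for a fitted Metascore model on aligned features.

    ``model`` may be a fitted :class:`~metanet.metascore.MetascoreClassifier`
    or a bare HistGradientBoostingClassifier; ``features`` must carry the
    training columns (order is realigned by name).
    """
    booster = getattr(model, "model_", model)
    cols = getattr(model, "feature_names_", None) or list(features.columns)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature matrix missing training columns: {missing}")
    X = features[cols].to_numpy(dtype=float)
    phi, base = tree_shap_values(booster, X)
    return [
        AttributionRecord(
            sample_id=str(idx), base_value=base,
            attributions=dict(zip(cols, phi[i])),
        )
        for i, idx in enumerate(features.index)
    ]
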