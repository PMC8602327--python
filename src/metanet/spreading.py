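"""Metastatic spreading patterns: destination-fraction tables, correlation
networks over origins (PCN) and destinations (MSN), barycentric simplex
projection, and cross-cohort concordance.

The primary cancer network (PCN) links origin organs whose fractional
destination profiles are significantly Pearson-correlated; the metastatic
site network (MSN) does the same for destination organs over the origins
they receive.  Rendering is left to external tools: these functions emit
plain tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Cohort, METASTATIC
from .stats import TestResult, pearson_correlation_test

logger = logging.getLogger(__name__)

__all__ = [
    "FractionTable",
    "NetworkEdge",
    "SimplexCoordinates",
    "destination_fractions",
    "build_network",
    "simplex_project",
    "cross_cohort_concordance",
    "TRIANGLE_VERTICES",
    "TETRAHEDRON_VERTICES",
]

#: equilateral reference triangle
TRIANGLE_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])
#: regular tetrahedron (alternate cube corners), scaled to unit edge
TETRAHEDRON_VERTICES = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / (2.0 * np.sqrt(2.0))


@dataclass
class FractionTable:
    """Row-normalized origin x destination fractions with counts kept."""

    counts: pd.DataFrame
    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        rows = self.fractions.sum(axis=1)
        if len(rows) and not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    pcc: float
    p_value: float
    kept: bool


@dataclass(frozen=True)
class SimplexCoordinates:
    weights: np.ndarray
    coords: np.ndarray


def destination_fractions(cohort: Cohort) -> FractionTable:
    """Counts and row fractions of metastases per origin x destination."""
    mets = cohort.samples[cohort.samples.sample_type == METASTATIC]
    if len(mets) == 0:
        logger.warning("no metastatic samples; empty fraction table")
        empty = pd.DataFrame()
        return FractionTable(counts=empty, fractions=empty)
    counts = (
        mets.groupby(["cancer_type", "metastatic_site"]).size().unstack(fill_value=0)
    )
    counts = counts.loc[counts.sum(axis=1) > 0]
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return FractionTable(counts=counts, fractions=fractions)


def build_network(
    fraction_table: FractionTable,
    mode: str = "pcn",
    p_threshold: Optional[float] = None,
) -> list[NetworkEdge]:
    """All pairwise Pearson correlations between organ profiles.

    ``pcn`` correlates origin rows over destinations (default keep p < 0.05);
    ``msn`` correlates destination columns over origins (default p < 0.1).
    Organs with constant profiles contribute no edges.
    """
    if mode == "pcn":
        profiles = fraction_table.fractions
        thr = 0.05 if p_threshold is None else p_threshold
    elif mode == "msn":
        profiles = fraction_table.fractions.T
        thr = 0.1 if p_threshold is None else p_threshold
    else:
        raise ValueError("mode must be pcn or msn")
    if profiles.shape[0] < 3 or profiles.shape[1] < 3:
        raise ValueError("need at least 3 organ profiles of length >= 3")
    edges: list[NetworkEdge] = []
    nodes = list(profiles.index)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            x = profiles.loc[a].to_numpy(dtype=float)
            y = profiles.loc[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                logger.warning("constant profile for %s or %s; edge dropped", a, b)
                continue
            res, r = pearson_correlation_test(x, y)
            edges.append(NetworkEdge(a, b, pcc=r, p_value=res.p_value,
                                     kept=res.p_value < thr))
    return edges


def connected_components(edges: Sequence[NetworkEdge]) -> list[set]:
    """Components of the kept-positive-edge subgraph (convenience export)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        if e.kept and e.pcc > 0:
            ra, rb = find(e.node_a), find(e.node_b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, set] = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return list(groups.values())


def simplex_project(weights: Sequence[float]) -> SimplexCoordinates:
    """Barycentric projection of 3 or 4 nonnegative weights.

    Weights are normalized to sum 1 (so the projection is scale-invariant)
    and combined with the fixed reference triangle/tetrahedron vertices.
    """
    w = np.asarray(weights, dtype=float)
    if w.size not in (3, 4):
        raise ValueError("need 3 or 4 weights")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    w = w / total
    verts = TRIANGLE_VERTICES if w.size == 3 else TETRAHEDRON_VERTICES
    return SimplexCoordinates(weights=w, coords=w @ verts)


def cross_cohort_concordance(
    fractions_a: pd.DataFrame, fractions_b: pd.DataFrame
) -> tuple[TestResult, float, pd.DataFrame]:
    """Concordance of destination fractions between two cohorts.

    Flattens the shared origin x destination cells of both tables and
    Pearson-correlates them; also returns per-origin correlations.
    """
    rows = fractions_a.index.intersection(fractions_b.index)
    cols = fractions_a.columns.intersection(fractions_b.columns)
    dropped = (set(fractions_a.index) ^ set(fractions_b.index)) | (
        set(fractions_a.columns) ^ set(fractions_b.columns)
    )
    if dropped:
        logger.info("concordance: non-shared labels ignored: %s", sorted(dropped))
    a = fractions_a.loc[rows, cols]
    b = fractions_b.loc[rows, cols]
    if a.size < 3:
        raise ValueError("fewer than 3 shared origin x destination pairs")
    res, r = pearson_correlation_test(a.to_numpy().ravel(), b.to_numpy().ravel())
    per_origin = []
    for origin in rows:
        x, y = a.loc[origin].to_numpy(), b.loc[origin].to_numpy()
        if x.size >= 3 and np.std(x) > 0 and np.std(y) > 0:
            o_res, o_r = pearson_correlation_test(x, y)
            per_origin.append((origin, o_r, o_res.p_value))
    table = pd.DataFrame(per_origin, columns=["origin", "pcc", "p_value"])
    return res, r, table
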