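"""Mutual-information food networks and eating-hub detection.

Eleven categorical variables are analysed jointly: age binned into five
classes, sex, and the nine MeDi items.  Pairwise dependence is measured by
the plug-in mutual information of the joint contingency table,

    I(X; Y) = sum_ij  p_ij ln( p_ij / (p_i. p_.j) )      [nats]

with empty cells contributing zero.  MI makes no linearity assumption, which
matters for ordinal intake scores.  Edges of the food network are the pairs
whose MI is significant under a permutation null (default), or alternatively
the pairs whose MI exceeds the mean off-diagonal MI.  Hubs are the nodes
whose degree strictly exceeds the mean degree plus one (sample) standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import stage_rng
from .scoring import ITEMS

#: Canonical node order of the network.
VARIABLES = ("age", "sex") + ITEMS

AGE_BIN_EDGES = (20.0, 30.0, 40.0, 50.0)  # class 0: <20 ... class 4: >49


def bin_age(age):
    """Map age in years to the five analysis classes.

    <20 -> 0, 20-29 -> 1, 30-39 -> 2, 40-49 -> 3, >49 -> 4.  Vectorised.
    """
    arr = np.asarray(age, dtype=float)
    if np.any(arr < 0):
        raise ValueError("age must be non-negative")
    classes = np.digitize(arr, AGE_BIN_EDGES)
    return classes if arr.ndim else int(classes)


def encode_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Encode a participant table into the 11 categorical network variables.

    Age becomes its 5-level class, sex is 0 (F) / 1 (M), items stay 0-2.
    Column order follows :data:`VARIABLES`.
    """
    missing = sorted({"age", "sex", *ITEMS} - set(table.columns))
    if missing:
        raise ValueError(f"table missing columns: {missing}")
    enc = pd.DataFrame(index=table.index)
    enc["age"] = bin_age(table["age"].to_numpy())
    sex = table["sex"]
    if not sex.isin(["F", "M"]).all():
        raise ValueError("sex column must contain only 'F'/'M'")
    enc["sex"] = (sex == "M").astype(int)
    for item in ITEMS:
        enc[item] = table[item].astype(int)
    return enc[list(VARIABLES)]


def _as_codes(x) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(x))
    return codes.astype(np.int64), len(uniques)


def entropy(x, base: str = "nats") -> float:
    """Plug-in Shannon entropy of a categorical vector."""
    codes, k = _as_codes(x)
    p = np.bincount(codes, minlength=k) / codes.size
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(2) if base == "bits" else h


def mutual_information(x, y, base: str = "nats") -> float:
    """Plug-in mutual information of two categorical vectors.

    Zero-count cells contribute zero; the estimate is non-negative and
    bounded by min(H(x), H(y)) up to floating-point rounding.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-d vectors, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    cx, kx = _as_codes(x)
    cy, ky = _as_codes(y)
    counts = np.bincount(cx * ky + cy, minlength=kx * ky).reshape(kx, ky)
    mi = _mi_from_counts(counts)
    return mi / np.log(2) if base == "bits" else mi


def _mi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    pij = counts / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pij * np.log(pij / (pi * pj))
    return max(float(np.nansum(terms)), 0.0)


def _mi_from_counts_batch(counts: np.ndarray) -> np.ndarray:
    """MI for a (R, kx, ky) stack of contingency tables."""
    n = counts.sum(axis=(1, 2), keepdims=True)
    pij = counts / n
    pi = pij.sum(axis=2, keepdims=True)
    pj = pij.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pij * np.log(pij / (pi * pj))
    return np.maximum(np.nansum(terms, axis=(1, 2)), 0.0)


@dataclass
class MutualInfoMatrix:
    """Symmetric MI matrix over the 11 network variables.

    Diagonal entries hold the plug-in entropy of each variable.
    """

    variable_names: tuple[str, ...]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.variable_names, columns=self.variable_names)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.variable_names), k=1)
        return self.values[iu]


def build_mi_matrix(encoded: pd.DataFrame, base: str = "nats") -> MutualInfoMatrix:
    """All 55 pairwise MI values plus diagonal entropies, canonical order."""
    if len(encoded) < 2:
        raise ValueError("need at least 2 subjects")
    names = tuple(encoded.columns)
    p = len(names)
    values = np.zeros((p, p))
    cols = [encoded[c].to_numpy() for c in names]
    for i in range(p):
        values[i, i] = entropy(cols[i], base=base)
        for j in range(i + 1, p):
            values[i, j] = values[j, i] = mutual_information(cols[i], cols[j], base=base)
    return MutualInfoMatrix(variable_names=names, values=values)


def edge_test(x, y, n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
              rng: np.random.Generator | None = None) -> tuple[float, bool]:
    """Permutation test of MI(x, y) against independence.

    y is permuted ``n_perm`` times with x fixed; the p-value is
    (1 + #{MI_perm >= MI_obs}) / (1 + n_perm) and an edge is declared when
    p <= alpha.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    cx, kx = _as_codes(x)
    cy, ky = _as_codes(y)
    observed = _mi_from_counts(
        np.bincount(cx * ky + cy, minlength=kx * ky).reshape(kx, ky)
    )
    if rng is None:
        rng = stage_rng(seed, "edge_test")
    perms = rng.permuted(np.tile(cy, (n_perm, 1)), axis=1)
    codes = cx[None, :] * ky + perms
    m = kx * ky
    counts = np.stack([np.bincount(row, minlength=m) for row in codes]).reshape(n_perm, kx, ky)
    null_mi = _mi_from_counts_batch(counts)
    p_value = (1.0 + np.count_nonzero(null_mi >= observed - 1e-15)) / (1.0 + n_perm)
    return float(p_value), bool(p_value <= alpha)


@dataclass
class FoodNetwork:
    """Thresholded graph over the 11 variables with MI edge weights."""

    graph: nx.Graph
    mi: MutualInfoMatrix
    edge_rule: str
    alpha: float | None = None

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.mi.variable_names

    @property
    def degrees(self) -> dict[str, int]:
        return {v: int(self.graph.degree(v)) for v in self.nodes}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "mi": d["mi"], "p_value": d.get("p_value", np.nan)}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "mi", "p_value"])


def build_network(encoded: pd.DataFrame, edge_rule: str = "perm", alpha: float = 0.05,
                  n_perm: int = 1000, seed: int = 0, base: str = "nats") -> FoodNetwork:
    """Build the food network from an encoded cohort.

    edge_rule "perm": per-pair permutation significance at ``alpha``.
    edge_rule "mean": edge iff MI exceeds the mean off-diagonal MI.
    """
    if edge_rule not in ("perm", "mean"):
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    mi = build_mi_matrix(encoded, base=base)
    names = mi.variable_names
    graph = nx.Graph()
    graph.add_nodes_from(names)
    cols = [encoded[c].to_numpy() for c in names]
    if edge_rule == "mean":
        cut = mi.upper_triangle().mean()
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if mi.values[i, j] > cut:
                    graph.add_edge(names[i], names[j], mi=mi.values[i, j], p_value=np.nan)
        return FoodNetwork(graph=graph, mi=mi, edge_rule=edge_rule, alpha=None)

    rng = stage_rng(seed, "edge_test")
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p, is_edge = edge_test(cols[i], cols[j], n_perm=n_perm, alpha=alpha, rng=rng)
            if is_edge:
                graph.add_edge(names[i], names[j], mi=mi.values[i, j], p_value=p)
    return FoodNetwork(graph=graph, mi=mi, edge_rule=edge_rule, alpha=alpha)


@dataclass
class HubSet:
    """Hubs: nodes with degree strictly above mean + sample SD of degrees."""

    hubs: tuple[str, ...]
    threshold: float
    degrees: dict[str, int] = field(default_factory=dict)


def identify_hubs(network: FoodNetwork) -> HubSet:
    """Degree-threshold hub rule: degree > mean(degrees) + SD(degrees).

    The SD uses the n-1 (sample) denominator; the inequality is strict, so a
    regular graph has no hubs.
    """
    degrees = network.degrees
    if len(degrees) < 2:
        raise ValueError("need at least 2 nodes")
    values = np.array(list(degrees.values()), dtype=float)
    threshold = float(values.mean() + values.std(ddof=1))
    hubs = tuple(v for v in network.nodes if degrees[v] > threshold)
    return HubSet(hubs=hubs, threshold=threshold, degrees=degrees)
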