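"""Neighborhood interaction testing.

Two voxels interact when their centers are within a radius (default 5 px,
Euclidean in 3D). For K neighborhood labels, the observed K x K matrix of
unordered interacting pairs is compared to a null built by shuffling the
labels over voxel positions: the geometry (the set of interacting position
pairs) is computed once, each permutation only recounts labels. One-sided
p-values follow the add-one rule

    p = (#{permutation counts beyond the observed count} + 1) / (n_perm + 1)

with strict inequalities (ties count toward neither tail), and enrichment is
log2(observed / mean permuted count), undefined (NaN) when either side is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "InteractionConfig",
    "InteractionResult",
    "pairwise_distance",
    "neighbor_pairs",
    "count_interactions",
    "permutation_test",
    "permutation_test_naive",
    "significant_edges",
    "to_graph",
]


@dataclass
class InteractionConfig:
    radius: float = 5.0
    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class InteractionResult:
    """Observed vs label-permuted interaction counts for one analysis unit."""

    labels: np.ndarray            # sorted distinct neighborhood ids (K,)
    real_counts: np.ndarray       # (K, K) symmetric, unordered pair counts
    perm_mean: np.ndarray         # (K, K) mean count over permutations
    log2_enrichment: np.ndarray   # (K, K); NaN where undefined
    p_greater: np.ndarray         # (K, K) one-sided, enrichment tail
    p_less: np.ndarray            # (K, K) one-sided, depletion tail
    n_perm: int
    radius: float
    unit: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Long-form table, one row per unordered label pair."""
        rows = []
        K = len(self.labels)
        for i in range(K):
            for j in range(i, K):
                rows.append({
                    "unit": self.unit,
                    "a": self.labels[i], "b": self.labels[j],
                    "real": self.real_counts[i, j],
                    "perm_mean": self.perm_mean[i, j],
                    "log2_enrichment": self.log2_enrichment[i, j],
                    "p_greater": self.p_greater[i, j],
                    "p_less": self.p_less[i, j],
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        return (f"InteractionResult(unit={self.unit!r}, K={len(self.labels)}, "
                f"radius={self.radius}, n_perm={self.n_perm})\n"
                + df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


def pairwise_distance(a, b) -> float:
    """Euclidean distance between two (x, y, z) voxel centers."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.sum((a - b) ** 2)))


def neighbor_pairs(coords: np.ndarray, radius: float) -> np.ndarray:
    """All unordered index pairs (i < j) with center distance <= radius.

    Spatially binned (k-d tree); the pair set depends only on geometry, so
    permutation tests reuse it across label shuffles.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3) (x, y, z) centers")
    pairs = cKDTree(coords).query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    return pairs


def _count_pairs(idx_a: np.ndarray, idx_b: np.ndarray, K: int) -> np.ndarray:
    lo = np.minimum(idx_a, idx_b)
    hi = np.maximum(idx_a, idx_b)
    flat = np.bincount(lo * K + hi, minlength=K * K)
    upper = flat.reshape(K, K)
    return upper + np.triu(upper, 1).T  # symmetric; diagonal once


def count_interactions(coords, labels, radius: float = 5.0,
                       label_order: np.ndarray | None = None) -> np.ndarray:
    """Observed K x K matrix of interacting unordered voxel pairs.

    Entry (A, B) counts pairs {i, j} with distance <= radius and label set
    {A, B}; the diagonal counts same-label pairs (each once). Rows/columns
    follow ``label_order`` (default: sorted distinct labels).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if len(coords) != len(labels):
        raise ValueError(
            f"{len(coords)} coordinates but {len(labels)} labels"
        )
    if label_order is None:
        uniq, idx = np.unique(labels, return_inverse=True)
    else:
        uniq = np.asarray(label_order)
        lookup = {l: i for i, l in enumerate(uniq)}
        idx = np.array([lookup[l] for l in labels], dtype=int)
    pairs = neighbor_pairs(coords, radius)
    return _count_pairs(idx[pairs[:, 0]], idx[pairs[:, 1]], len(uniq))


def _finalize(labels, real, perm_counts, n_perm, radius, unit):
    perm_mean = perm_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fe = np.log2(real / perm_mean)
    log2_fe[(real == 0) | (perm_mean == 0)] = np.nan
    p_greater = ((perm_counts > real).sum(axis=0) + 1) / (n_perm + 1)
    p_less = ((perm_counts < real).sum(axis=0) + 1) / (n_perm + 1)
    return InteractionResult(
        labels=labels, real_counts=real, perm_mean=perm_mean,
        log2_enrichment=log2_fe, p_greater=p_greater, p_less=p_less,
        n_perm=n_perm, radius=radius, unit=unit,
    )


def permutation_test(coords, labels, config: InteractionConfig | None = None,
                     unit: str = "") -> InteractionResult:
    """Label-shuffle permutation test of neighborhood interactions.

    The interacting-pair set is built once from the coordinates; each of the
    ``n_perm`` permutations draws ``rng.permutation(n)`` from
    ``numpy.random.default_rng(seed)`` and recounts the K x K matrix.
    Deterministic given the seed.
    """
    config = config or InteractionConfig()
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if len(coords) != len(labels):
        raise ValueError(f"{len(coords)} coordinates but {len(labels)} labels")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("permutation test needs at least 2 distinct labels")
    idx = np.searchsorted(uniq, labels)
    K = len(uniq)
    pairs = neighbor_pairs(coords, config.radius)
    ia, ib = pairs[:, 0], pairs[:, 1]
    real = _count_pairs(idx[ia], idx[ib], K)

    rng = np.random.default_rng(config.seed)
    perm_counts = np.empty((config.n_perm, K, K), dtype=np.int64)
    for t in range(config.n_perm):
        shuffled = idx[rng.permutation(len(idx))]
        perm_counts[t] = _count_pairs(shuffled[ia], shuffled[ib], K)
    return _finalize(uniq, real, perm_counts, config.n_perm, config.radius,
                     unit)


def permutation_test_naive(coords, labels,
                           config: InteractionConfig | None = None,
                           unit: str = "") -> InteractionResult:
    """Reference implementation: dense all-pairs distances, per-permutation
    recount by explicit loops. Consumes the same permutation stream as
    :func:`permutation_test`; used to validate the binned implementation."""
    config = config or InteractionConfig()
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("permutation test needs at least 2 distinct labels")
    idx = np.searchsorted(uniq, labels)
    K = len(uniq)
    n = len(coords)

    def count(lab):
        M = np.zeros((K, K), dtype=np.int64)
        for i in range(n):
            for j in range(i + 1, n):
                if pairwise_distance(coords[i], coords[j]) <= config.radius:
                    a, b = sorted((lab[i], lab[j]))
                    M[a, b] += 1
        return M + np.triu(M, 1).T

    real = count(idx)
    rng = np.random.default_rng(config.seed)
    perm_counts = np.empty((config.n_perm, K, K), dtype=np.int64)
    for t in range(config.n_perm):
        perm_counts[t] = count(idx[rng.permutation(n)])
    return _finalize(uniq, real, perm_counts, config.n_perm, config.radius,
                     unit)


def significant_edges(result: InteractionResult,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Edges of the significance graph: one row per label pair with a
    one-sided p below alpha; sign +1 for enrichment, -1 for depletion;
    weight is the log2 enrichment."""
    rows = []
    K = len(result.labels)
    for i in range(K):
        for j in range(i, K):
            if result.p_greater[i, j] < alpha:
                sign, p = 1, result.p_greater[i, j]
            elif result.p_less[i, j] < alpha:
                sign, p = -1, result.p_less[i, j]
            else:
                continue
            rows.append({
                "a": result.labels[i], "b": result.labels[j], "sign": sign,
                "weight": result.log2_enrichment[i, j], "p": p,
            })
    return pd.DataFrame(rows, columns=["a", "b", "sign", "weight", "p"])


def to_graph(result: InteractionResult, alpha: float = 0.05):
    """Significance graph as a networkx.Graph (node size = voxel count is
    left to the caller; edge attrs: sign, weight, p)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(int(l) for l in result.labels)
    for _, row in significant_edges(result, alpha).iterrows():
        g.add_edge(int(row["a"]), int(row["b"]), sign=int(row["sign"]),
                   weight=float(row["weight"]), p=float(row["p"]))
    return g
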