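"""K-order propagation number node importance.

For an unweighted undirected graph with diameter ``d``, each node ``i`` gets
a K-order neighbourhood number ``N_i^K = 1 + #{j != i : l_ij <= K}`` for every
step size ``K in {0..d}``.  Per-K Shannon entropies of the count distribution
measure how heterogeneous the graph looks at that scale; min-max-normalized
counts ``S^K`` weighted by ``c_K = 1 - minmax(H_K)`` combine into the node
importance score ``Q_i = sum_K c_K * S_i^K``, so scales at which nodes differ
most contribute most.

Degenerate conventions (chosen so vertex-transitive graphs give uniform Q
and nothing divides by zero):

* all counts equal at some K  ->  ``S^K = 0`` for every node;
* all entropies equal         ->  ``c_K = 1/(d+1)`` for every K.

Entropies use the natural log; since ``c_K`` min-max-normalizes ``H``, the
log base cancels and Q is base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netgraph import BinaryNetwork, DistanceMatrix, shortest_paths

__all__ = [
    "KOrderProfile",
    "ImportanceVector",
    "k_neighbourhood_counts",
    "k_order_entropy",
    "normalize_counts",
    "entropy_weights",
    "node_importance",
    "feature_vector",
]


@dataclass
class KOrderProfile:
    """All per-K intermediates behind one importance vector.

    Attributes
    ----------
    d : int
        Graph diameter (max finite shortest-path length).
    counts : ndarray, shape (d + 1, n)
        ``counts[K, i]`` = K-order neighbourhood number of node i.
    entropies : ndarray, shape (d + 1,)
        Shannon entropy of each K's count distribution (natural log).
    normalized : ndarray, shape (d + 1, n)
        Min-max-normalized counts S in [0, 1].
    weights : ndarray, shape (d + 1,)
        Entropy-derived weights c in [0, 1].
    """

    d: int
    counts: np.ndarray
    entropies: np.ndarray
    normalized: np.ndarray
    weights: np.ndarray


@dataclass
class ImportanceVector:
    """Per-node importance scores Q plus the profile they came from."""

    Q: np.ndarray
    profile: KOrderProfile
    channel_labels: list[str] | None = None


def k_neighbourhood_counts(L: DistanceMatrix, K: int) -> np.ndarray:
    """Count of nodes each node reaches within K hops, self included.

    ``N_i^K = 1 + #{j != i : l_ij <= K, l_ij finite}``; K = 0 gives the
    all-ones vector and N is non-decreasing in K.
    """
    if K < 0:
        raise ValueError("K must be nonnegative")
    within = (L.l <= K) & np.isfinite(L.l)
    # the diagonal (l_ii = 0) contributes each node's own +1
    return within.sum(axis=1).astype(np.int64)


def k_order_entropy(NK: np.ndarray) -> float:
    """Shannon entropy (natural log) of the count distribution p_i = N_i / sum N."""
    NK = np.asarray(NK, dtype=float)
    if NK.size == 0:
        raise ValueError("empty count vector")
    if np.any(NK < 1):
        raise ValueError("counts must be >= 1")
    p = NK / NK.sum()
    return float(-(p * np.log(p)).sum())


def normalize_counts(NK: np.ndarray) -> np.ndarray:
    """Min-max normalize counts to [0, 1]; all-equal counts map to all zeros."""
    NK = np.asarray(NK, dtype=float)
    if NK.size == 0:
        raise ValueError("empty count vector")
    lo, hi = NK.min(), NK.max()
    if hi == lo:
        return np.zeros_like(NK)
    return (NK - lo) / (hi - lo)


def entropy_weights(H: np.ndarray) -> np.ndarray:
    """Weights c_K = 1 - minmax(H_K); uniform 1/(d+1) when all H equal.

    The scale with the lowest entropy — the one where node importance
    differs most — always receives weight 1 in the non-degenerate case.
    """
    H = np.asarray(H, dtype=float)
    if H.size == 0:
        raise ValueError("empty entropy vector")
    lo, hi = H.min(), H.max()
    if hi == lo:
        return np.full_like(H, 1.0 / H.size)
    return 1.0 - (H - lo) / (hi - lo)


def node_importance(G: BinaryNetwork) -> ImportanceVector:
    """Full K-order propagation number score for every node of ``G``."""
    L = shortest_paths(G)
    d = L.max_finite()
    n = G.n_nodes
    counts = np.empty((d + 1, n), dtype=np.int64)
    for K in range(d + 1):
        counts[K] = k_neighbourhood_counts(L, K)
    entropies = np.array([k_order_entropy(counts[K]) for K in range(d + 1)])
    normalized = np.vstack([normalize_counts(counts[K]) for K in range(d + 1)])
    weights = entropy_weights(entropies)
    Q = weights @ normalized
    profile = KOrderProfile(d, counts, entropies, normalized, weights)
    labels = list(G.channel_labels) if G.channel_labels else None
    return ImportanceVector(Q, profile, channel_labels=labels)


def feature_vector(iv: ImportanceVector, ordering: str = "channel") -> np.ndarray:
    """Arrange Q into the classifier feature vector.

    ``channel`` keeps the fixed channel order (preserves spatial identity,
    required by montage-based node grouping); ``sorted_desc`` sorts scores
    descending, discarding channel identity.
    """
    if ordering == "channel":
        return iv.Q.copy()
    if ordering == "sorted_desc":
        return np.sort(iv.Q)[::-1].copy()
    raise ValueError(f"unknown ordering {ordering!r}")
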