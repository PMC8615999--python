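"""Threshold binarization, z-score thresholds and unweighted graph primitives."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "BinaryNetwork",
    "DistanceMatrix",
    "binarize",
    "threshold_from_zscore",
    "shortest_paths",
    "diameter",
]

UNREACHABLE = np.inf


@dataclass
class BinaryNetwork:
    """Undirected 0-1 graph over channels (symmetric, zero diagonal)."""

    adjacency: np.ndarray
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("diagonal must be zero")
        self.adjacency = adj.astype(np.uint8)
        if self.channel_labels is not None and len(self.channel_labels) != adj.shape[0]:
            raise ValueError("channel_labels length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return set(zip(i.tolist(), j.tolist()))

    def to_edge_list_tsv(self, path: str | Path) -> None:
        labels = self.channel_labels or [str(i) for i in range(self.n_nodes)]
        with open(path, "w") as fh:
            for i, j in sorted(self.edge_set()):
                fh.write(f"{labels[i]}\t{labels[j]}\n")


@dataclass
class DistanceMatrix:
    """All-pairs unweighted shortest-path lengths; inf marks unreachable."""

    l: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        if self.l.ndim != 2 or self.l.shape[0] != self.l.shape[1]:
            raise ValueError("distance matrix must be square")

    @property
    def n_nodes(self) -> int:
        return self.l.shape[0]

    def max_finite(self) -> int:
        finite = self.l[np.isfinite(self.l)]
        return int(finite.max()) if finite.size else 0


def binarize(A: ConnectivityMatrix, tri: float, rule: str = "ge") -> BinaryNetwork:
    """Threshold a weighted matrix into a 0-1 network.

    ``rule="ge"`` places an edge where the weight is >= ``tri`` (higher
    threshold => sparser network); ``rule="le"`` inverts the comparison for
    the low-entropy-means-strong-coupling reading.
    """
    if rule == "ge":
        adj = (A.values >= tri)
    elif rule == "le":
        adj = (A.values <= tri)
    else:
        raise ValueError("rule must be 'ge' or 'le'")
    adj = adj.astype(np.uint8)
    np.fill_diagonal(adj, 0)
    labels = list(A.channel_labels) if A.channel_labels else None
    return BinaryNetwork(adj, channel_labels=labels)


def threshold_from_zscore(A: ConnectivityMatrix, z: float) -> float:
    """Threshold at ``mean + z x sd`` of the off-diagonal weights (sd with
    n-1 denominator); affine in z."""
    off = A.offdiag()
    if off.size < 2 or np.ptp(off) == 0:
        raise ValueError("degenerate matrix: need >= 2 distinct off-diagonal values")
    return float(off.mean() + z * off.std(ddof=1))


def shortest_paths(G: BinaryNetwork) -> DistanceMatrix:
    """All-pairs BFS shortest-path lengths; unreachable pairs are inf."""
    if G.n_nodes == 0:
        return DistanceMatrix(np.zeros((0, 0)))
    d = _csgraph_shortest_path(G.adjacency, method="D", unweighted=True,
                               directed=False)
    return DistanceMatrix(d)


def diameter(G: BinaryNetwork) -> int:
    """Maximum finite shortest-path length; 0 for an edgeless graph.

    Disconnected graphs use the max over finite distances only, so the
    downstream K range {0..d} stays well defined.
    """
    return shortest_paths(G).max_finite()
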