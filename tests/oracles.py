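"""Independent reference implementations used only by the tests.

These deliberately share no code with the package: pure-python loops,
networkx BFS instead of scipy csgraph, math.log instead of numpy.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def csen_match_counts(x, y, m, r):
    """Brute-force cross template-match counts (A, B) by exhaustive loops."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    n_templates = n - m
    a = b = 0
    for i in range(n_templates):
        for j in range(n_templates):
            if max(abs(x[i + k] - y[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - y[j + k]) for k in range(m + 1)) <= r:
                a += 1
    return a, b


def csen_bruteforce(x, y, m, r):
    """Brute-force cross-sample entropy; raises on zero matches."""
    a, b = csen_match_counts(x, y, m, r)
    if a == 0 or b == 0:
        raise ZeroDivisionError("no matches")
    return -math.log(a / b)


def shannon_entropy(counts, base=math.e):
    total = sum(counts)
    return -sum((c / total) * math.log(c / total, base) for c in counts)


def kprop_reference(adj, log_base=math.e):
    """Straight-line K-order propagation number importance on a 0-1 matrix."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    graph = nx.from_numpy_array(adj)
    lengths = dict(nx.all_pairs_shortest_path_length(graph))
    finite = [l for row in lengths.values() for l in row.values()]
    d = max(finite) if finite else 0

    counts = []
    for K in range(d + 1):
        row = []
        for i in range(n):
            reachable = sum(
                1 for j in range(n)
                if j != i and j in lengths[i] and lengths[i][j] <= K
            )
            row.append(reachable + 1)
        counts.append(row)

    entropies = [shannon_entropy(counts[K], base=log_base) for K in range(d + 1)]

    normalized = []
    for K in range(d + 1):
        lo, hi = min(counts[K]), max(counts[K])
        if hi == lo:
            normalized.append([0.0] * n)
        else:
            normalized.append([(v - lo) / (hi - lo) for v in counts[K]])

    lo_h, hi_h = min(entropies), max(entropies)
    if hi_h == lo_h:
        weights = [1.0 / (d + 1)] * (d + 1)
    else:
        weights = [1.0 - (h - lo_h) / (hi_h - lo_h) for h in entropies]

    return [
        sum(weights[K] * normalized[K][i] for K in range(d + 1))
        for i in range(n)
    ]


def floyd_warshall(adj):
    """All-pairs shortest paths by the classic triple loop; inf = unreachable."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    dist = [[0.0 if i == j else (1.0 if adj[i][j] else math.inf)
             for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return np.array(dist)


def random_adjacency(rng, n, p):
    """Symmetric 0-1 adjacency with zero diagonal, edge probability p."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    adj = (adj | adj.T).astype(int)
    return adj
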