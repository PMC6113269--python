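"""Independent brute-force oracles used to validate the fast
implementations. Deliberately naive: explicit path enumeration,
exhaustive spanning-tree / partition search, direct formula evaluation."""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adjacency: np.ndarray, weighted: bool) -> np.ndarray:
    """All-pairs shortest paths by triple loop; lengths are 1/weight for
    weighted graphs, hops otherwise."""
    n = adjacency.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and adjacency[i, j] != 0:
                d[i, j] = 1.0 / adjacency[i, j] if weighted else 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length(adjacency: np.ndarray, weighted: bool = False) -> float:
    d = floyd_warshall(adjacency, weighted)
    n = d.shape[0]
    vals = d[~np.eye(n, dtype=bool)]
    return float(vals.mean())


def efficiency(adjacency: np.ndarray, weighted: bool = False) -> float:
    d = floyd_warshall(adjacency, weighted)
    n = d.shape[0]
    if n < 2:
        return 0.0
    vals = d[~np.eye(n, dtype=bool)]
    with np.errstate(divide="ignore"):
        inv = np.where(vals > 0, 1.0 / vals, 0.0)
    return float(inv.mean())


def binary_clustering(adjacency: np.ndarray, i: int) -> float:
    """Watts-Strogatz: closed neighbor pairs / possible neighbor pairs."""
    a = adjacency != 0
    nbrs = np.nonzero(a[i])[0]
    k = len(nbrs)
    if k < 2:
        return 0.0
    closed = sum(
        1 for u, v in itertools.combinations(nbrs, 2) if a[u, v]
    )
    return 2.0 * closed / (k * (k - 1))


def onnela_clustering(adjacency: np.ndarray, i: int) -> float:
    w = adjacency / adjacency.max()
    a = adjacency != 0
    nbrs = np.nonzero(a[i])[0]
    k = len(nbrs)
    if k < 2:
        return 0.0
    s = sum(
        (w[i, u] * w[i, v] * w[u, v]) ** (1.0 / 3.0)
        for u, v in itertools.combinations(nbrs, 2)
    )
    return 2.0 * s / (k * (k - 1))


def local_efficiency_node(adjacency: np.ndarray, i: int, weighted: bool = False) -> float:
    nbrs = np.nonzero(adjacency[i])[0]
    if len(nbrs) < 2:
        return 0.0
    sub = adjacency[np.ix_(nbrs, nbrs)]
    return efficiency(sub, weighted)


def max_spanning_tree_exhaustive(weights: np.ndarray) -> tuple[set, float]:
    """Best spanning tree by enumerating all (N-1)-edge subsets."""
    n = weights.shape[0]
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0
    ]
    best, best_w = None, -np.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        acyclic = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                acyclic = False
                break
            parent[rv] = ru
        if not acyclic:
            continue
        total = sum(weights[u, v] for u, v in subset)
        if total > best_w:
            best_w, best = total, set(subset)
    return best, best_w


def modularity_q(adjacency: np.ndarray, labels: np.ndarray) -> float:
    a = adjacency
    two_m = a.sum()
    k = a.sum(axis=1)
    q = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def best_partition_exhaustive(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-modularity partition by enumerating all set partitions."""
    n = adjacency.shape[0]

    def partitions(idx):
        if not idx:
            yield []
            return
        first, rest = idx[0], idx[1:]
        for part in partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [part[k] + [first]] + part[k + 1 :]
            yield part + [[first]]

    best_q, best_labels = -np.inf, None
    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for mod_id, members in enumerate(part):
            labels[members] = mod_id
        q = modularity_q(adjacency, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_labels, best_q


def nmi_entropy(x: np.ndarray, y: np.ndarray) -> float:
    """NMI by direct entropy bookkeeping, 2I/(Hx+Hy)."""
    n = len(x)

    def h(labels):
        _, counts = np.unique(labels, return_counts=True)
        p = counts / n
        return -np.sum(p * np.log(p))

    pairs = list(zip(x, y))
    mi = 0.0
    for a, b in set(pairs):
        pxy = pairs.count((a, b)) / n
        px = np.mean(x == a)
        py = np.mean(y == b)
        mi += pxy * np.log(pxy / (px * py))
    denom = h(x) + h(y)
    return 1.0 if denom == 0 else 2.0 * mi / denom
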