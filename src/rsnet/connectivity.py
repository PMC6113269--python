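"""Functional network construction from parcel time series.

Edges are interregional Pearson correlations, Fisher r-to-z transformed;
edge weight is |z| (the sign is kept for audit but never used downstream).
Thresholding first extracts a maximum-weight spanning tree so the network
is connected at every sparsity — no isolated islands — and then grows the
tree by adding the strongest remaining edges until the target cost
(fraction of all possible node pairs) is met. The same backbone and edge
ranking serve every cost, so networks over a grid are nested.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    ConnectivityMatrix,
    CostGrid,
    Mode,
    ParcelTimeSeries,
    ThresholdedNetwork,
    round_half_up,
)

Edge = tuple[int, int]


def correlation_matrix(series: ParcelTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of parcel time series."""
    values = series.values
    sd = values.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        names = [series.parcel_labels[i] for i in dead]
        raise ValueError(f"zero-variance parcel(s): {names}")
    r = np.corrcoef(values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # symmetrize away rounding
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r=r, parcel_labels=series.parcel_labels)


def fisher_z(conn: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fill the Fisher z matrix (atanh r) and the |z| weight matrix.

    Off-diagonal |r| = 1 would map to an infinite weight and is rejected,
    naming the offending parcel pair.
    """
    r = conn.r
    n = conn.n_parcels
    off = ~np.eye(n, dtype=bool)
    perfect = np.abs(r) >= 1.0 - 1e-15
    bad = np.argwhere(perfect & off)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            "perfect correlation (|r| = 1) between parcels "
            f"{conn.parcel_labels[i]!r} and {conn.parcel_labels[j]!r}: "
            "Fisher z is infinite"
        )
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    weights = np.abs(z)
    return ConnectivityMatrix(
        r=r, parcel_labels=conn.parcel_labels, z=z, weights=weights
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def ranked_edges(weights: np.ndarray) -> list[Edge]:
    """All positive-weight edges sorted by descending weight; ties broken
    lexicographically by (smaller index, larger index) for determinism."""
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    w = weights[iu, ju]
    keep = w > 0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, -w))
    return list(zip(iu[order].tolist(), ju[order].tolist()))


def backbone_spanning_tree(weights: np.ndarray) -> set[Edge]:
    """Maximum-total-weight spanning tree of the |z| weight matrix
    (Kruskal on descending weights), guaranteeing a connected, acyclic
    backbone of N-1 edges.

    Raises if the positive-weight graph is disconnected.
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    uf = _UnionFind(n)
    tree: set[Edge] = set()
    for i, j in ranked_edges(weights):
        if uf.union(i, j):
            tree.add((i, j))
            if len(tree) == n - 1:
                return tree
    raise ValueError(
        "weight graph is disconnected: no spanning tree exists "
        f"({len(tree)} of {n - 1} tree edges found)"
    )


def edge_count_for_cost(cost: float, n_nodes: int) -> int:
    """Target edge count at a cost level: round-half-up of cost * number
    of possible pairs."""
    return round_half_up(cost * n_nodes * (n_nodes - 1) / 2.0)


def grow_to_cost(
    weights: np.ndarray,
    backbone: set[Edge],
    cost: float,
    mode: Mode,
    parcel_labels: list[str] | None = None,
) -> ThresholdedNetwork:
    """Grow the backbone with the strongest non-tree edges until the edge
    count matches the cost, then emit the weighted or binary adjacency."""
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    target = edge_count_for_cost(cost, n)
    if target < len(backbone):
        min_cost = len(backbone) / (n * (n - 1) / 2.0)
        raise ValueError(
            f"cost {cost} yields {target} edges, below the {len(backbone)}-edge "
            f"backbone; minimum feasible cost is {min_cost:.4f}"
        )
    edges = list(backbone)
    if target > len(backbone):
        for e in ranked_edges(weights):
            if e in backbone:
                continue
            edges.append(e)
            if len(edges) == target:
                break
        else:
            raise ValueError(
                f"cost {cost} requests {target} edges but only {len(edges)} "
                "positive-weight edges exist"
            )
    adj = np.zeros((n, n))
    idx = np.array(edges)
    vals = 1.0 if mode == "binary" else weights[idx[:, 0], idx[:, 1]]
    adj[idx[:, 0], idx[:, 1]] = vals
    adj[idx[:, 1], idx[:, 0]] = vals
    if parcel_labels is None:
        parcel_labels = [f"n{i}" for i in range(n)]
    return ThresholdedNetwork(adj, cost=float(cost), mode=mode, parcel_labels=parcel_labels)


def build_networks_over_grid(
    conn: ConnectivityMatrix,
    grid: CostGrid,
    mode: Mode,
) -> list[ThresholdedNetwork]:
    """One network per grid cost, all sharing the same backbone and edge
    ranking, hence nested: edges(c) is a subset of edges(c') for c < c'."""
    if conn.weights is None:
        conn = fisher_z(conn)
    backbone = backbone_spanning_tree(conn.weights)
    return [
        grow_to_cost(conn.weights, backbone, cost, mode, conn.parcel_labels)
        for cost in grid
    ]


def connectivity_from_series(series: ParcelTimeSeries) -> ConnectivityMatrix:
    """Convenience: correlation + Fisher z in one call."""
    return fisher_z(correlation_matrix(series))
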