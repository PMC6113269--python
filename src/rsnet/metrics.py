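"""Global and regional graph metrics on thresholded networks.

Global: mean clustering coefficient (Cp), characteristic path length (Lp),
global efficiency, local efficiency, and small-worldness sigma against
degree-preserving rewired nulls. Regional: nodal clustering, nodal local
efficiency, and degree.

Conventions
-----------
* Binary clustering is the Watts-Strogatz fraction of closed neighbor
  pairs; weighted clustering is the Onnela geometric-mean triangle formula
  with weights normalized by the network maximum.
* Weighted shortest paths use edge length 1/weight (stronger connection =
  shorter distance).
* Degree counts links in both modes; strength is out of scope.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph as csgraph

from .datatypes import Mode, ThresholdedNetwork


# ---------------------------------------------------------------- distances

def _distance_matrix(adjacency: np.ndarray, mode: Mode) -> np.ndarray:
    """All-pairs shortest-path distances; hops for binary graphs, summed
    1/weight lengths for weighted graphs. Unreachable pairs are inf."""
    n = adjacency.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    if mode == "binary":
        graph = scipy.sparse.csr_matrix(adjacency != 0)
        return csgraph.shortest_path(graph, method="D", unweighted=True)
    lengths = np.zeros_like(adjacency)
    nz = adjacency != 0
    lengths[nz] = 1.0 / adjacency[nz]
    graph = scipy.sparse.csr_matrix(lengths)
    return csgraph.shortest_path(graph, method="D", directed=False)


def _pairwise_off_diagonal(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    return d[~np.eye(n, dtype=bool)]


def characteristic_path_length(net: ThresholdedNetwork) -> float:
    """Mean shortest-path distance over all ordered node pairs (Lp).

    Raises on disconnected input; pipeline-built networks are connected by
    construction.
    """
    d = _pairwise_off_diagonal(_distance_matrix(net.adjacency, net.mode))
    if np.any(np.isinf(d)):
        raise ValueError("graph is disconnected: characteristic path length undefined")
    return float(d.mean())


def global_efficiency(net: ThresholdedNetwork) -> float:
    """Mean inverse shortest-path distance over ordered pairs; a
    disconnected pair contributes 0 (1/inf)."""
    return _efficiency_of_adjacency(net.adjacency, net.mode)


def _efficiency_of_adjacency(adjacency: np.ndarray, mode: Mode) -> float:
    n = adjacency.shape[0]
    if n < 2:
        return 0.0
    d = _pairwise_off_diagonal(_distance_matrix(adjacency, mode))
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / d, 0.0)
    return float(inv.mean())


# --------------------------------------------------------------- clustering

def _node_index(net: ThresholdedNetwork, node: str) -> int:
    try:
        return net.parcel_labels.index(node)
    except ValueError:
        raise KeyError(f"unknown node label: {node!r}") from None


def _clustering_vector(net: ThresholdedNetwork) -> np.ndarray:
    """Nodal clustering for every node at once (degree < 2 gives 0)."""
    a = (net.adjacency != 0).astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    if net.mode == "binary":
        triangles = np.diagonal(a @ a @ a)
    else:
        w_hat = net.adjacency / net.adjacency.max()
        w3 = np.cbrt(w_hat)
        triangles = np.diagonal(w3 @ w3 @ w3)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def nodal_clustering(net: ThresholdedNetwork, node: str) -> float:
    """Clustering coefficient of one node: how interconnected its
    neighborhood is (0 for degree < 2)."""
    return float(_clustering_vector(net)[_node_index(net, node)])


def mean_clustering(net: ThresholdedNetwork) -> float:
    """Cp: unweighted average of nodal clustering over all nodes, zeros
    included."""
    return float(_clustering_vector(net).mean())


# --------------------------------------------------------- local efficiency

def local_efficiency(net: ThresholdedNetwork, node: str | None = None) -> float:
    """Efficiency of the subgraph induced by a node's neighbors (node
    itself excluded); with ``node=None`` returns the network mean over all
    nodes. Degree < 2 gives 0."""
    if node is not None:
        return _nodal_local_efficiency(net, _node_index(net, node))
    vals = [_nodal_local_efficiency(net, i) for i in range(net.n_nodes)]
    return float(np.mean(vals)) if vals else 0.0


def _nodal_local_efficiency(net: ThresholdedNetwork, i: int) -> float:
    neighbors = np.nonzero(net.adjacency[i])[0]
    if neighbors.size < 2:
        return 0.0
    sub = net.adjacency[np.ix_(neighbors, neighbors)]
    return _efficiency_of_adjacency(sub, net.mode)


def degree(net: ThresholdedNetwork, node: str) -> int:
    """Number of links attached to a node (same in both modes)."""
    return int(np.count_nonzero(net.adjacency[_node_index(net, node)]))


def degree_vector(net: ThresholdedNetwork) -> np.ndarray:
    return (net.adjacency != 0).sum(axis=1)


# ------------------------------------------------------- small-world nulls

def rewire_null(
    net: ThresholdedNetwork,
    n_iterations: int | None = None,
    seed: int | np.random.Generator = 0,
) -> ThresholdedNetwork:
    """Degree-preserving randomization of a connected binary network by
    double-edge swaps; swap windows that break connectivity are rolled
    back, so the result is connected with the input's exact degree
    sequence.

    ``n_iterations`` is the number of swap attempts (default 10x the edge
    count). Graphs admitting no swap (e.g. complete graphs) are returned
    unchanged with a warning.
    """
    if net.mode != "binary":
        raise ValueError("rewiring nulls are defined for binary networks")
    n = net.n_nodes
    m = net.edge_count
    if m == n * (n - 1) // 2:
        warnings.warn("complete graph admits no degree-preserving swap")
        return net
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_iterations is None:
        n_iterations = 10 * m

    edges = sorted(net.edge_set())
    neighbors: list[set[int]] = [set(np.nonzero(net.adjacency[i])[0].tolist()) for i in range(n)]
    window = max(1, m // 10)
    applied: list[tuple[int, int, int, int, int, int]] = []  # swap log for rollback

    def connected() -> bool:
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in neighbors[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == n

    def apply_swap(e1: int, e2: int, u: int, v: int, x: int, y: int) -> None:
        neighbors[u].discard(v)
        neighbors[v].discard(u)
        neighbors[x].discard(y)
        neighbors[y].discard(x)
        neighbors[u].add(x)
        neighbors[x].add(u)
        neighbors[v].add(y)
        neighbors[y].add(v)
        edges[e1] = (min(u, x), max(u, x))
        edges[e2] = (min(v, y), max(v, y))

    def undo_swap(e1: int, e2: int, u: int, v: int, x: int, y: int) -> None:
        neighbors[u].discard(x)
        neighbors[x].discard(u)
        neighbors[v].discard(y)
        neighbors[y].discard(v)
        neighbors[u].add(v)
        neighbors[v].add(u)
        neighbors[x].add(y)
        neighbors[y].add(x)
        edges[e1] = (min(u, v), max(u, v))
        edges[e2] = (min(x, y), max(x, y))

    swaps_in_window = 0
    for _ in range(n_iterations):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if rng.random() < 0.5:
            x, y = y, x
        # propose replacing (u,v),(x,y) with (u,x),(v,y)
        if len({u, v, x, y}) < 4:
            continue
        if x in neighbors[u] or y in neighbors[v]:
            continue
        apply_swap(e1, e2, u, v, x, y)
        applied.append((e1, e2, u, v, x, y))
        swaps_in_window += 1
        if swaps_in_window >= window:
            if connected():
                applied.clear()
            else:
                for rec in reversed(applied):
                    undo_swap(*rec)
                applied.clear()
            swaps_in_window = 0
    if applied:
        if not connected():
            for rec in reversed(applied):
                undo_swap(*rec)
    adj = np.zeros((n, n))
    for i, js in enumerate(neighbors):
        for j in js:
            adj[i, j] = 1.0
    return ThresholdedNetwork(adj, cost=net.cost, mode="binary", parcel_labels=net.parcel_labels)


def small_worldness(
    net: ThresholdedNetwork,
    n_null: int = 100,
    seed: int = 0,
) -> float:
    """Small-world sigma: (Cp / <Cp_null>) / (Lp / <Lp_null>) over
    degree-preserving rewired null networks.

    Values above 1 indicate the high-clustering / short-path combination
    characteristic of small-world organization.
    """
    if net.mode != "binary":
        raise ValueError("small-worldness is computed on binary networks")
    cp = mean_clustering(net)
    lp = characteristic_path_length(net)
    children = np.random.SeedSequence(seed).spawn(n_null)
    cps, lps = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for child in children:
            null = rewire_null(net, seed=np.random.default_rng(child))
            cps.append(mean_clustering(null))
            lps.append(characteristic_path_length(null))
    cp_null = float(np.mean(cps))
    lp_null = float(np.mean(lps))
    if cp_null == 0:
        raise ValueError("null networks have zero clustering; sigma undefined")
    return (cp / cp_null) / (lp / lp_null)


def global_metrics(net: ThresholdedNetwork, sigma: bool = False, n_null: int = 100, seed: int = 0) -> dict[str, float]:
    """All global metrics of one network as a flat dict."""
    out = {
        "cp": mean_clustering(net),
        "lp": characteristic_path_length(net),
        "e_glob": global_efficiency(net),
        "e_loc": local_efficiency(net),
    }
    if sigma:
        out["smallworld_sigma"] = small_worldness(net, n_null=n_null, seed=seed)
    return out


def nodal_metrics(net: ThresholdedNetwork) -> dict[str, np.ndarray]:
    """Per-node degree, clustering, and local efficiency arrays."""
    return {
        "degree": degree_vector(net).astype(float),
        "clustering": _clustering_vector(net),
        "local_efficiency": np.array(
            [_nodal_local_efficiency(net, i) for i in range(net.n_nodes)]
        ),
    }
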