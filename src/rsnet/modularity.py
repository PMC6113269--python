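"""Modular structure and partition-similarity machinery.

Partitions come from Louvain optimization (best modularity over seeded
restarts). Similarity between two subjects' partitions is either

* NMI — normalized mutual information, 2*I/(H1+H2) form, in [0, 1]; or
* phi — for a node of interest (NOI), the Pearson correlation of the two
  subjects' dichotomous "shares a module with the NOI" vectors.

Group differences in similarity are tested by permuting group membership:
the statistic is the pooled mean within-group pairwise similarity, and the
p-value is the fraction of permutations whose statistic strictly exceeds
the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import ModularPartition, ThresholdedNetwork


def _to_graph(net: ThresholdedNetwork) -> nx.Graph:
    g = nx.from_numpy_array(net.adjacency)
    return g


def detect_modules(
    net: ThresholdedNetwork,
    n_restarts: int = 20,
    seed: int = 0,
    resolution: float = 1.0,
) -> ModularPartition:
    """Best-of-``n_restarts`` Louvain partition of the network.

    Weighted networks are partitioned on their |z| weights, binary on unit
    weights. Deterministic given the seed; Q is the weighted Newman-Girvan
    modularity of the returned labels.
    """
    g = _to_graph(net)
    weight = "weight"
    best_labels: np.ndarray | None = None
    best_q = -np.inf
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        sub = int(rng.integers(0, 2**31 - 1))
        communities = nx.community.louvain_communities(
            g, weight=weight, resolution=resolution, seed=sub
        )
        labels = np.empty(net.n_nodes, dtype=int)
        for mod_id, members in enumerate(communities, start=1):
            labels[list(members)] = mod_id
        q = modularity_q(net, labels)
        if q > best_q:
            best_q = q
            best_labels = labels
    assert best_labels is not None
    return ModularPartition(
        labels=best_labels,
        node_labels=net.parcel_labels,
        q=float(best_q),
        cost=net.cost,
        mode=net.mode,
    )


def modularity_q(net: ThresholdedNetwork, labels: np.ndarray | ModularPartition) -> float:
    """Newman-Girvan modularity Q of a given partition (weighted
    generalization in weighted mode):

        Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] * delta(c_i, c_j)
    """
    if isinstance(labels, ModularPartition):
        labels = labels.labels
    labels = np.asarray(labels)
    if labels.size != net.n_nodes:
        raise ValueError("every node must be labeled")
    a = net.adjacency
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("empty graph has undefined modularity")
    k = a.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    q = (a[same].sum() - (np.outer(k, k)[same]).sum() / two_m) / two_m
    return float(q)


# ---------------------------------------------------------------- similarity

def nmi(p1: ModularPartition, p2: ModularPartition) -> float:
    """Normalized mutual information between two partitions of the same
    node set, 2*I(X;Y)/(H(X)+H(Y)), in [0, 1]; 1 for identical partitions
    (up to relabeling), 0 for independent ones.

    Two single-module partitions (both entropies zero) are identical and
    return 1.
    """
    if p1.node_labels != p2.node_labels:
        raise ValueError("partitions cover different node sets")
    return nmi_labels(p1.labels, p2.labels)


def nmi_labels(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("label vectors differ in length")
    n = x.size
    joint: dict[tuple[int, int], int] = {}
    for a, b in zip(x.tolist(), y.tolist()):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    pxy = np.array(list(joint.values()), dtype=float) / n
    _, cx = np.unique(x, return_counts=True)
    _, cy = np.unique(y, return_counts=True)
    px = cx / n
    py = cy / n
    hx = -np.sum(px * np.log(px))
    hy = -np.sum(py * np.log(py))
    if hx + hy == 0:
        return 1.0  # both trivial single-module partitions: identical
    px_of = {a: c / n for a, c in zip(*np.unique(x, return_counts=True))}
    py_of = {b: c / n for b, c in zip(*np.unique(y, return_counts=True))}
    mi = 0.0
    for (a, b), cnt in joint.items():
        p = cnt / n
        mi += p * np.log(p / (px_of[a] * py_of[b]))
    return float(min(1.0, max(0.0, 2.0 * mi / (hx + hy))))


def phi_comodule(noi: str, p1: ModularPartition, p2: ModularPartition) -> float | None:
    """Phi coefficient between two subjects' comodule vectors for a node
    of interest: each other node scores 1 if it shares the NOI's module.

    Returns None when either vector is constant (the NOI alone in its
    module, or the whole graph one module) — the pair is undefined and is
    excluded from averaging by the callers.
    """
    v1 = p1.comodule_vector(noi)
    v2 = p2.comodule_vector(noi)
    if v1.std() == 0 or v2.std() == 0:
        return None
    return float(np.corrcoef(v1, v2)[0, 1])


def nmi_matrix(partitions: list[ModularPartition]) -> np.ndarray:
    """Symmetric subject x subject NMI matrix (diagonal 1)."""
    n = len(partitions)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = nmi(partitions[i], partitions[j])
    return s


def phi_matrix(noi: str, partitions: list[ModularPartition]) -> np.ndarray:
    """Symmetric subject x subject phi matrix for one NOI; undefined pairs
    are NaN (excluded downstream) and their count is reported via a
    warning when nonzero."""
    n = len(partitions)
    s = np.full((n, n), np.nan)
    np.fill_diagonal(s, 1.0)
    n_undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            val = phi_comodule(noi, partitions[i], partitions[j])
            if val is None:
                n_undefined += 1
            else:
                s[i, j] = s[j, i] = val
    if n_undefined:
        warnings.warn(
            f"{n_undefined} undefined phi pair(s) for NOI {noi!r} excluded"
        )
    return s


# ----------------------------------------------------------- permutation test

@dataclass
class PermutationTestResult:
    """Outcome of the group-membership permutation test."""

    observed_within: float
    permuted_within: np.ndarray
    n_perm: int
    seed: int
    statistic_kind: str = "similarity"

    @property
    def p_value(self) -> float:
        """Fraction of permutations strictly exceeding the observed pooled
        within-group similarity (ties never exceed)."""
        return float(np.sum(self.permuted_within > self.observed_within) / self.n_perm)


def _within_group_mean(s: np.ndarray, groups: np.ndarray) -> float:
    """Pooled mean pairwise similarity over same-group pairs (both groups
    pooled, weighted by pair counts); NaN entries excluded."""
    same = groups[:, None] == groups[None, :]
    iu = np.triu_indices(s.shape[0], k=1)
    vals = s[iu]
    mask = same[iu] & ~np.isnan(vals)
    if not mask.any():
        raise ValueError("no defined within-group pairs")
    return float(vals[mask].mean())


def between_group_mean(s: np.ndarray, groups: np.ndarray) -> float:
    groups = np.asarray(groups)
    diff = groups[:, None] != groups[None, :]
    iu = np.triu_indices(s.shape[0], k=1)
    vals = s[iu]
    mask = diff[iu] & ~np.isnan(vals)
    return float(vals[mask].mean())


def permutation_similarity_test(
    similarities: np.ndarray,
    group_labels: list[str] | np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    statistic_kind: str = "similarity",
) -> PermutationTestResult:
    """Permutation test of whether within-group partition similarity
    exceeds what random group membership produces.

    ``similarities`` is the symmetric subject-pair matrix (NaN = undefined
    pair, excluded); each permutation shuffles the group labels and
    recomputes the pooled within-group mean. The p-value counts strict
    exceedances only.
    """
    s = np.asarray(similarities, dtype=float)
    groups = np.asarray(group_labels)
    if s.shape[0] != s.shape[1] or s.shape[0] != groups.size:
        raise ValueError("similarity matrix and group labels are inconsistent")
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size != 2:
        raise ValueError(f"exactly two groups required, got {uniq.size}")
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 subjects for within-group pairs")
    observed = _within_group_mean(s, groups)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        permuted[k] = _within_group_mean(s, rng.permutation(groups))
    return PermutationTestResult(
        observed_within=observed,
        permuted_within=permuted,
        n_perm=n_perm,
        seed=seed,
        statistic_kind=statistic_kind,
    )
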