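"""Core containers shared across the pipeline.

A subject's journey through the pipeline is: parcel-level BOLD time series
(:class:`ParcelTimeSeries`) -> interregional Pearson correlations and
Fisher-z edge weights (:class:`ConnectivityMatrix`) -> a connected,
cost-thresholded graph (:class:`ThresholdedNetwork`) -> graph metrics and a
modular partition (:class:`ModularPartition`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Mode = Literal["weighted", "binary"]

#: fraction of possible node pairs retained as edges, for a grid purpose
GLOBAL_COST_RANGE = (0.03, 0.40)
REGIONAL_COST_RANGE = (0.03, 0.10)


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return int(np.floor(x + 0.5))


@dataclass
class ParcelTimeSeries:
    """One subject-phase matrix of BOLD-like values, T samples x N parcels.

    Parameters
    ----------
    values
        T x N array; rows are time points, columns are parcels.
    parcel_labels
        N unique parcel names.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    """

    values: np.ndarray
    parcel_labels: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.parcel_labels = list(self.parcel_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (T x N) matrix")
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise ValueError(f"need T >= 2 and N >= 2, got T={t}, N={n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if len(self.parcel_labels) != n:
            raise ValueError(
                f"{len(self.parcel_labels)} labels for {n} parcels"
            )
        if len(set(self.parcel_labels)) != n:
            raise ValueError("parcel labels must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    def with_values(self, values: np.ndarray) -> "ParcelTimeSeries":
        """Same metadata, new values (cleaning steps never change shape)."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("cleaning must preserve the T x N shape")
        return ParcelTimeSeries(values, self.parcel_labels, self.tr_seconds)


@dataclass
class ConnectivityMatrix:
    """Symmetric interregional connectivity: r, Fisher z, and |z| weights.

    ``weights`` (= |z|) is what thresholding consumes; the signed ``r`` and
    ``z`` matrices are retained for audit only.
    """

    r: np.ndarray
    parcel_labels: list[str]
    z: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("r must be square")
        if len(self.parcel_labels) != n:
            raise ValueError("label count must match matrix size")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("r must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("diagonal of r must be 1")
        offdiag = self.r[~np.eye(n, dtype=bool)]
        if np.any(np.abs(offdiag) > 1.0 + 1e-12):
            raise ValueError("|r| must not exceed 1")

    @property
    def n_parcels(self) -> int:
        return self.r.shape[0]


@dataclass
class ThresholdedNetwork:
    """Connected graph at a given cost, weighted (|z| entries) or binary."""

    adjacency: np.ndarray
    cost: float
    mode: Mode
    parcel_labels: list[str]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.allclose(self.adjacency, self.adjacency.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are excluded")
        if np.any(self.adjacency < 0):
            raise ValueError("weights must be nonnegative")
        if self.mode == "binary":
            nz = self.adjacency[self.adjacency != 0]
            if not np.all(nz == 1.0):
                raise ValueError("binary adjacency entries must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return set(zip(i.tolist(), j.tolist()))


@dataclass
class CostGrid:
    """Ordered cost (sparsity) levels at which networks are built.

    The global grid spans 0.03-0.40 and the regional grid 0.03-0.10, both
    in steps of 0.01 (38 and 8 levels respectively).
    """

    costs: list[float]
    purpose: Literal["global", "regional", "custom"] = "custom"

    def __post_init__(self) -> None:
        self.costs = [float(c) for c in self.costs]
        if not self.costs:
            raise ValueError("grid is empty")
        if any(not (0 < c < 1) for c in self.costs):
            raise ValueError("costs must lie in (0, 1)")
        if any(b <= a for a, b in zip(self.costs, self.costs[1:])):
            raise ValueError("costs must be strictly increasing")

    def __len__(self) -> int:
        return len(self.costs)

    def __iter__(self):
        return iter(self.costs)

    @classmethod
    def from_range(
        cls,
        low: float,
        high: float,
        step: float = 0.01,
        purpose: Literal["global", "regional", "custom"] = "custom",
    ) -> "CostGrid":
        n = round_half_up((high - low) / step) + 1
        costs = [round(low + k * step, 10) for k in range(n)]
        return cls(costs, purpose)

    @classmethod
    def global_grid(cls) -> "CostGrid":
        return cls.from_range(*GLOBAL_COST_RANGE, purpose="global")

    @classmethod
    def regional_grid(cls) -> "CostGrid":
        return cls.from_range(*REGIONAL_COST_RANGE, purpose="regional")


@dataclass
class ModularPartition:
    """Node -> module assignment with its modularity score.

    Module ids are contiguous integers starting at 1, ordered by first
    appearance over the node order.
    """

    labels: np.ndarray
    node_labels: list[str]
    q: float = float("nan")
    cost: float | None = None
    mode: Mode | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if len(self.node_labels) != self.labels.size:
            raise ValueError("one module label per node required")
        self.labels = _canonical_labels(self.labels)

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def n_nodes(self) -> int:
        return int(self.labels.size)

    def comodule_vector(self, noi: str) -> np.ndarray:
        """Binary vector over the other nodes: 1 if in the NOI's module."""
        try:
            idx = self.node_labels.index(noi)
        except ValueError:
            raise KeyError(f"unknown node of interest: {noi!r}") from None
        same = (self.labels == self.labels[idx]).astype(int)
        return np.delete(same, idx)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..K in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[int(lab)] = len(mapping) + 1
        out[i] = mapping[int(lab)]
    return out


def default_parcel_labels(n_parcels: int = 90) -> list[str]:
    """Parcel names for an n-region cerebral parcellation (45 or 55 areas
    per hemisphere for the 90- and 110-node label sets)."""
    half = n_parcels // 2
    labels = []
    for k in range(1, half + 1):
        labels.append(f"region{k:03d}_L")
        labels.append(f"region{k:03d}_R")
    # odd n: pad with a midline region
    if n_parcels % 2:
        labels.append("region_midline")
    return labels[:n_parcels] if len(labels) >= n_parcels else labels
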