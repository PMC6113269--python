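import numpy as np
import pytest

from rsnet.datatypes import ParcelTimeSeries, ThresholdedNetwork


def network_from_edges(n, edges, mode="binary", weights=None, cost=0.2):
    adj = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        adj[i, j] = adj[j, i] = w
    return ThresholdedNetwork(
        adj, cost=cost, mode=mode, parcel_labels=[f"n{i}" for i in range(n)]
    )


@pytest.fixture
def k4():
    """Complete binary graph on 4 nodes."""
    return network_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])


@pytest.fixture
def star4():
    """Star: hub 0 with 3 leaves."""
    return network_from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def path3():
    """Path 0-1-2."""
    return network_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def bowtie():
    """Two triangles sharing node 0 (nodes 1,2 and 3,4)."""
    return network_from_edges(
        5, [(0, 1), (0, 2), (1, 2), (0, 3), (0, 4), (3, 4)]
    )


@pytest.fixture
def random_series():
    rng = np.random.default_rng(7)
    return ParcelTimeSeries(
        rng.standard_normal((120, 12)),
        [f"p{i}" for i in range(12)],
        tr_seconds=2.5,
    )
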