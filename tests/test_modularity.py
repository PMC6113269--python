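"""Module detection, modularity, NMI/phi similarity, permutation test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import networkx as nx

from rsnet.cohort import near_equal_partition, generate_subject_timeseries
from rsnet.connectivity import build_networks_over_grid, connectivity_from_series
from rsnet.datatypes import CostGrid, ModularPartition
from rsnet.modularity import (
    detect_modules,
    modularity_q,
    nmi,
    nmi_labels,
    permutation_similarity_test,
    phi_comodule,
    phi_matrix,
)

from _oracles import best_partition_exhaustive, modularity_q as oracle_q, nmi_entropy
from conftest import network_from_edges


def two_cliques_bridge():
    """Two K4 cliques joined by a single bridge edge."""
    edges = [(i, j) for i, j in itertools.combinations(range(4), 2)]
    edges += [(i + 4, j + 4) for i, j in itertools.combinations(range(4), 2)]
    edges += [(3, 4)]
    return network_from_edges(8, edges)


def partition_of(net, labels):
    return ModularPartition(np.asarray(labels), net.parcel_labels)


class TestModularityQ:
    def test_single_module_is_zero(self, k4):
        assert modularity_q(k4, np.ones(4, int)) == pytest.approx(0.0)

    def test_two_disjoint_cliques_half(self):
        edges = [(i, j) for i, j in itertools.combinations(range(4), 2)]
        edges += [(i + 4, j + 4) for i, j in itertools.combinations(range(4), 2)]
        edges += [(0, 4)]  # keep container's graph connected via weak bridge
        net = network_from_edges(8, edges)
        # remove the bridge to evaluate the idealized two-component case
        adj = net.adjacency.copy()
        adj[0, 4] = adj[4, 0] = 0
        net2 = network_from_edges(8, [(i, j) for i in range(8) for j in range(i + 1, 8) if adj[i, j]])
        q = modularity_q(net2, np.repeat([1, 2], 4))
        assert q == pytest.approx(0.5)

    def test_bridge_example_value_and_oracle(self):
        net = two_cliques_bridge()
        labels = np.repeat([1, 2], 4)
        q = modularity_q(net, labels)
        assert q == pytest.approx(11 / 26, abs=1e-12)
        assert q == pytest.approx(oracle_q(net.adjacency, labels), abs=1e-12)

    def test_matches_networkx_on_random_weighted_graph(self):
        rng = np.random.default_rng(1)
        w = np.abs(rng.standard_normal((10, 10)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = network_from_edges(
            10,
            [(i, j) for i in range(10) for j in range(i + 1, 10)],
            mode="weighted",
            weights=[w[i, j] for i in range(10) for j in range(i + 1, 10)],
        )
        labels = rng.integers(1, 4, size=10)
        g = nx.from_numpy_array(net.adjacency)
        communities = [set(np.nonzero(labels == m)[0]) for m in np.unique(labels)]
        assert modularity_q(net, labels) == pytest.approx(
            nx.community.modularity(g, communities, weight="weight"), abs=1e-12
        )

    def test_unlabeled_node_rejected(self, k4):
        with pytest.raises(ValueError):
            modularity_q(k4, np.ones(3, int))


class TestDetectModules:
    def test_two_cliques_found_exactly(self):
        net = two_cliques_bridge()
        part = detect_modules(net, seed=0)
        assert part.n_modules == 2
        assert part.q == pytest.approx(11 / 26, abs=1e-9)
        # matches the exhaustive optimum over all partitions of 8 nodes
        _, best_q = best_partition_exhaustive(net.adjacency)
        assert part.q == pytest.approx(best_q, abs=1e-9)
        assert len(set(part.labels[:4])) == 1 and len(set(part.labels[4:])) == 1

    def test_deterministic_given_seed(self, random_series):
        conn = connectivity_from_series(random_series)
        net = build_networks_over_grid(conn, CostGrid([0.4]), "weighted")[0]
        p1 = detect_modules(net, seed=123)
        p2 = detect_modules(net, seed=123)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.q == p2.q

    def test_planted_partition_recovered(self):
        part = near_equal_partition(60, 5)
        hits = []
        for seed in range(10):
            ts = generate_subject_timeseries(part, 0.5, 0.05, t=200, ar=0.3, seed=seed)
            conn = connectivity_from_series(ts)
            net = build_networks_over_grid(conn, CostGrid([0.2]), "weighted")[0]
            found = detect_modules(net, seed=seed)
            hits.append(nmi_labels(found.labels, part))
        assert np.mean(hits) >= 0.9

    def test_q_at_least_trivial_partition(self, star4, path3):
        for net in (star4, path3):
            assert detect_modules(net, seed=0).q >= -1e-12


class TestNMI:
    def test_identity_and_relabeling(self):
        labels = np.array([1, 1, 2, 2, 3, 3, 3])
        nodes = [f"n{i}" for i in range(7)]
        p = ModularPartition(labels, nodes)
        q = ModularPartition(np.array([3, 3, 1, 1, 2, 2, 2]), nodes)
        assert nmi(p, p) == 1.0
        assert nmi(p, q) == 1.0

    def test_independent_partitions_zero(self):
        x = np.array([1, 1, 2, 2])
        y = np.array([1, 2, 1, 2])
        assert nmi_labels(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_entropy_oracle_and_sklearn(self):
        from sklearn.metrics import normalized_mutual_info_score

        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.integers(1, 5, size=30)
            y = rng.integers(1, 4, size=30)
            ours = nmi_labels(x, y)
            assert ours == pytest.approx(nmi_entropy(x, y), abs=1e-10)
            assert ours == pytest.approx(
                normalized_mutual_info_score(x, y, average_method="arithmetic"),
                abs=1e-10,
            )

    def test_node_set_mismatch_rejected(self):
        p = ModularPartition(np.array([1, 2]), ["a", "b"])
        q = ModularPartition(np.array([1, 2]), ["a", "c"])
        with pytest.raises(ValueError):
            nmi(p, q)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(1, 4), min_size=4, max_size=24),
        st.data(),
    )
    def test_symmetry_and_range(self, x, data):
        y = data.draw(st.lists(st.integers(1, 4), min_size=len(x), max_size=len(x)))
        x, y = np.array(x), np.array(y)
        a, b = nmi_labels(x, y), nmi_labels(y, x)
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= 1.0


class TestPhi:
    def _partitions(self):
        nodes = [f"n{i}" for i in range(5)]
        p1 = ModularPartition(np.array([1, 1, 1, 2, 2]), nodes)  # comodule(n0): 1,1,0,0
        p2 = ModularPartition(np.array([1, 1, 2, 1, 2]), nodes)  # comodule(n0): 1,0,1,0
        return nodes, p1, p2

    def test_identical_and_complementary(self):
        nodes, p1, _ = self._partitions()
        assert phi_comodule("n0", p1, p1) == pytest.approx(1.0)
        p_comp = ModularPartition(np.array([1, 2, 2, 1, 1]), nodes)
        assert phi_comodule("n0", p1, p_comp) == pytest.approx(-1.0)

    def test_balanced_2x2_table_zero(self):
        _, p1, p2 = self._partitions()
        assert phi_comodule("n0", p1, p2) == pytest.approx(0.0)

    def test_constant_vector_undefined(self):
        nodes = [f"n{i}" for i in range(4)]
        lonely = ModularPartition(np.array([1, 2, 2, 2]), nodes)  # n0 alone
        other = ModularPartition(np.array([1, 1, 2, 2]), nodes)
        assert phi_comodule("n0", lonely, other) is None
        with pytest.warns(UserWarning, match="undefined"):
            s = phi_matrix("n0", [lonely, other])
        assert np.isnan(s[0, 1])


class TestPermutationTest:
    def test_perfectly_separated_groups(self):
        # 3+3 subjects, each group internally identical, groups differ
        nodes = [f"n{i}" for i in range(6)]
        pa = ModularPartition(np.array([1, 1, 1, 2, 2, 2]), nodes)
        pb = ModularPartition(np.array([1, 1, 2, 2, 3, 3]), nodes)
        parts = [pa] * 3 + [pb] * 3
        from rsnet.modularity import nmi_matrix

        sim = nmi_matrix(parts)
        res = permutation_similarity_test(
            sim, ["A"] * 3 + ["B"] * 3, n_perm=2000, seed=0
        )
        assert res.observed_within == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_all_identical_strict_rule_gives_zero(self):
        sim = np.ones((6, 6))
        res = permutation_similarity_test(sim, ["A"] * 3 + ["B"] * 3, n_perm=500, seed=1)
        assert res.p_value == 0.0  # ties never strictly exceed

    def test_exhaustive_enumeration_matches(self):
        # small asymmetric similarity structure; compare the permutation
        # distribution against explicit enumeration of all 4!/(2!2!)-type
        # label arrangements via itertools
        rng = np.random.default_rng(2)
        s = rng.random((4, 4))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1)
        groups = np.array(["A", "A", "B", "B"])
        res = permutation_similarity_test(s, groups, n_perm=4000, seed=3)
        iu = np.triu_indices(4, 1)

        def stat(lab):
            lab = np.array(lab)
            same = lab[:, None] == lab[None, :]
            return s[iu][same[iu]].mean()

        all_stats = [stat(p) for p in set(itertools.permutations(groups))]
        exceed = np.mean([v > res.observed_within for v in all_stats])
        assert res.p_value == pytest.approx(exceed, abs=0.03)

    def test_reproducible_and_strict_count(self):
        rng = np.random.default_rng(4)
        s = rng.random((10, 10))
        s = (s + s.T) / 2
        groups = ["A"] * 5 + ["B"] * 5
        r1 = permutation_similarity_test(s, groups, n_perm=300, seed=7)
        r2 = permutation_similarity_test(s, groups, n_perm=300, seed=7)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.permuted_within, r2.permuted_within)
        assert r1.p_value == np.sum(r1.permuted_within > r1.observed_within) / 300

    def test_small_group_rejected(self):
        s = np.ones((3, 3))
        with pytest.raises(ValueError, match="at least 2"):
            permutation_similarity_test(s, ["A", "B", "B"], n_perm=10, seed=0)
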