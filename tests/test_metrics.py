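"""Graph metrics against networkx and hand-derived values."""

import networkx as nx
import numpy as np
import pytest

from bruteforce import complete_graph, path_graph, random_graph, ring_lattice, star_graph

from scnkit import (
    DataError,
    assortativity,
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    global_metrics,
    local_efficiency,
    modularity,
    random_null_ensemble,
    small_world,
    transitivity,
)
from scnkit.metrics import modularity_partition, randomize_degree_preserving


class TestAgainstNetworkx:
    """networkx is an independent implementation of every standard metric."""

    @pytest.mark.parametrize("seed,n,p", [(0, 15, 0.3), (1, 25, 0.5), (2, 40, 0.2)])
    def test_metrics_match(self, seed, n, p):
        adj = random_graph(n, p, np.random.default_rng(seed))
        G = nx.from_numpy_array(adj)
        assert clustering_coefficient(adj) == pytest.approx(
            nx.average_clustering(G), abs=1e-12
        )
        assert transitivity(adj) == pytest.approx(nx.transitivity(G), abs=1e-12)
        assert local_efficiency(adj) == pytest.approx(nx.local_efficiency(G), abs=1e-12)
        assert global_efficiency(adj) == pytest.approx(nx.global_efficiency(G), abs=1e-12)
        if nx.is_connected(G):
            assert characteristic_path_length(adj) == pytest.approx(
                nx.average_shortest_path_length(G), abs=1e-12
            )
        nx_bc = nx.betweenness_centrality(G, normalized=False)
        mine = betweenness(adj)
        assert np.allclose(mine.bc_raw, [nx_bc[i] for i in range(n)], atol=1e-10)
        nx_assort = nx.degree_assortativity_coefficient(G)
        assert assortativity(adj) == pytest.approx(nx_assort, abs=1e-9)


class TestHandValues:
    def test_path_p4(self):
        p4 = path_graph(4)
        assert characteristic_path_length(p4) == pytest.approx(10 / 6)
        assert list(betweenness(p4).bc_raw) == [0, 2, 2, 0]
        assert list(betweenness(p4).bc_norm) == [0, 2, 2, 0]

    def test_star(self):
        s = star_graph(3)
        assert global_efficiency(s) == pytest.approx(0.75)
        assert local_efficiency(s) == 0.0
        assert assortativity(s) == pytest.approx(-1.0)
        nm = betweenness(s)
        assert nm.bc_raw[0] == 3.0 and nm.bc_norm[0] == pytest.approx(4.0)

    def test_ring_lattice_assortativity_undefined(self):
        assert np.isnan(assortativity(ring_lattice(10, 4)))

    def test_disconnected_lp_raises(self):
        adj = np.zeros((4, 4), dtype=np.uint8)
        adj[0, 1] = adj[1, 0] = 1
        with pytest.raises(DataError, match="disconnected"):
            characteristic_path_length(adj)
        assert global_efficiency(np.zeros((2, 2), dtype=np.uint8)) == 0.0


class TestModularity:
    def test_two_triangles(self):
        adj = np.zeros((6, 6), dtype=np.uint8)
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[a, b] = adj[b, a] = 1
        q, labels = modularity_partition(adj)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len({labels[0], labels[3]}) == 2
        assert labels[0] == labels[1] == labels[2]

    def test_complete_graph_single_community(self):
        assert modularity(complete_graph(5)) == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_rejected(self):
        with pytest.raises(DataError):
            modularity(np.zeros((4, 4), dtype=np.uint8))

    def test_heuristic_close_to_louvain_at_scale(self):
        """Above the exact-search size the greedy+refine heuristic should be
        competitive with networkx's Louvain on a planted-partition graph."""
        rng = np.random.default_rng(0)
        sizes = [15, 15, 15]
        n = sum(sizes)
        labels = np.repeat([0, 1, 2], 15)
        prob = np.where(labels[:, None] == labels[None, :], 0.6, 0.05)
        adj = (rng.random((n, n)) < prob).astype(np.uint8)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        q_mine = modularity(adj)
        G = nx.from_numpy_array(adj)
        part = nx.community.louvain_communities(G, seed=1)
        q_louvain = nx.community.modularity(G, part)
        assert q_mine >= q_louvain - 0.02


class TestNullEnsemble:
    def test_degree_sequence_and_connectivity_preserved(self):
        adj = random_graph(30, 0.25, np.random.default_rng(5))
        G = nx.from_numpy_array(adj)
        if not nx.is_connected(G):  # make it connected deterministically
            comps = list(nx.connected_components(G))
            for c1, c2 in zip(comps, comps[1:]):
                i, j = min(c1), min(c2)
                adj[i, j] = adj[j, i] = 1
        null = randomize_degree_preserving(adj, seed=3)
        assert (null.degrees() == adj.sum(axis=1)).all()
        assert null.is_connected()
        assert not (null.adjacency == adj).all()

    def test_same_seed_identical_summary(self):
        adj = ring_lattice(20, 4)
        assert random_null_ensemble(adj, n_null=5, seed=9) == random_null_ensemble(
            adj, n_null=5, seed=9
        )

    def test_ring_lattice_null_cp_below_lattice(self):
        adj = ring_lattice(20, 4)
        cpr, lpr = random_null_ensemble(adj, n_null=20, seed=1)
        assert cpr < clustering_coefficient(adj)
        assert lpr < characteristic_path_length(adj)

    def test_er_mode_runs(self):
        adj = ring_lattice(20, 4)
        cpr, lpr = random_null_ensemble(adj, n_null=5, seed=2, null_model="er")
        assert 0 < cpr < 1 and lpr > 1

    def test_disconnected_input_rejected(self):
        with pytest.raises(DataError, match="connected"):
            random_null_ensemble(np.zeros((5, 5), dtype=np.uint8))


class TestSmallWorld:
    def test_self_normalization(self):
        assert small_world(0.5, 2.0, 0.5, 2.0) == (1.0, 1.0, 1.0)

    def test_arithmetic(self):
        gamma, lam, sigma = small_world(0.6, 2.2, 0.3, 2.0)
        assert (gamma, lam) == (2.0, pytest.approx(1.1))
        assert sigma == pytest.approx(2.0 / 1.1)

    def test_zero_null_rejected(self):
        with pytest.raises(DataError):
            small_world(0.5, 2.0, 0.0, 2.0)

    def test_ring_lattice_is_small_world_vs_nulls(self):
        gm = global_metrics(ring_lattice(24, 6), n_null=10, seed=4)
        assert gm.gamma > 1 and gm.sigma > 1
        assert gm.sigma == pytest.approx(gm.gamma / gm.lam)

    def test_complete_graph_limits(self):
        k = complete_graph(6)
        assert clustering_coefficient(k) == 1.0
        assert transitivity(k) == 1.0
        assert characteristic_path_length(k) == 1.0
        assert global_efficiency(k) == 1.0
        assert local_efficiency(k) == 1.0
        nm = betweenness(k)
        assert (nm.bc_raw == 0).all() and not nm.norm_defined
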