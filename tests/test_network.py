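"""Graph construction and small-world metrics against brute-force oracles."""

import numpy as np
import pytest

from synchnet.network import (
    NetworkSummary,
    WeightedGraph,
    char_path_length,
    clustering_coefficient,
    density_sweep,
    node_degree,
    rewire_random,
    small_world_indices,
    threshold_graph,
)
from synchnet.phasesync import PSIMatrix

from conftest import random_weighted_graph


# -- independent oracles -----------------------------------------------------


def degree_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    return np.array([sum(w[i, j] for j in range(n)) for i in range(n)])


def clustering_oracle(w: np.ndarray, mode: str) -> float:
    n = w.shape[0]
    what = (w / w.max()) ** (1.0 / 3.0)
    cis = []
    for i in range(n):
        s = 0.0
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) == 3:
                    s += what[i, j] * what[i, h] * what[j, h]
        if mode == "onnela":
            k_i = sum(1 for j in range(n) if w[i, j] > 0)
            denom = k_i * (k_i - 1)
        else:
            d_i = sum(w[i])
            denom = d_i * (d_i - 1)
        cis.append(s / denom if denom > 0 else 0.0)
    return float(np.mean(cis))


def path_length_oracle(w: np.ndarray) -> float:
    """Floyd-Warshall over 1/w lengths; harmonic mean over ordered pairs."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    inv = [
        0.0 if np.isinf(d[i, j]) else 1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    mean_inv = np.mean(inv)
    return np.inf if mean_inv == 0 else float(1.0 / mean_inv)


# -- threshold_graph ---------------------------------------------------------


class TestThresholdGraph:
    def test_full_graph_density_one(self, rng):
        m = rng.uniform(0.1, 1, size=(28, 28))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        g = threshold_graph(m, 378)
        assert g.density == 1.0

    def test_density_120_of_378(self, rng):
        g = random_weighted_graph(rng, 28, 120)
        assert g.density == pytest.approx(120 / 378)
        assert g.density == pytest.approx(0.3175, abs=5e-5)

    def test_top_k_matches_sort_oracle(self, rng):
        m = rng.uniform(0, 1, size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        g = threshold_graph(m, 3)
        iu = np.triu_indices(4, k=1)
        top3 = sorted(m[iu], reverse=True)[:3]
        kept = sorted(g.weights[iu][g.weights[iu] > 0], reverse=True)
        assert kept == pytest.approx(top3)

    def test_exactly_k_edges_under_ties(self):
        m = np.full((5, 5), 0.5)
        np.fill_diagonal(m, 0)
        g = threshold_graph(m, 4)
        assert g.k == 4
        # deterministic tie order: ascending (i, j) pairs win
        assert g.edge_list() == [
            (0, 1, 0.5), (0, 2, 0.5), (0, 3, 0.5), (0, 4, 0.5)
        ]

    def test_k_out_of_range(self, rng):
        m = np.zeros((4, 4))
        with pytest.raises(ValueError):
            threshold_graph(m, 7)
        with pytest.raises(ValueError):
            threshold_graph(m, 0)

    def test_psi_matrix_input_keeps_labels(self, rng):
        m = rng.uniform(0, 1, size=(4, 4))
        m = np.clip((m + m.T) / 2, 0, 1)
        np.fill_diagonal(m, 0)
        mat = PSIMatrix(values=m, channels=["a", "b", "c", "d"], band="theta")
        g = threshold_graph(mat, 2)
        assert g.labels == ["a", "b", "c", "d"]


# -- metric oracles ----------------------------------------------------------


class TestMetricOracles:
    def test_degree_complete_equal_weight(self):
        n, w = 6, 0.4
        m = np.full((n, n), w)
        np.fill_diagonal(m, 0)
        g = WeightedGraph([f"N{i}" for i in range(n)], m, n * (n - 1) // 2, w)
        assert node_degree(g) == pytest.approx([(n - 1) * w] * n)

    def test_handshake_identity(self, rng):
        g = random_weighted_graph(rng, 7, 11)
        iu = np.triu_indices(7, k=1)
        assert node_degree(g).sum() == pytest.approx(2 * g.weights[iu].sum())

    def test_unit_triangle_clustering(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = m[0, 2] = m[2, 0] = m[1, 2] = m[2, 1] = 1.0
        g = WeightedGraph(["a", "b", "c"], m, 3, 1.0)
        assert clustering_coefficient(g, "onnela") == pytest.approx(1.0)

    def test_star_graph_no_triangles(self):
        m = np.zeros((4, 4))
        for j in (1, 2, 3):
            m[0, j] = m[j, 0] = 0.8
        g = WeightedGraph(list("abcd"), m, 3, 0.8)
        assert clustering_coefficient(g, "onnela") == 0.0

    @pytest.mark.parametrize("mode", ["onnela", "literal"])
    def test_weighted_triangle_both_modes(self, mode):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.8
        m[0, 2] = m[2, 0] = 0.5
        m[1, 2] = m[2, 1] = 0.2
        g = WeightedGraph(list("abc"), m, 3, 0.2)
        assert clustering_coefficient(g, mode) == pytest.approx(
            clustering_oracle(m, mode), abs=1e-12
        )

    def test_two_node_path_length(self):
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = 0.25
        g = WeightedGraph(["a", "b"], m, 1, 0.25)
        assert char_path_length(g) == pytest.approx(4.0)

    def test_unit_triangle_path_length(self):
        m = np.ones((3, 3)) - np.eye(3)
        g = WeightedGraph(list("abc"), m, 3, 1.0)
        assert char_path_length(g) == pytest.approx(1.0)

    def test_random_graphs_match_oracles(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 9))
            k_max = n * (n - 1) // 2
            k = int(rng.integers(2, k_max + 1))
            g = random_weighted_graph(rng, n, k)
            assert node_degree(g) == pytest.approx(degree_oracle(g.weights), abs=1e-10)
            for mode in ("onnela", "literal"):
                assert clustering_coefficient(g, mode) == pytest.approx(
                    clustering_oracle(g.weights, mode), abs=1e-10
                )
            ell = char_path_length(g)
            oracle = path_length_oracle(g.weights)
            if np.isinf(oracle):
                assert np.isinf(ell)
            else:
                assert ell == pytest.approx(oracle, abs=1e-10)

    def test_arithmetic_path_length_mode(self, rng):
        g = random_weighted_graph(rng, 6, 10)
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import floyd_warshall

        lengths = np.where(g.weights > 0, 1.0 / np.where(g.weights > 0, g.weights, 1), 0)
        d = floyd_warshall(csr_matrix(lengths), directed=False)
        off = ~np.eye(6, dtype=bool)
        assert char_path_length(g, "arithmetic") == pytest.approx(d[off].mean())


# -- rewiring ----------------------------------------------------------------


class TestRewiring:
    def test_binary_degree_preserved(self, rng):
        for seed in range(10):
            g = random_weighted_graph(rng, 10, 18)
            null = rewire_random(g, seed=seed)
            assert ((null.weights > 0).sum(axis=1)
                    == (g.weights > 0).sum(axis=1)).all()

    def test_weight_multiset_preserved(self, rng):
        g = random_weighted_graph(rng, 10, 18)
        null = rewire_random(g, seed=3)
        iu = np.triu_indices(10, k=1)
        assert sorted(null.weights[iu][null.weights[iu] > 0]) == pytest.approx(
            sorted(g.weights[iu][g.weights[iu] > 0])
        )

    def test_no_self_loops_or_asymmetry(self, rng):
        g = random_weighted_graph(rng, 12, 30)
        null = rewire_random(g, seed=5)
        assert np.all(np.diag(null.weights) == 0)
        assert np.allclose(null.weights, null.weights.T)
        assert null.k == g.k

    def test_ring_lattice_clustering_destroyed(self):
        # n=28, each node tied to 2 neighbours either side -> K=56, C large
        n = 28
        m = np.zeros((n, n))
        for i in range(n):
            for off in (1, 2):
                j = (i + off) % n
                m[i, j] = m[j, i] = 1.0
        g = WeightedGraph([f"N{i}" for i in range(n)], m, 56, 1.0)
        c_lattice = clustering_coefficient(g)
        drops = 0
        n_seeds = 40
        for seed in range(n_seeds):
            null = rewire_random(g, seed=seed)
            if clustering_coefficient(null) < 0.5 * c_lattice:
                drops += 1
        assert drops >= 0.95 * n_seeds

    def test_unswappable_graph_warns_and_returns_input(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.9
        g = WeightedGraph(list("abc"), m, 1, 0.9)
        with pytest.warns(UserWarning):
            null = rewire_random(g, seed=0)
        assert np.allclose(null.weights, g.weights)


# -- small-world indices -----------------------------------------------------


class TestSmallWorld:
    def test_sigma_identity(self, rng):
        g = random_weighted_graph(rng, 12, 30)
        s = small_world_indices(g, n_random=5, seed=11)
        assert s.sigma == pytest.approx(s.gamma / s.lambda_)
        assert s.gamma == pytest.approx(s.clustering / s.c_rand)
        assert s.lambda_ == pytest.approx(s.path_length / s.l_rand)

    def test_rewired_input_self_normalizes(self, rng):
        g = random_weighted_graph(rng, 16, 40)
        null_input = rewire_random(g, seed=21)
        s = small_world_indices(null_input, n_random=20, seed=22)
        assert 0.8 < s.gamma < 1.2
        assert 0.8 < s.lambda_ < 1.2
        assert 0.8 < s.sigma < 1.2

    def test_density_sweep_counts_and_span(self, rng):
        m = rng.uniform(0, 1, size=(28, 28))
        m = np.clip((m + m.T) / 2, 0, 1)
        np.fill_diagonal(m, 0)
        mat = PSIMatrix(values=m, channels=[f"N{i}" for i in range(28)], band="theta")
        sweep = tuple(range(60, 181, 20))
        out = density_sweep(mat, sweep, n_random=2, seed=0)
        assert len(out) == 7
        assert round(out[0].density, 2) == 0.16
        assert round(out[-1].density, 2) == 0.48
        assert all(isinstance(s, NetworkSummary) for s in out)

    def test_metrics_local_to_top_k(self, rng):
        """The K=120 summary only depends on the top-120 edge set."""
        m = rng.uniform(0, 1, size=(28, 28))
        m = np.clip((m + m.T) / 2, 0, 1)
        np.fill_diagonal(m, 0)
        g_full = threshold_graph(m, 120)
        # zero out everything below the 121st edge; re-threshold
        g_121 = threshold_graph(m, 121)
        g_again = threshold_graph(g_121.weights, 120)
        assert np.allclose(g_full.weights, g_again.weights)

    def test_n_random_validation(self, rng):
        g = random_weighted_graph(rng, 8, 12)
        with pytest.raises(ValueError):
            small_world_indices(g, n_random=0)
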