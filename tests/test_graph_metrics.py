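"""Graph-metric oracles, surrogate invariants and normalization behaviour.

Brute-force oracles (explicit triple loops; exhaustive Floyd-Warshall via
scipy) are deliberately independent of the Dijkstra/einsum implementation
paths they check.
"""

import logging

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epinet.graph_metrics import (
    clustering_weighted,
    normalize,
    path_length_harmonic,
    rewire_surrogate,
)


# ------------------------------------------------------------------ oracles
def brute_clustering(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Onnela clustering by explicit triple enumeration."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0, np.zeros(n)
    wh = w / wmax
    c_i = np.zeros(n)
    k = (w > 0).sum(axis=1)
    for i in range(n):
        if k[i] < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != h and j != i and h != i:
                    acc += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        c_i[i] = acc / (k[i] * (k[i] - 1))
    can = k >= 2
    return (float(c_i[can].mean()) if can.any() else 0.0), c_i


def brute_path_length(w: np.ndarray) -> float:
    """Harmonic-mean path length via exhaustive Floyd-Warshall."""
    from scipy.sparse.csgraph import floyd_warshall

    n = w.shape[0]
    lengths = np.full((n, n), np.inf)
    lengths[w > 0] = 1.0 / w[w > 0]
    np.fill_diagonal(lengths, 0.0)
    d = floyd_warshall(lengths)
    inv = []
    for i in range(n):
        for j in range(n):
            if i != j:
                inv.append(0.0 if np.isinf(d[i, j]) else 1.0 / d[i, j])
    mean_inv = np.mean(inv)
    return float(1.0 / mean_inv) if mean_inv > 0 else float("inf")


def random_weighted_graph(rng, n, p=0.5):
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.uniform(0.1, 1.0, size=len(iu[0])) * (rng.random(len(iu[0])) < p)
    w[iu] = vals
    return w + w.T


class TestClusteringWeighted:
    def test_complete_triangle_equal_weights(self):
        w = np.array([[0, 0.4, 0.4], [0.4, 0, 0.4], [0.4, 0.4, 0]])
        c, c_i = clustering_weighted(w)
        assert c == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(c_i, 1.0)

    def test_path_graph_has_no_triangles(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.7
        w[1, 2] = w[2, 1] = 0.3
        c, c_i = clustering_weighted(w)
        assert c == 0.0
        assert np.all(c_i == 0.0)

    def test_four_node_weighted_graph_matches_brute_force(self):
        w = np.zeros((4, 4))
        pairs = {(0, 1): 1.0, (0, 2): 0.5, (1, 2): 0.5, (2, 3): 1.0}
        for (i, j), v in pairs.items():
            w[i, j] = w[j, i] = v
        c, c_i = clustering_weighted(w)
        bc, bc_i = brute_clustering(w)
        assert np.allclose(c_i, bc_i, atol=1e-12)
        assert c == pytest.approx(bc, abs=1e-12)

    def test_matches_networkx_onnela_per_node(self):
        rng = np.random.default_rng(7)
        w = random_weighted_graph(rng, 7, p=0.6)
        _, c_i = clustering_weighted(w)
        g = nx.from_numpy_array(w)
        nx_c = nx.clustering(g, weight="weight")
        k = (w > 0).sum(axis=1)
        for i in range(7):
            if k[i] >= 2:
                assert c_i[i] == pytest.approx(nx_c[i], abs=1e-10)

    def test_all_zero_matrix_warns(self, caplog):
        with caplog.at_level(logging.WARNING):
            c, c_i = clustering_weighted(np.zeros((4, 4)))
        assert c == 0.0
        assert "all-zero" in caplog.text

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        w = random_weighted_graph(rng, 6)
        c1, _ = clustering_weighted(w)
        c2, _ = clustering_weighted(3.7 * w)
        assert c1 == pytest.approx(c2, abs=1e-12)


class TestPathLengthHarmonic:
    def test_two_node_graph(self):
        w = np.array([[0, 0.5], [0.5, 0]])
        length, d = path_length_harmonic(w)
        assert d[0, 1] == pytest.approx(2.0)
        assert length == pytest.approx(2.0)

    def test_three_node_chain(self):
        # unit weights: pair distances {1, 1, 2}, inverse mean (1+1+0.5)/3
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        length, d = path_length_harmonic(w)
        assert d[0, 2] == pytest.approx(2.0)
        assert length == pytest.approx(1.2, abs=1e-12)

    def test_isolated_node_keeps_length_finite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        length, _ = path_length_harmonic(w)
        # pairs to the isolate contribute 0 inverse distance
        assert np.isfinite(length)
        assert length == pytest.approx(3.0)  # mean inverse = (1+1+0+0+0+0)/6

    def test_single_node_errors(self):
        with pytest.raises(ValueError):
            path_length_harmonic(np.zeros((1, 1)))

    def test_scaling_weights_scales_length_inversely(self):
        rng = np.random.default_rng(2)
        w = random_weighted_graph(rng, 6)
        l1, _ = path_length_harmonic(w)
        l2, _ = path_length_harmonic(2.0 * w)
        assert l2 == pytest.approx(l1 / 2.0, rel=1e-12)

    def test_adding_edge_never_increases_length(self):
        rng = np.random.default_rng(3)
        w = random_weighted_graph(rng, 7, p=0.3)
        l1, d1 = path_length_harmonic(w)
        zeros = np.argwhere(np.triu(w == 0, k=1))
        i, j = zeros[0]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = 0.5
        l2, d2 = path_length_harmonic(w2)
        assert np.all(d2 <= d1 + 1e-12)
        assert l2 <= l1 + 1e-12

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            w = random_weighted_graph(rng, int(rng.integers(2, 9)), p=0.5)
            length, _ = path_length_harmonic(w)
            assert length == pytest.approx(brute_path_length(w), rel=1e-12)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=3, max_value=8))
def test_metric_properties_hold_on_arbitrary_graphs(seed, n):
    """Clustering is scale-invariant and bounded; path length scales as 1/c
    under weight scaling; both match the brute-force oracles."""
    rng = np.random.default_rng(seed)
    w = random_weighted_graph(rng, n, p=0.6)
    c, c_i = clustering_weighted(w)
    assert 0.0 <= c <= 1.0 + 1e-12
    assert np.all((c_i >= 0) & (c_i <= 1 + 1e-12))
    bc, _ = brute_clustering(w)
    assert c == pytest.approx(bc, abs=1e-12)
    c_scaled, _ = clustering_weighted(2.5 * w)
    assert c_scaled == pytest.approx(c, abs=1e-12)
    if w.max() > 0:
        l1, _ = path_length_harmonic(w)
        l2, _ = path_length_harmonic(2.5 * w)
        if np.isfinite(l1):
            assert l2 == pytest.approx(l1 / 2.5, rel=1e-12)


class TestRewireSurrogate:
    def test_star_graph_has_no_valid_swap(self, caplog):
        w = np.zeros((4, 4))
        for j in (1, 2, 3):
            w[0, j] = w[j, 0] = 0.5 + 0.1 * j
        with caplog.at_level(logging.WARNING):
            out = rewire_surrogate(w, n_swaps=50, seed=0)
        assert np.array_equal(out, w)
        assert "no valid" in caplog.text

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_degree_sequence_and_weight_multiset_preserved(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng, 20, p=0.3)
        out = rewire_surrogate(w, seed=seed)
        assert np.array_equal(
            np.sort((w > 0).sum(axis=1)), np.sort((out > 0).sum(axis=1))
        )
        iu = np.triu_indices(20, k=1)
        assert np.allclose(np.sort(w[iu][w[iu] > 0]), np.sort(out[iu][out[iu] > 0]))
        assert not np.array_equal(out, w)  # something actually moved
        assert np.array_equal(out, out.T)
        assert np.all(np.diag(out) == 0)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        w = random_weighted_graph(rng, 15, p=0.4)
        assert np.array_equal(rewire_surrogate(w, seed=42), rewire_surrogate(w, seed=42))

    def test_shuffle_weights_mode_keeps_topology(self):
        rng = np.random.default_rng(6)
        w = random_weighted_graph(rng, 10, p=0.4)
        out = rewire_surrogate(w, seed=1, shuffle_weights=True)
        assert np.array_equal(out > 0, w > 0)
        iu = np.triu_indices(10, k=1)
        assert np.allclose(np.sort(w[iu]), np.sort(out[iu]))


class TestNormalize:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(0)
        w = random_weighted_graph(rng, 12, p=0.5)
        a = normalize(w, n_surrogates=3, seed=9)
        b = normalize(w, n_surrogates=3, seed=9)
        assert a.gamma == b.gamma and a.lambda_ == b.lambda_
        assert np.array_equal(a.C_surr, b.C_surr)

    def test_random_graph_is_its_own_null(self):
        rng = np.random.default_rng(1)
        w = random_weighted_graph(rng, 40, p=0.25)
        s = normalize(w, n_surrogates=30, seed=0)
        c_sd = np.std(s.C_surr, ddof=1)
        l_sd = np.std(s.L_surr, ddof=1)
        assert abs(s.C - s.C_surr_mean) < 3 * c_sd + 1e-12
        assert abs(s.L - s.L_surr_mean) < 3 * l_sd + 1e-12

    def test_ring_lattice_more_regular_than_surrogates(self):
        n, k = 30, 3  # each node connected to k nearest neighbours per side
        w = np.zeros((n, n))
        for i in range(n):
            for off in range(1, k + 1):
                j = (i + off) % n
                w[i, j] = w[j, i] = 1.0 - 0.05 * off
        s = normalize(w, n_surrogates=20, seed=3)
        assert s.gamma > 1.0
        assert s.lambda_ > 1.0

    def test_summary_serialization_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        w = random_weighted_graph(rng, 10, p=0.5)
        s = normalize(w, n_surrogates=2, seed=0)
        path = tmp_path / "summary.json"
        s.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["gamma"] == pytest.approx(s.gamma)
        assert loaded["n_surrogates"] == 2
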