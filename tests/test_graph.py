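"""Graph metrics against brute-force enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_weight_matrix
from oracles import (
    oracle_clustering,
    oracle_degrees,
    oracle_path_length,
    oracle_strength,
)
from vigilnet.graph import (
    clustering_global,
    clustering_local,
    nodal_degree,
    nodal_strength,
    normalized_degree,
    path_length,
    sparsity_integral,
    threshold_absolute,
    threshold_proportional,
)


class TestThresholding:
    def test_zero_threshold_keeps_everything(self, rng):
        W = random_weight_matrix(rng, 6)
        assert np.array_equal(threshold_absolute(W, 0.0).W, W)

    def test_strict_cut_keeps_at_threshold(self):
        W = np.zeros((3, 3))
        W[0, 1], W[0, 2], W[1, 2] = 0.05, 0.2, 0.3
        g = threshold_absolute(W, 0.2)
        assert g.W[0, 1] == 0.0 and g.W[0, 2] == 0.2 and g.W[1, 2] == 0.3

    def test_proportional_edge_count_62_channels(self, rng):
        W = random_weight_matrix(rng, 62, density=1.0)
        g = threshold_proportional(W, 0.10)
        assert int(g.A.sum()) == 378  # floor(0.10 * 62 * 61)

    def test_proportional_full_sparsity_keeps_all(self, rng):
        W = random_weight_matrix(rng, 5, density=1.0)
        assert np.array_equal(threshold_proportional(W, 1.0).W, W)

    def test_tie_broken_by_index_deterministically(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 2] = 0.5  # equal weights at the cut
        W[0, 2] = 0.9
        g1 = threshold_proportional(W, 2 / 6)  # keep 2 of 6 slots
        g2 = threshold_proportional(W, 2 / 6)
        assert np.array_equal(g1.W, g2.W)
        assert g1.W[0, 2] == 0.9 and g1.W[0, 1] == 0.5 and g1.W[1, 2] == 0.0

    def test_raising_threshold_never_raises_degree_or_strength(self, rng):
        W = random_weight_matrix(rng, 10, density=0.8)
        prev_deg = None
        prev_ns = None
        for T in (0.0, 0.1, 0.15, 0.2, 0.25, 0.3):
            g = threshold_absolute(W, T)
            deg = nodal_degree(g)["d_tot"]
            ns = nodal_strength(g.W)
            if prev_deg is not None:
                assert np.all(deg <= prev_deg)
                assert np.all(ns <= prev_ns + 1e-12)
            prev_deg, prev_ns = deg, ns


class TestAgainstOracles:
    @pytest.mark.parametrize("trial", range(20))
    def test_degrees_strength_clustering_paths(self, trial):
        rng = np.random.default_rng(trial)
        m = int(rng.integers(3, 9))
        W = random_weight_matrix(rng, m, density=float(rng.uniform(0.2, 0.9)))
        g = threshold_absolute(W, 0.0)

        d = nodal_degree(g)
        o_in, o_out, o_tot = oracle_degrees(W)
        assert np.array_equal(d["d_in"], o_in)
        assert np.array_equal(d["d_out"], o_out)
        assert np.array_equal(d["d_tot"], o_tot)

        assert np.allclose(nodal_strength(W), oracle_strength(W), atol=1e-10)
        assert np.allclose(clustering_local(W), oracle_clustering(W), atol=1e-10)

        try:
            pl, unreach = path_length(W)
        except ValueError:
            with pytest.raises(ValueError):
                oracle_path_length(W)
            return
        o_pl, o_unreach = oracle_path_length(W)
        assert pl == pytest.approx(o_pl, abs=1e-10)
        assert unreach == pytest.approx(o_unreach, abs=1e-12)

    def test_degree_conservation(self, rng):
        W = random_weight_matrix(rng, 8, density=0.5)
        d = nodal_degree(threshold_absolute(W, 0.0))
        n_edges = int((W != 0).sum())
        assert d["d_in"].sum() == d["d_out"].sum() == n_edges

    def test_strength_double_counting_identity(self, rng):
        W = random_weight_matrix(rng, 7)
        assert nodal_strength(W).sum() == pytest.approx(2 * W.sum())


class TestClustering:
    def test_no_triangles_gives_zero(self):
        W = np.zeros((4, 4))
        W[1, 0] = W[2, 1] = 0.5  # chain 0 -> 1 -> 2
        assert np.allclose(clustering_local(W), 0.0)

    def test_fully_connected_triangle_closed_form(self):
        w = 0.7
        W = np.full((3, 3), w)
        np.fill_diagonal(W, 0.0)
        C = clustering_local(W)
        # all pairs reciprocal: d_tot = 4, d_bi = 2 per node;
        # numerator (2 w^{1/3})^3 * 2 ordered triangles
        expect = 2 * (2 * w ** (1 / 3)) ** 3 / (2 * (4 * 3 - 2 * 2))
        assert np.allclose(C, expect)
        assert np.allclose(C, oracle_clustering(W))

    def test_global_is_mean_of_local(self, rng):
        W = random_weight_matrix(rng, 6)
        C = clustering_local(W)
        assert clustering_global(C) == pytest.approx(C.mean())
        assert clustering_global(np.array([0.0, 1.0])) == 0.5

    def test_negative_weights_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = -0.5
        with pytest.raises(ValueError, match="nonnegative"):
            clustering_local(W)


class TestPathLength:
    def test_reciprocal_two_node(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        pl, unreach = path_length(W)
        assert pl == pytest.approx(2.0)
        assert unreach == 0.0

    def test_chain_with_unreachable_pairs(self):
        # chain 1 -> 2 -> 3 with unit weights, row = receiver
        W = np.zeros((3, 3))
        W[1, 0] = 1.0
        W[2, 1] = 1.0
        pl, unreach = path_length(W)
        assert pl == pytest.approx((1 + 1 + 2) / 3)
        assert unreach == pytest.approx(3 / 6)

    def test_fully_disconnected_raises(self):
        with pytest.raises(ValueError, match="connected"):
            path_length(np.zeros((3, 3)))


class TestScalingHomogeneity:
    @settings(derandomize=True, max_examples=20)
    @given(
        c=st.floats(min_value=0.1, max_value=0.9),
        seed=st.integers(min_value=0, max_value=500),
    )
    def test_uniform_weight_scaling(self, c, seed):
        rng = np.random.default_rng(seed)
        W = random_weight_matrix(rng, 6, density=0.7)
        d0 = nodal_degree(threshold_absolute(W, 0.0))["d_tot"]
        d1 = nodal_degree(threshold_absolute(c * W, 0.0))["d_tot"]
        assert np.array_equal(d0, d1)
        assert np.allclose(nodal_strength(c * W), c * nodal_strength(W))
        assert np.allclose(clustering_local(c * W), c * clustering_local(W))
        try:
            pl0, _ = path_length(W)
        except ValueError:
            return
        pl1, _ = path_length(c * W)
        assert pl1 == pytest.approx(pl0 / c)


class TestIntegralAndNormalizedDegree:
    def test_constant_metric_rectangle(self):
        grid = (0.10, 0.15, 0.20, 0.25, 0.30)
        assert sparsity_integral([3.0] * 5, grid) == pytest.approx(0.2 * 3.0)

    def test_linear_metric_exact(self):
        grid = np.array([0.10, 0.15, 0.20, 0.25, 0.30])
        vals = 2.0 * grid + 1.0
        exact = (vals[0] + vals[-1]) / 2 * 0.2
        assert sparsity_integral(vals, grid) == pytest.approx(exact)

    def test_default_grid_has_five_points(self):
        from vigilnet.graph import DEFAULT_SPARSITIES
        assert len(DEFAULT_SPARSITIES) == 5
        assert DEFAULT_SPARSITIES[0] == 0.10 and DEFAULT_SPARSITIES[-1] == 0.30

    def test_normalized_degree_bounds(self):
        assert normalized_degree(0, 62) == 0.0
        assert normalized_degree(2 * 61, 62) == 1.0
        assert normalized_degree(61, 62) == pytest.approx(0.5)
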