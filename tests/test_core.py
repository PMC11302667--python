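import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rdistance as rd
from rdistance.core import MASK_CLAMPED, MASK_UNREACHABLE
from rdistance.errors import BeyondCriticalGainError

from _oracles import brute_force_walk_counts, p3_resolvent_closed_form
from conftest import small_random_graphs


class TestResolvent:
    @pytest.mark.parametrize("gamma", [0.05, 0.1, 0.2, 0.4, 0.6])
    def test_p3_matches_closed_form(self, p3, gamma):
        y, valid = rd.resolvent(p3, gamma)
        assert valid
        np.testing.assert_allclose(y, p3_resolvent_closed_form(gamma), rtol=1e-12)

    def test_p3_printed_entry(self, p3):
        y, _ = rd.resolvent(p3, 0.1)
        assert y[1, 0] == pytest.approx(0.1 / 0.98, rel=1e-12)

    def test_edgeless_graph_gives_identity(self):
        g = rd.Graph(np.full((4, 4), np.inf))
        y, _ = rd.resolvent(g, 0.3)
        np.testing.assert_array_equal(y, np.eye(4))

    def test_single_node(self):
        g = rd.Graph(np.full((1, 1), np.inf))
        y, _ = rd.resolvent(g, 0.5)
        np.testing.assert_array_equal(y, [[1.0]])

    def test_gamma_outside_unit_interval_rejected(self, p3):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                rd.resolvent(p3, bad)

    def test_beyond_critical_gain_raises(self, p3):
        with pytest.raises(BeyondCriticalGainError):
            rd.resolvent(p3, 0.8)  # gamma_c(P3) = 1/sqrt(2) ~ 0.707

    def test_directed_cycle_at_high_gain_still_converges(self):
        # permutation adjacency has rho = 1, so any gamma < 1 is valid
        g = rd.cycle_graph(8, directed=True)
        y, valid = rd.resolvent(g, 0.97)
        assert valid and np.all(y >= 0)


class TestRDistance:
    def test_p3_rounds_to_bfs_distances(self, p3, p3_oracle):
        res = rd.rdistance(p3, 0.1)  # below the sufficient bound 1/4
        np.testing.assert_array_equal(res.rounded, p3_oracle.D)

    def test_diagonal_rounds_to_zero(self):
        for g in small_random_graphs(6):
            res = rd.rdistance(g, 0.1 / max(g.out_degrees().max(), 1))
            assert np.all(np.diag(res.rounded) == 0)
            assert np.all(np.diag(res.Y) >= 1.0)
            assert np.all(np.diag(res.R) <= 0.0)

    def test_unreachable_pair_is_exact_infinity(self):
        g = rd.Graph.from_edges(2, [(0, 1)], directed=True)
        res = rd.rdistance(g, 0.3)
        assert res.Y[0, 1] == 0.0
        assert np.isinf(res.rounded[0, 1]) and res.rounded[1, 0] == 1
        assert res.mask[0, 1] == MASK_UNREACHABLE

    def test_monotone_map_min_r_equals_max_y(self):
        # log base < 1 reverses order: smallest R is largest Y
        for g in small_random_graphs(8):
            res = rd.rdistance(g, 0.4 / max(g.out_degrees().max(), 1))
            for row in range(g.n):
                finite = res.Y[row] > 0
                if finite.sum() < 2:
                    continue
                assert np.argmin(res.R[row][finite]) == np.argmax(res.Y[row][finite])

    @given(st.floats(1e-12, 1 - 1e-12), st.floats(1e-12, 1 - 1e-12))
    @settings(max_examples=50, deadline=None)
    def test_r_strictly_decreasing_in_y(self, y1, y2):
        gamma = 0.3
        r1, r2 = np.log(y1) / np.log(gamma), np.log(y2) / np.log(gamma)
        if y1 < y2:
            assert r1 > r2
        elif y1 > y2:
            assert r1 < r2

    def test_asymptotic_limit_small_gain(self):
        # max |R - D| over reachable pairs shrinks as gamma -> 0; with
        # redundant shortest paths the residual is ln(S)/|ln gamma|, so the
        # decay is logarithmic on dense graphs and fast on trees (S = 1)
        g = rd.dense_random(12, 0.4, seed=31)
        o = rd.oracle_apsp(g)
        reach = np.isfinite(o.D)
        errs = []
        for gamma in (1e-2, 1e-4, 1e-6):
            res = rd.rdistance(g, gamma)
            errs.append(np.max(np.abs(res.R[reach] - o.D[reach])))
        assert errs[0] > errs[1] > errs[2]
        p = rd.path_graph(6)
        op = rd.oracle_apsp(p)
        res = rd.rdistance(p, 1e-6)
        assert np.max(np.abs(res.R[np.isfinite(op.D)] - op.D[np.isfinite(op.D)])) < 1e-5

    def test_weighted_all_ones_bitwise_identical_to_unweighted(self):
        g = rd.dense_random(15, 0.5, directed=True, seed=8)
        res_unw = rd.rdistance(g, 0.05)
        # same topology, explicitly built through the weighted code path
        gw = rd.Graph(np.where(np.isfinite(g.weights), 1.0, np.inf), directed=True)
        res_w = rd.rdistance(gw, 0.05)
        assert np.array_equal(res_unw.Y, res_w.Y)

    def test_two_node_weighted_edge_r_equals_weight(self):
        g = rd.Graph.from_edges(2, [(0, 1, 7.25)], directed=True)
        res = rd.rdistance(g, 0.01)
        assert res.R[1, 0] == pytest.approx(7.25, rel=1e-12)

    def test_highprec_extends_dynamic_range(self):
        # a path long enough that gamma**d underflows double precision
        g = rd.path_graph(40)
        o = rd.oracle_apsp(g)
        gamma = 1e-9  # gamma**39 = 1e-351 < subnormal floor
        res64 = rd.rdistance(g, gamma)
        assert rd.global_correctness(res64, o) < 1.0
        res_mp = rd.rdistance_highprec(g, gamma, dps=500)
        np.testing.assert_array_equal(res_mp.rounded, o.D)


class TestPowerSeries:
    def test_first_orders_are_identity_and_adjacency(self, p3):
        series = rd.power_series_oracle(p3, 0.1, kmax=2)
        np.testing.assert_array_equal(series.counts[0].astype(int), np.eye(3, dtype=int))
        np.testing.assert_array_equal(series.counts[1].astype(float), p3.adjacency)
        assert series.counts[2][0, 2] == 1  # the walk 3 -> 2 -> 1

    def test_walk_counts_match_exhaustive_enumeration(self):
        for g in small_random_graphs(6, n_max=6):
            series = rd.power_series_oracle(g, 0.2 / max(g.out_degrees().max(), 1), kmax=5)
            ref = brute_force_walk_counts(g.weights, 5)
            for k in range(6):
                assert np.array_equal(series.counts[k], ref[k])

    def test_walk_count_degree_bound(self):
        for g in small_random_graphs(6):
            delta = max(int(g.out_degrees().max()), 1)
            series = rd.power_series_oracle(g, 0.1, kmax=6)
            for k in range(1, 7):
                # per-pair k-walk count is capped by the (k-1)-walk fan-out
                assert int(np.max(series.counts[k])) <= delta ** (k - 1)

    def test_partial_sum_converges_to_resolvent(self):
        g = rd.dense_random(20, 0.3, directed=True, seed=17)
        delta = int(g.out_degrees().max())
        gamma = 0.5 / delta
        series = rd.power_series_oracle(g, gamma, kmax=60)
        y, _ = rd.resolvent(g, gamma)
        assert np.max(np.abs(series.partial_sum - y)) < 1e-12

    def test_weighted_partial_sum_within_tail_bound(self):
        g = rd.with_log_uniform_weights(rd.dense_random(10, 0.5, directed=True, seed=3), 1, 5, seed=4)
        gamma = 0.05
        series = rd.power_series_oracle(g, gamma, kmax=40)
        y, _ = rd.resolvent(g, gamma)
        assert np.max(np.abs(series.partial_sum - y)) <= series.tail_bound + 1e-12


class TestDiscretization:
    def test_exact_multiples(self):
        g = rd.Graph.from_edges(3, [(0, 1, 1.0), (1, 2, 2.5)], directed=True)
        h = rd.discretize_weights(g, 0.5)
        assert h.weights[1, 0] == 2 and h.weights[2, 1] == 5
        assert h.meta["delta_w"] == 0.5

    def test_integer_weights_identity_under_unit_increment(self):
        g = rd.Graph.from_edges(3, [(0, 1, 3.0), (1, 2, 7.0)], directed=True)
        h = rd.discretize_weights(g, 1.0)
        assert np.array_equal(h.weights, g.weights)

    def test_too_coarse_increment_rejected(self):
        g = rd.Graph.from_edges(2, [(0, 1, 0.2)], directed=True)
        with pytest.raises(ValueError, match="rounds to 0"):
            rd.discretize_weights(g, 1.0)

    def test_discretized_distances_within_per_edge_error(self):
        # rescaled distances deviate by at most delta_w/2 per edge on a path
        g = rd.with_log_uniform_weights(rd.dense_random(20, 0.5, directed=True, seed=55), 1, 100, seed=56)
        o_exact = rd.oracle_apsp(g)
        dw = 0.01
        h = rd.discretize_weights(g, dw)
        o_disc = rd.oracle_apsp(h)
        reach = np.isfinite(o_exact.D)
        # any shortest path here has < n edges
        bound = dw / 2 * g.n
        assert np.max(np.abs(o_disc.D[reach] * dw - o_exact.D[reach])) <= bound
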