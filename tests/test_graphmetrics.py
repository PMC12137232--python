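import numpy as np
import pytest

from gsrpipe.connectivity import FCMatrix
from gsrpipe.graphmetrics import (WeightedGraph, cost_threshold,
                                  shortest_paths, char_path_length,
                                  weighted_clustering, local_efficiency,
                                  global_efficiency, random_ensemble,
                                  normalized_metrics, feasible_cost_range,
                                  metrics_over_costs, compute_metrics,
                                  disconnected_fraction)

from oracles import (random_weighted_graph, floyd_warshall_lengths,
                     char_path_length_brute, clustering_brute,
                     local_efficiency_brute, global_efficiency_brute)


def _graph(w, cost=0.5):
    return WeightedGraph(w=np.asarray(w, dtype=float), cost=cost)


def _fc_from(values):
    v = np.asarray(values, dtype=float)
    np.fill_diagonal(v, 0.0)
    return FCMatrix(values=v, labels=[f"n{i}" for i in range(v.shape[0])],
                    level="roi114")


def _random_fc(rng, n):
    a = rng.uniform(-1, 1, (n, n))
    v = np.clip((a + a.T) / 2, -0.99, 0.99)
    np.fill_diagonal(v, 0.0)
    return _fc_from(v)


def complete_graph(n, w=1.0):
    a = np.full((n, n), w)
    np.fill_diagonal(a, 0.0)
    return _graph(a, cost=1.0)


def star_graph(n):
    a = np.zeros((n, n))
    a[0, 1:] = 1.0
    a[1:, 0] = 1.0
    return _graph(a)


def path3_graph():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 1.0
    a[1, 2] = a[2, 1] = 1.0
    return _graph(a)


class TestCostThreshold:
    def test_edge_count_formula(self):
        rng = np.random.default_rng(0)
        fc = _random_fc(rng, 17)
        g = cost_threshold(fc, 0.25)
        assert g.n_edges == round(0.25 * 17 * 16 / 2) == 34

    def test_cost_one_on_positive_matrix_is_complete(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.1, 0.9, (10, 10))
        fc = _fc_from((a + a.T) / 2)
        g = cost_threshold(fc, 1.0)
        assert g.n_edges == 45

    def test_matches_sort_and_take_oracle(self):
        rng = np.random.default_rng(2)
        fc = _random_fc(rng, 20)
        cost = 0.3
        g = cost_threshold(fc, cost)
        m = round(cost * 20 * 19 / 2)
        iu, ju = np.triu_indices(20, 1)
        vals = sorted(fc.values[iu, ju], reverse=True)[:m]
        kept = np.sort(g.w[np.triu_indices(20, 1)])
        kept = kept[kept > 0]
        np.testing.assert_allclose(np.sort(vals), kept, atol=1e-12)

    def test_infeasible_cost_signalled(self):
        v = -0.5 * np.ones((6, 6))
        np.fill_diagonal(v, 0.0)
        with pytest.raises(ValueError, match="infeasible"):
            cost_threshold(_fc_from(v), 0.5)

    def test_edge_counts_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            fc = _fc_from(np.abs(
                (lambda a: (a + a.T) / 2)(rng.uniform(0, 1, (n, n)))))
            cost = float(rng.uniform(0.05, 0.6))
            g = cost_threshold(fc, cost)
            assert g.n_edges == round(cost * n * (n - 1) / 2)


class TestShortestPaths:
    def test_unit_path_distance(self):
        d = shortest_paths(path3_graph())
        assert d[0, 2] == pytest.approx(2.0)

    def test_detour_beats_weak_edge(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.1
        a[0, 2] = a[2, 0] = 1.0
        a[2, 1] = a[1, 2] = 1.0
        d = shortest_paths(_graph(a))
        assert d[0, 1] == pytest.approx(2.0)   # 1/1 + 1/1 beats 1/0.1

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(4)
        w = random_weighted_graph(rng, 20, density=0.3)
        d = shortest_paths(_graph(w))
        expected = floyd_warshall_lengths(w)
        np.testing.assert_allclose(d, expected, atol=1e-12)


class TestClosedFormCases:
    def test_complete_graph_metrics(self):
        g = complete_graph(6)
        d = shortest_paths(g)
        L, _, frac = char_path_length(d)
        assert L == pytest.approx(1.0)
        assert frac == 0.0
        C, per_c = weighted_clustering(g)
        assert C == pytest.approx(1.0)
        e_glob, _ = global_efficiency(d)
        assert e_glob == pytest.approx(1.0)
        e_loc, per_e = local_efficiency(g)
        assert e_loc == pytest.approx(1.0)
        np.testing.assert_allclose(per_e, 1.0)

    def test_star_graph_metrics(self):
        g = star_graph(6)
        C, _ = weighted_clustering(g)
        assert C == 0.0
        e_loc, per = local_efficiency(g)
        assert e_loc == 0.0
        np.testing.assert_array_equal(per, 0.0)

    def test_path3_closed_forms(self):
        g = path3_graph()
        d = shortest_paths(g)
        L, _, _ = char_path_length(d)
        assert L == pytest.approx(4.0 / 3.0)
        e_glob, _ = global_efficiency(d)
        assert e_glob == pytest.approx(5.0 / 6.0)

    def test_fully_disconnected_efficiency(self):
        d = shortest_paths(_graph(np.zeros((5, 5))))
        e_glob, _ = global_efficiency(d)
        assert e_glob == 0.0

    def test_isolated_node_excluded_and_flagged(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[1, 2] = a[2, 1] = 1.0
        d = shortest_paths(_graph(a))
        L, per, frac = char_path_length(d)
        assert np.isnan(per[3])
        assert np.isfinite(L)
        assert frac > 0


class TestOracleEquivalence:
    """Every metric vs independent brute-force enumeration, 50 graphs."""

    def test_metric_suite_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for rep in range(50):
            n = int(rng.integers(6, 16))
            w = random_weighted_graph(rng, n, density=float(rng.uniform(0.2, 0.7)))
            if (w > 0).sum() == 0:
                continue
            g = _graph(w)
            d = shortest_paths(g)
            d_brute = floyd_warshall_lengths(w)
            np.testing.assert_allclose(d, d_brute, atol=1e-12)
            L, _, _ = char_path_length(d)
            assert L == pytest.approx(char_path_length_brute(d_brute),
                                      abs=1e-12)
            _, per_c = weighted_clustering(g)
            np.testing.assert_allclose(per_c, clustering_brute(w), atol=1e-12)
            _, per_e = local_efficiency(g)
            np.testing.assert_allclose(per_e, local_efficiency_brute(w),
                                       atol=1e-12)
            e_glob, _ = global_efficiency(d)
            assert e_glob == pytest.approx(global_efficiency_brute(d_brute),
                                           abs=1e-12)


class TestRandomEnsemble:
    def test_degree_and_edge_conservation(self):
        rng = np.random.default_rng(6)
        w = random_weighted_graph(rng, 30, density=0.2)
        g = _graph(w)
        from gsrpipe.graphmetrics import _rewire
        weights_orig = np.sort(w[np.triu_indices(30, 1)])
        for _ in range(100):
            adj = _rewire(g, rng, swaps_per_edge=5)
            assert adj is not None
            np.testing.assert_array_equal((adj > 0).sum(axis=1), g.degrees)
            assert (adj > 0).sum() // 2 == g.n_edges
            # weights travel with edges: the multiset is conserved
            np.testing.assert_allclose(
                np.sort(adj[np.triu_indices(30, 1)]), weights_orig, atol=0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        w = random_weighted_graph(rng, 20, density=0.3)
        g = _graph(w)
        a = random_ensemble(g, 5, np.random.default_rng(1), swaps_per_edge=3)
        b = random_ensemble(g, 5, np.random.default_rng(1), swaps_per_edge=3)
        assert a == b

    def test_clique_falls_back_with_flag(self):
        g = complete_graph(5)
        l_rand, c_rand, degenerate = random_ensemble(
            g, 3, np.random.default_rng(0))
        assert degenerate
        d = shortest_paths(g)
        L, _, _ = char_path_length(d)
        assert l_rand == pytest.approx(L)

    def test_self_null_gives_unit_ratios(self):
        g = complete_graph(5)
        d = shortest_paths(g)
        L, _, _ = char_path_length(d)
        C, _ = weighted_clustering(g)
        lam, gamma, sw = normalized_metrics(L, C, L, C)
        assert lam == gamma == sw == 1.0


class TestFeasibleCosts:
    def test_mean_degree_bound_closed_form(self):
        # the mean-degree criterion at n=114: cost*(n-1) > ln(114),
        # i.e. cost above ln(114)/113 ~ 0.0419
        n = 114
        bound = np.log(n) / (n - 1)
        assert bound == pytest.approx(0.0419, abs=2e-4)
        below = round(0.95 * bound * n * (n - 1) / 2)
        above = round(1.05 * bound * n * (n - 1) / 2)
        assert 2 * below / n <= np.log(n) < 2 * above / n

    def test_grid_step_count(self):
        grid = np.arange(0.005, 1.0 + 0.0025, 0.005)
        assert len(grid) == 200

    def test_dense_positive_cohort_has_nonempty_range(self, small_rng):
        mats = []
        for _ in range(4):
            shared = small_rng.standard_normal((120, 1))
            ts = shared + 0.7 * small_rng.standard_normal((120, 30))
            v = np.corrcoef(ts, rowvar=False)
            np.fill_diagonal(v, 0.0)
            mats.append(_fc_from(v))
        rng_scan = np.random.default_rng(0)
        rang = feasible_cost_range(mats, step=0.05, n_rand=5, rng=rng_scan,
                                   swaps_per_edge=3, max_cost=0.6)
        assert rang is not None
        lo, hi = rang
        assert 0 < lo <= hi <= 0.6


class TestMetricsOverCosts:
    def test_single_cost_equals_direct_metrics(self, small_rng):
        fc = _random_fc(small_rng, 25)
        res_a = metrics_over_costs(fc, [0.3], n_rand=4,
                                   rng=np.random.default_rng(2),
                                   swaps_per_edge=3)
        res_b = compute_metrics(cost_threshold(fc, 0.3), n_rand=4,
                                rng=np.random.default_rng(2),
                                swaps_per_edge=3)
        assert res_a.L == pytest.approx(res_b.L)
        assert res_a.sw == pytest.approx(res_b.sw)

    def test_grid_average_is_mean_of_singles(self, small_rng):
        fc = _fc_from(np.abs(_random_fc(small_rng, 20).values))
        kw = dict(n_rand=3, swaps_per_edge=3)
        r1 = metrics_over_costs(fc, [0.2], rng=np.random.default_rng(3), **kw)
        r2 = metrics_over_costs(fc, [0.4], rng=np.random.default_rng(4), **kw)
        # deterministic sub-streams: rebuild with a fresh rng pair
        both = metrics_over_costs(fc, [0.2, 0.4],
                                  rng=np.random.default_rng(3), **kw)
        # L, C, e_glob, e_loc do not involve the null ensemble
        assert both.L == pytest.approx((r1.L + r2.L) / 2)
        assert both.C == pytest.approx((r1.C + r2.C) / 2)
        assert both.e_glob == pytest.approx((r1.e_glob + r2.e_glob) / 2)
        assert both.e_loc == pytest.approx((r1.e_loc + r2.e_loc) / 2)

    def test_sparser_graphs_never_shorten_paths(self, small_rng):
        """Monotonicity: decreasing cost cannot decrease L."""
        fc = _fc_from(np.abs(_random_fc(small_rng, 30).values))
        d_prev = None
        for cost in (0.5, 0.4, 0.3, 0.2):   # dense -> sparse
            d = shortest_paths(cost_threshold(fc, cost))
            if d_prev is not None:
                # removing edges can only lengthen (or disconnect) pairs
                assert np.all(d >= d_prev - 1e-12)
            d_prev = d


def test_disconnected_fraction():
    a = np.zeros((5, 5))
    a[0, 1] = a[1, 0] = 1.0
    a[1, 2] = a[2, 1] = 1.0
    assert disconnected_fraction(_graph(a)) == pytest.approx(2 / 5)
    assert disconnected_fraction(complete_graph(4)) == 0.0
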