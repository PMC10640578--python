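import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from burstnet import (IntervalSample, aggregate_and_strengths,
                      burstiness_and_memory, construct_static,
                      extract_intervals, fit_discrete_exponential,
                      fit_discrete_power_law, make_distribution,
                      normalized_strength_survival, pooled)
from burstnet.analysis import _gaps_from_series, intervals_from_contacts
from burstnet.construction import SpanningTree, TemporalNetwork
from burstnet.distributions import default_support
from burstnet.errors import EstimationError, ParameterError
from burstnet.io import ContactEvent
from burstnet.topologies import generate_fixture_topology


def toy_network(states, graph=None):
    """TemporalNetwork from an explicit (T+1, N) state table."""
    states = np.asarray(states, dtype=bool)
    n = states.shape[1]
    if graph is None:
        graph = nx.path_graph(n)
    parent = {0: None, **{i: i - 1 for i in range(1, n)}}
    tree = SpanningTree(roots=[0], parent=parent,
                        layers=[[i] for i in range(n)],
                        trunks={(i, i + 1) for i in range(n - 1)},
                        branches={tuple(sorted(e)) for e in graph.edges()}
                        - {(i, i + 1) for i in range(n - 1)})
    return TemporalNetwork(graph=graph, tree=tree,
                           t_tol=states.shape[0] - 1,
                           columns={i: i for i in range(n)},
                           node_states=states,
                           birth=np.zeros(n, dtype=np.int64))


class TestExtractIntervals:
    def test_gap_definition(self):
        assert _gaps_from_series(np.array([1, 0, 0, 1, 1],
                                          dtype=bool)).tolist() == [3, 1]

    def test_single_edge_ict_equals_link_iet(self, rng):
        L = default_support(500)
        F = make_distribution("power_law", 2.0, L)
        H = make_distribution("power_law", 1.9, L)
        net = construct_static(nx.path_graph(2), F, H, 500, seed=rng)
        ict = extract_intervals(net, "node_ict")
        liet = extract_intervals(net, "link_iet")
        assert ict[0].gaps.tolist() == liet[0].gaps.tolist()
        assert ict[1].gaps.tolist() == liet[0].gaps.tolist()

    def test_pooling_identity(self, rng):
        L = default_support(300)
        F = make_distribution("power_law", 2.0, L)
        H = make_distribution("power_law", 1.9, L)
        g = generate_fixture_topology("ws", {"n": 20, "k": 4, "p": 0.3}, rng)
        net = construct_static(g, F, H, 300, seed=rng)
        per_unit = extract_intervals(net, "node_iet", scope="per_unit")
        agg = extract_intervals(net, "node_iet", scope="aggregated")
        assert sorted(agg.gaps.tolist()) == sorted(
            int(x) for s in per_unit for x in s.gaps)

    def test_unit_without_two_activations_contributes_nothing(self):
        states = np.array([[1, 1], [0, 0], [0, 0]])
        net = toy_network(states)
        samples = extract_intervals(net, "node_iet")
        assert all(len(s.gaps) == 0 for s in samples)

    def test_too_short_network(self):
        net = toy_network(np.array([[1, 1]]))
        with pytest.raises(ParameterError):
            extract_intervals(net, "node_iet")

    def test_bad_mode(self, rng):
        net = toy_network(np.array([[1, 1], [1, 1]]))
        with pytest.raises(ParameterError):
            extract_intervals(net, "node_frequency")

    @pytest.mark.slow
    def test_ict_converges_to_iet_with_degree(self):
        """Median KS(ICT, IET) decreases with degree on regular graphs."""
        L = default_support(1500)
        F = make_distribution("power_law", 2.0, L)
        H = make_distribution("power_law", 1.9, L)
        med = {}
        for k in (2, 8, 32):
            dists = []
            for s in range(12):
                g = nx.random_regular_graph(k, 60, seed=s)
                net = construct_static(
                    g, F, H, 1500, seed=np.random.default_rng(1000 + s))
                iet = extract_intervals(net, "node_iet", scope="aggregated")
                ict = extract_intervals(net, "node_ict", scope="aggregated")
                dists.append(stats.ks_2samp(iet.gaps, ict.gaps).statistic)
            med[k] = np.median(dists)
        assert med[2] > med[8] > med[32]


class TestPowerLawFit:
    def test_parameter_recovery(self, rng):
        d = make_distribution("power_law", 2.5, 10 ** 5)
        gaps = d.sample(10 ** 5, rng)
        fit = fit_discrete_power_law(IntervalSample("u", "node_iet", gaps))
        assert fit.exponent_hat == pytest.approx(2.5, abs=0.05)
        assert abs(fit.exponent_hat - 2.5) < 4 * fit.se
        assert fit.ks_distance < 0.01

    def test_window_corrected_recovery(self, rng):
        """Gaps censored by a finite window are recovered without bias by
        the completed-interval likelihood."""
        T = 5000
        d = make_distribution("power_law", 2.0, default_support(T))
        all_gaps = []
        for _ in range(400):
            draws = d.sample(3000, rng)
            all_gaps.append(draws[np.cumsum(draws) <= T])
        gaps = np.concatenate(all_gaps)
        plain = fit_discrete_power_law(gaps).exponent_hat
        corrected = fit_discrete_power_law(gaps, window=T).exponent_hat
        assert abs(corrected - 2.0) < abs(plain - 2.0)
        assert corrected == pytest.approx(2.0, abs=0.01)

    def test_per_gap_window_recovery(self, rng):
        """Units observed for different durations: the heterogeneous
        completed-interval likelihood still recovers the exponent."""
        d = make_distribution("power_law", 2.0, default_support(2000))
        gaps, wins = [], []
        for T in (300, 800, 2000):
            for _ in range(150):
                draws = d.sample(2500, rng)
                kept = draws[np.cumsum(draws) <= T]
                gaps.append(kept)
                wins.append(np.full(len(kept), T))
        gaps, wins = np.concatenate(gaps), np.concatenate(wins)
        plain = fit_discrete_power_law(gaps).exponent_hat
        fit = fit_discrete_power_law(gaps, window=wins)
        assert abs(fit.exponent_hat - 2.0) < abs(plain - 2.0)
        assert fit.exponent_hat == pytest.approx(2.0, abs=0.02)
        assert np.isfinite(fit.ks_distance)

    def test_degenerate_sample(self):
        with pytest.raises(EstimationError):
            fit_discrete_power_law(np.full(100, 7))

    def test_too_few_samples(self):
        with pytest.raises(EstimationError):
            fit_discrete_power_law(np.array([1, 2, 3]))

    def test_xmin_scan_runs(self, rng):
        d = make_distribution("power_law", 2.2, 1000)
        gaps = d.sample(5000, rng)
        fit = fit_discrete_power_law(gaps, scan_xmin=True)
        assert fit.exponent_hat == pytest.approx(2.2, abs=0.2)


class TestExponentialFit:
    def test_parameter_recovery(self, rng):
        d = make_distribution("discrete_exponential", 2.0, 200)
        gaps = d.sample(10 ** 5, rng)
        fit = fit_discrete_exponential(gaps)
        assert fit.exponent_hat == pytest.approx(2.0, abs=0.02)
        assert abs(fit.exponent_hat - 2.0) < 4 * fit.se

    def test_boundary_all_ones(self):
        fit = fit_discrete_exponential(np.ones(100, dtype=int))
        assert fit.boundary
        assert math.isinf(fit.exponent_hat)

    def test_too_few(self):
        with pytest.raises(EstimationError):
            fit_discrete_exponential(np.array([1, 2]))


class TestBurstiness:
    def test_constant_gaps_give_minus_one(self):
        s = burstiness_and_memory(np.array([5, 5, 5, 5]))
        assert s.B == pytest.approx(-1.0)

    def test_bursty_positive_poisson_negative(self, rng):
        L = default_support(3000)
        bF = make_distribution("power_law", 1.8, L)
        bH = make_distribution("power_law", 1.3, L)
        pF = make_distribution("discrete_exponential", 2.5, L)
        pH = make_distribution("discrete_exponential", 2.0, L)
        g = nx.path_graph(10)
        net_b = construct_static(g, bF, bH, 3000, seed=rng)
        net_p = construct_static(g, pF, pH, 3000, seed=rng)
        B_b = burstiness_and_memory(
            extract_intervals(net_b, "node_iet", scope="aggregated").gaps).B
        B_p = burstiness_and_memory(
            extract_intervals(net_p, "node_iet", scope="aggregated").gaps).B
        assert B_b > 0
        assert B_p < 0

    def test_memoryless_autocorrelation(self, rng):
        # iid geometric activations => binary series is iid Bernoulli
        series = rng.random(20000) < 0.4
        gaps = np.diff(np.flatnonzero(series))
        s = burstiness_and_memory(gaps, activity_series=series, max_lag=5)
        assert s.autocorrelation[0] == 1.0
        for lag in range(1, 6):
            assert abs(s.autocorrelation[lag]) < 0.03

    def test_needs_two_gaps(self):
        with pytest.raises(ParameterError):
            burstiness_and_memory(np.array([3]))


class TestAggregation:
    def test_toy_counting(self):
        states = np.array([
            [1, 1],   # t=0 (excluded from aggregation)
            [1, 1],   # t=1 active
            [1, 0],
            [1, 1],   # t=3 active
        ])
        net = toy_network(states)
        agg = aggregate_and_strengths(net, t_agg=3)
        assert agg.edge_weights[(0, 1)] == 2

    def test_handshake_identity(self, rng):
        L = default_support(200)
        F = make_distribution("power_law", 2.0, L)
        H = make_distribution("power_law", 1.9, L)
        g = generate_fixture_topology("ws", {"n": 24, "k": 4, "p": 0.2}, rng)
        net = construct_static(g, F, H, 200, seed=rng)
        agg = aggregate_and_strengths(net, t_agg=150)
        assert sum(agg.node_strengths.values()) == \
            2 * sum(agg.edge_weights.values())

    def test_conservation_against_active_edge_count(self, rng):
        L = default_support(100)
        F = make_distribution("power_law", 2.0, L)
        H = make_distribution("power_law", 1.9, L)
        net = construct_static(nx.complete_graph(8), F, H, 100, seed=rng)
        agg = aggregate_and_strengths(net, t_agg=100)
        total = sum(len(net.active_edges(t)) for t in range(1, 101))
        assert sum(agg.edge_weights.values()) == total

    def test_parameter_validation(self, rng):
        net = toy_network(np.array([[1, 1], [1, 1], [1, 1]]))
        with pytest.raises(ParameterError):
            aggregate_and_strengths(net, t_agg=1, t_base=2)
        with pytest.raises(ParameterError):
            aggregate_and_strengths(net, t_agg=99)

    @pytest.mark.slow
    def test_ws_normalized_collapse(self):
        """Fig. 5c: normalized strength survival curves collapse onto the
        t_base baseline for t_agg in {2, 4} x t_base.

        Uses the Poisson-like target pair: its gap law has a finite mean,
        so activation counts scale linearly in time (the premise of the
        t_base/t_agg normalization); the alpha=2.0 bursty pair has a
        log-divergent mean gap and only collapses asymptotically.
        """
        t_base = 6000
        L = default_support(4 * t_base)
        F = make_distribution("discrete_exponential", 2.5, L)
        H = make_distribution("discrete_exponential", 2.0, L)
        g = generate_fixture_topology("ws", {"n": 300, "k": 6, "p": 0.3}, 2)
        net = construct_static(g, F, H, 4 * t_base,
                               seed=np.random.default_rng(3))
        curves = {}
        for t_agg in (t_base, 2 * t_base, 4 * t_base):
            agg = aggregate_and_strengths(net, t_agg=t_agg, t_base=t_base)
            curves[t_agg] = normalized_strength_survival(agg)

        def sup_distance(c1, c2):
            grid = np.unique(np.concatenate([c1[0], c2[0]]))
            s1 = np.interp(grid, c1[0], c1[1])
            s2 = np.interp(grid, c2[0], c2[1])
            return np.max(np.abs(s1 - s2))

        for t_agg in (2 * t_base, 4 * t_base):
            assert sup_distance(curves[t_base], curves[t_agg]) < 0.05

    @pytest.mark.slow
    def test_ba_strength_slope_matches_degree_slope(self):
        """Fig. 5b: on a scale-free topology the strength survival slope
        equals the degree survival slope, independent of t_agg."""
        t_tol = 2000
        L = default_support(t_tol)
        F = make_distribution("power_law", 2.0, L)
        H = make_distribution("power_law", 1.9, L)
        g = generate_fixture_topology("ba", {"n": 600, "m": 3}, 4)
        net = construct_static(g, F, H, t_tol, seed=np.random.default_rng(5))
        deg = np.array([d for _, d in g.degree()])
        ks = np.arange(3, int(np.quantile(deg, 0.95)))
        dslope = np.polyfit(np.log(ks),
                            np.log([(deg > k).mean() for k in ks]), 1)[0]
        for t_agg in (1000, 2000):
            agg = aggregate_and_strengths(net, t_agg=t_agg)
            s = np.array(list(agg.node_strengths.values()), dtype=float)
            xs = np.exp(np.linspace(np.log(np.quantile(s, 0.1)),
                                    np.log(np.quantile(s, 0.95)), 20))
            sslope = np.polyfit(np.log(xs),
                                np.log([(s > x).mean() for x in xs]), 1)[0]
            assert sslope == pytest.approx(dslope, abs=0.35)


def test_intervals_from_contacts():
    events = [ContactEvent(1, 0, 1), ContactEvent(3, 0, 1),
              ContactEvent(4, 1, 2)]
    ict = {s.unit: s.gaps.tolist()
           for s in intervals_from_contacts(events, "node_ict")}
    assert ict[0] == [2]
    assert ict[1] == [2, 1]
    assert ict[2] == []
    liet = {s.unit: s.gaps.tolist()
            for s in intervals_from_contacts(events, "link_iet")}
    assert liet[(0, 1)] == [2]


def test_pooled_requires_samples():
    with pytest.raises(ParameterError):
        pooled([])
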