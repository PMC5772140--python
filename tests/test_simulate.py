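import numpy as np
import pytest
from scipy import stats

from netsir import (DiseaseModel, StaticNetwork, align_at_threshold,
                    ensemble_average, make_degree_distribution, parse_delay_spec,
                    sample_configuration_network, simulate_event_driven,
                    simulate_rejection, transmissibility)


def check_log_consistency(log):
    """Event times non-decreasing; one infection/recovery per node, in order;
    infectors infectious at the moment of transmission."""
    times = [e[0] for e in log.events]
    assert times == sorted(times)
    infected_at, recovered_at = {}, {}
    for tt, node, kind, source in log.events:
        if kind == "infection":
            assert node not in infected_at
            infected_at[node] = tt
            if source is not None:
                assert infected_at[source] <= tt
                assert recovered_at.get(source, np.inf) >= tt
        else:
            assert node in infected_at and node not in recovered_at
            assert tt > infected_at[node] or (tt == infected_at[node] == 0.0)
            recovered_at[node] = tt
    assert set(recovered_at) <= set(infected_at)


@pytest.fixture(scope="module")
def small_net():
    dd = make_degree_distribution("powerlaw_truncated", exponent=2.5, kmin=3, kmax=10)
    return sample_configuration_network(dd, 50, seed=4)


class TestRejectionMethod:
    def test_determinism(self, small_net):
        q = parse_delay_spec("normal:2,0.75")
        a = simulate_rejection(small_net, 0.3, q, 0.1, seed=12)
        b = simulate_rejection(small_net, 0.3, q, 0.1, seed=12)
        assert a.events == b.events

    def test_event_log_consistency(self, small_net):
        for seed in range(10):
            log = simulate_rejection(small_net, 0.5, parse_delay_spec("fixed:2"),
                                     3, seed=seed)
            check_log_consistency(log)

    def test_all_infected_only_recover(self, small_net):
        log = simulate_rejection(small_net, 0.3, parse_delay_spec("exp:0.5"),
                                 list(range(50)), seed=0)
        kinds = {e[2] for e in log.events if e[0] > 0}
        assert kinds == {"recovery"}
        assert log.final_size() == 50

    def test_two_node_transmission_probability(self):
        """On one edge the partner is infected with probability 1 - e^{-beta
        sigma}, the transmissibility of the fixed-period model."""
        net = StaticNetwork(2, [(0, 1)])
        q = parse_delay_spec("fixed:2")
        n = 20_000
        hits = sum(
            simulate_rejection(net, 0.3, q, [0], seed=[21, i]).final_size() == 2
            for i in range(n))
        p = 1 - np.exp(-0.6)
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_empty_init_is_rejected(self, small_net):
        with pytest.raises(ValueError):
            simulate_rejection(small_net, 0.3, parse_delay_spec("exp:0.5"),
                               [], seed=0)


class TestEventDrivenMethod:
    def test_determinism(self, small_net):
        tau, q = parse_delay_spec("gamma:2,1"), parse_delay_spec("weibull:1.5,2")
        a = simulate_event_driven(small_net, tau, q, 0.1, seed=5)
        b = simulate_event_driven(small_net, tau, q, 0.1, seed=5)
        assert a.events == b.events

    def test_event_log_consistency(self, small_net):
        tau, q = parse_delay_spec("exp:0.4"), parse_delay_spec("normal:2,0.75")
        for seed in range(10):
            check_log_consistency(simulate_event_driven(small_net, tau, q, 2, seed=seed))

    def test_two_node_attempt_probability_matches_quadrature(self):
        net = StaticNetwork(2, [(0, 1)])
        tau, q = parse_delay_spec("gamma:2,1"), parse_delay_spec("normal:2,0.75")
        T = transmissibility(DiseaseModel(tau, q))
        n = 20_000
        hits = sum(
            simulate_event_driven(net, tau, q, [0], seed=[31, i]).final_size() == 2
            for i in range(n))
        assert abs(hits / n - T) < 3 * np.sqrt(T * (1 - T) / n)

    def test_final_sizes_indistinguishable_from_rejection(self, small_net):
        """With exponential transmission the two samplers draw from the same
        process; their final-size histograms must agree (chi-square)."""
        q = parse_delay_spec("fixed:2")
        tau = parse_delay_spec("exp:0.3")
        n = 3000
        fs_rej = [simulate_rejection(small_net, 0.3, q, [0], seed=[41, i]).final_size()
                  for i in range(n)]
        fs_evt = [simulate_event_driven(small_net, tau, q, [0], seed=[42, i]).final_size()
                  for i in range(n)]
        bins = [0, 2, 5, 10, 20, 30, 40, 51]
        c_rej, _ = np.histogram(fs_rej, bins=bins)
        c_evt, _ = np.histogram(fs_evt, bins=bins)
        keep = (c_rej + c_evt) > 10
        _, pval, _, _ = stats.chi2_contingency(np.vstack([c_rej[keep], c_evt[keep]]))
        assert pval > 0.01


class TestEnsembleAveraging:
    def test_identical_logs_average_to_themselves(self, small_net):
        log = simulate_rejection(small_net, 0.3, parse_delay_spec("exp:0.5"), 3, seed=1)
        grid = np.linspace(0, 10, 21)
        ens = ensemble_average([log] * 4, grid)
        S, I, R = log.state_fractions(grid)
        assert np.array_equal(ens.S_mean, S)
        assert np.array_equal(ens.I_mean, I)
        assert np.all(ens.S_se == 0)
        assert np.allclose(ens.S_mean + ens.I_mean + ens.R_mean, 1.0, atol=1e-12)

    def test_standard_error_scales_as_root_n(self, small_net):
        grid = np.array([3.0])
        q = parse_delay_spec("exp:0.5")
        se = {}
        for n in (25, 100, 400):
            logs = [simulate_rejection(small_net, 0.3, q, 3, seed=[55, n, i])
                    for i in range(n)]
            se[n] = ensemble_average(logs, grid).I_se[0]
        assert se[100] / se[25] == pytest.approx(0.5, rel=0.25)
        assert se[400] / se[100] == pytest.approx(0.5, rel=0.25)

    def test_state_between_events_is_the_earlier_state(self):
        log_events = ((0.0, 0, "infection", None), (2.0, 1, "infection", 0),
                      (3.0, 0, "recovery", None))
        from netsir import EpidemicEventLog
        log = EpidemicEventLog(3, 0, (0,), log_events)
        S, I, R = log.state_fractions(np.array([1.0, 2.5, 3.5]))
        assert np.allclose(S * 3, [2, 1, 1])
        assert np.allclose(I * 3, [1, 2, 1])
        assert np.allclose(R * 3, [0, 0, 1])

    def test_zero_retained_runs_is_an_error(self, small_net):
        log = simulate_rejection(small_net, 0.3, parse_delay_spec("exp:0.5"), 3, seed=1)
        with pytest.raises(ValueError):
            ensemble_average([log], np.linspace(0, 5, 6),
                             discard_policy=lambda lg: False)


class TestBurnInAlignment:
    def test_run_starting_above_threshold_is_unshifted(self, small_net):
        log = simulate_rejection(small_net, 0.3, parse_delay_spec("exp:0.5"),
                                 10, seed=2)
        shifted = align_at_threshold(log, 0.1)
        assert shifted.meta["shift"] == 0.0
        assert shifted.events[0][0] == 0.0

    def test_dying_run_is_discarded(self):
        net = StaticNetwork(4, [(0, 1), (1, 2), (2, 3)])
        # beta tiny: the single seed almost surely recovers without spreading
        log = simulate_rejection(net, 1e-6, parse_delay_spec("fixed:1"), [0], seed=3)
        assert align_at_threshold(log, 0.9) is None

    def test_infected_fraction_reaches_threshold_at_reset(self, small_net):
        threshold = 0.2
        for seed in range(5):
            log = simulate_rejection(small_net, 0.5, parse_delay_spec("exp:0.5"),
                                     [0], seed=seed)
            shifted = align_at_threshold(log, threshold)
            if shifted is None:
                continue
            grid = np.array([0.0])
            _, I, _ = shifted.state_fractions(grid)
            assert I[0] >= threshold - 1e-12
            assert 0.0 < shifted.meta["z_at_reset"] <= 1.0
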