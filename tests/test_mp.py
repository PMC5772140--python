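import numpy as np
import pytest

from netsir import (DiseaseModel, StaticNetwork, epidemic_threshold, final_size,
                    parse_delay_spec, solve_mp, solve_mp_markovian_ode,
                    solve_mp_per_edge)
from netsir.ebcm import equivalence_report

from conftest import sup_gap


def _check_trajectory_invariants(traj):
    assert np.all((traj.message >= -1e-12) & (traj.message <= 1 + 1e-12))
    assert np.all(np.diff(traj.message) <= 1e-10)
    assert np.allclose(traj.S + traj.I + traj.R, 1.0, atol=1e-8)
    assert np.all(np.diff(traj.S) <= 1e-10)
    assert np.all(np.diff(traj.R) >= -1e-8)


class TestAverageMessage:
    def test_all_susceptible_is_an_equilibrium(self, g_regular5, markovian_model):
        traj = solve_mp(g_regular5, markovian_model, z=1.0, T=5.0, h=0.05)
        assert np.allclose(traj.message, 1.0, atol=1e-12)
        assert np.allclose(traj.S, 1.0, atol=1e-12)
        assert np.allclose(traj.I, 0.0, atol=1e-12)

    def test_initial_condition(self, g_regular5, markovian_model):
        traj = solve_mp(g_regular5, markovian_model, z=0.97, T=5.0, h=0.05)
        assert traj.S[0] == pytest.approx(0.97, abs=1e-12)
        assert traj.I[0] == pytest.approx(0.03, abs=1e-12)
        assert traj.R[0] == 0.0

    @pytest.mark.parametrize("q_spec", ["exp:0.5", "fixed:2", "normal:2,0.75"])
    def test_invariants_hold_for_each_recovery_law(self, g_powerlaw, q_spec):
        model = DiseaseModel(parse_delay_spec("exp:0.3"), parse_delay_spec(q_spec))
        traj = solve_mp(g_powerlaw, model, z=0.99, T=12.0, h=0.02)
        _check_trajectory_invariants(traj)

    def test_agreement_with_markovian_ode(self, g_regular5, markovian_model):
        mp = solve_mp(g_regular5, markovian_model, z=0.99, T=10.0, h=0.01)
        ode = solve_mp_markovian_ode(g_regular5, 0.3, 0.5, z=0.99, T=10.0, h=0.01)
        assert sup_gap(mp, ode) < 1e-3

    def test_volterra_error_shrinks_with_step(self, g_regular5, markovian_model):
        """Halving h from 0.02 to 0.01 shrinks the gap to the ODE reference
        by at least a factor of 2 (the scheme is better than first order)."""
        gaps = []
        for h in (0.02, 0.01):
            mp = solve_mp(g_regular5, markovian_model, z=0.99, T=10.0, h=h)
            ode = solve_mp_markovian_ode(g_regular5, 0.3, 0.5, z=0.99, T=10.0, h=h)
            gaps.append(np.max(np.abs(mp.message - ode.message[:: 1])))
        assert gaps[1] <= gaps[0] / 2

    def test_grid_refinement_converges_monotonically(self, g_regular5,
                                                     fixed_recovery_model):
        sols = {h: solve_mp(g_regular5, fixed_recovery_model, 0.99, 8.0, h)
                for h in (0.08, 0.04, 0.02, 0.01)}
        diffs = []
        for h_c, h_f in ((0.08, 0.04), (0.04, 0.02), (0.02, 0.01)):
            coarse, fine = sols[h_c], sols[h_f]
            stride = int(round(h_c / h_f))
            diffs.append(np.max(np.abs(coarse.message - fine.message[::stride])))
        assert diffs[0] > diffs[1] > diffs[2]


class TestMarkovianOde:
    def test_equilibrium_at_z_one(self, g_regular5):
        traj = solve_mp_markovian_ode(g_regular5, 0.3, 0.5, z=1.0, T=5.0, h=0.01)
        assert np.allclose(traj.message, 1.0, atol=1e-12)

    def test_long_horizon_reaches_percolation_fixed_point(self, g_regular5):
        beta, gamma = 0.3, 0.5
        traj = solve_mp_markovian_ode(g_regular5, beta, gamma, z=1 - 1e-6,
                                      T=200.0, h=0.02)
        model = DiseaseModel(parse_delay_spec(f"exp:{beta}"),
                             parse_delay_spec(f"exp:{gamma}"))
        theta_inf, _ = final_size(g_regular5, model)
        assert traj.message[-1] == pytest.approx(theta_inf, abs=1e-4)

    def test_rejects_invalid_rates(self, g_regular5):
        with pytest.raises(ValueError):
            solve_mp_markovian_ode(g_regular5, -0.3, 0.5, 0.99, 5.0, 0.01)


class TestPerEdgeMessages:
    def test_isolated_node_stays_at_z(self, markovian_model):
        net = StaticNetwork(3, [(0, 1)])  # node 2 isolated
        res = solve_mp_per_edge(net, markovian_model, z=0.8, T=5.0, h=0.05)
        assert np.allclose(res.node_susceptibility[2], 0.8, atol=1e-12)

    def test_two_node_closed_form(self, path2, markovian_model):
        beta, gamma, z = 0.3, 0.5, 0.9
        res = solve_mp_per_edge(path2, markovian_model, z=z, T=8.0, h=0.02)
        t = res.t
        closed = z * (1 - (1 - z) * (beta / (beta + gamma))
                      * (1 - np.exp(-(beta + gamma) * t)))
        assert np.max(np.abs(res.node_susceptibility[0] - closed)) < 1e-6

    def test_cycle_is_rejected_without_flag(self, markovian_model):
        cyc = StaticNetwork(3, [(0, 1), (1, 2), (0, 2)])
        with pytest.raises(ValueError):
            solve_mp_per_edge(cyc, markovian_model, z=0.9, T=2.0, h=0.1)
        res = solve_mp_per_edge(cyc, markovian_model, z=0.9, T=2.0, h=0.1,
                                allow_cycles=True)
        assert res.node_susceptibility.shape == (3, 21)

    def test_long_path_interior_matches_average_message(self, markovian_model):
        """A long path is a 2-regular tree away from its ends: the central
        node's per-edge solution matches the ensemble-average model."""
        n = 200
        net = StaticNetwork(n, [(i, i + 1) for i in range(n - 1)])
        res = solve_mp_per_edge(net, markovian_model, z=0.9, T=8.0, h=0.04)
        from netsir import GeneratingFunctionSet, make_degree_distribution
        g2 = GeneratingFunctionSet(make_degree_distribution("regular", k=2))
        avg = solve_mp(g2, markovian_model, z=0.9, T=8.0, h=0.04)
        assert np.max(np.abs(res.node_susceptibility[n // 2] - avg.S)) < 1e-4


class TestFinalSize:
    def test_quadratic_oracle_regular3(self, g_regular3):
        # beta=1.5, gamma=0.5 gives transmissibility 0.75; the fixed point of
        # Theta = 1 - T + T Theta^2 solves 0.75 Theta^2 - Theta + 0.25 = 0
        model = DiseaseModel(parse_delay_spec("exp:1.5"), parse_delay_spec("exp:0.5"))
        theta_inf, r_inf = final_size(g_regular3, model)
        assert theta_inf == pytest.approx(1.0 / 3.0, abs=1e-10)
        assert r_inf == pytest.approx(26.0 / 27.0, abs=1e-10)

    def test_subthreshold_has_no_outbreak(self, g_regular3):
        model = DiseaseModel(parse_delay_spec("exp:0.1"), parse_delay_spec("exp:0.5"))
        assert epidemic_threshold(g_regular3, model) < 1.0
        theta_inf, r_inf = final_size(g_regular3, model)
        assert theta_inf == pytest.approx(1.0, abs=1e-9)
        assert r_inf == pytest.approx(0.0, abs=1e-9)

    def test_threshold_ratio_values(self, g_regular3):
        boundary = DiseaseModel(parse_delay_spec("exp:0.5"), parse_delay_spec("exp:0.5"))
        assert epidemic_threshold(g_regular3, boundary) == pytest.approx(1.0, abs=1e-8)
        _, r_inf = final_size(g_regular3, boundary)
        assert r_inf < 1e-3
        above = DiseaseModel(parse_delay_spec("exp:1.5"), parse_delay_spec("exp:0.5"))
        assert epidemic_threshold(g_regular3, above) == pytest.approx(1.5, abs=1e-8)
        _, r_above = final_size(g_regular3, above)
        assert r_above > 0.5
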