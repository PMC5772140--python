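import numpy as np
import pytest
from scipy.integrate import solve_ivp

from netsir import (DiseaseModel, GeneratingFunctionSet, UnsupportedModelError,
                    make_degree_distribution, parse_delay_spec, solve_mp,
                    solve_pairwise_cm, solve_pairwise_fixed_delay,
                    solve_pairwise_markovian, solve_pairwise_regular)

from conftest import sup_gap

Z, N, T, H = 0.99, 1000.0, 12.0, 0.01
BETA = 0.3


class TestInitialConditionsAndConservation:
    def test_si_edges_start_at_mixing_value(self, g_regular5):
        q = parse_delay_spec("exp:0.5")
        st = solve_pairwise_cm(g_regular5, BETA, q, Z, N, 2.0, 0.01)
        assert st.SI[0] == pytest.approx(5 * N * Z * (1 - Z), abs=1e-9)
        assert st.S[0] == pytest.approx(Z * N, abs=1e-9)
        assert st.I[0] == pytest.approx((1 - Z) * N, abs=1e-9)

    def test_all_susceptible_is_frozen(self, g_regular5):
        st = solve_pairwise_cm(g_regular5, BETA, parse_delay_spec("exp:0.5"),
                               1.0, N, 3.0, 0.01)
        assert np.allclose(st.SI, 0.0, atol=1e-9)
        assert np.allclose(st.S, N, atol=1e-6)
        mk = solve_pairwise_markovian(g_regular5, BETA, 0.5, 1.0, N, 3.0, 0.01)
        assert np.allclose(mk.SI, 0.0, atol=1e-9)
        assert np.allclose(mk.I, 0.0, atol=1e-9)

    @pytest.mark.parametrize("q_spec", ["exp:0.5", "fixed:2", "normal:2,0.75"])
    def test_population_is_conserved(self, g_regular5, q_spec):
        st = solve_pairwise_cm(g_regular5, BETA, parse_delay_spec(q_spec),
                               Z, N, T, H)
        assert np.allclose(st.S + st.I + st.R, N, atol=1e-6 * N)
        assert np.all(st.SI >= 0)
        assert np.all(st.SI <= 5 * N + 1e-6)
        # [S](t) = z N G0(H1(t)) is built in; check it numerically anyway
        assert np.allclose(st.S, Z * N * np.asarray(g_regular5.G0(st.H1)),
                           atol=1e-6 * N)


class TestHierarchyReductions:
    @pytest.mark.parametrize("q_spec", ["exp:0.5", "normal:2,0.75", "gamma:2,1"])
    def test_cm_system_reproduces_message_passing(self, g_regular5, q_spec):
        """The count system is an exact re-parametrisation of the MP model."""
        q = parse_delay_spec(q_spec)
        model = DiseaseModel(parse_delay_spec(f"exp:{BETA}"), q)
        pw = solve_pairwise_cm(g_regular5, BETA, q, Z, N, T, H).per_capita()
        mp = solve_mp(g_regular5, model, Z, T, H)
        assert sup_gap(pw, mp) < 1e-3

    def test_cm_system_reduces_to_regular_variant(self, g_regular5):
        q = parse_delay_spec("normal:2,0.75")
        cm = solve_pairwise_cm(g_regular5, BETA, q, Z, N, T, H)
        reg = solve_pairwise_regular(5, BETA, q, Z, N, T, H)
        for name in ("S", "I", "R", "SI"):
            assert np.max(np.abs(getattr(cm, name) - getattr(reg, name))) < 1e-3 * N

    def test_cm_system_reduces_to_markovian_variant(self, g_powerlaw):
        cm = solve_pairwise_cm(g_powerlaw, BETA, parse_delay_spec("exp:0.5"),
                               Z, N, T, H)
        mk = solve_pairwise_markovian(g_powerlaw, BETA, 0.5, Z, N, T, H)
        for name in ("S", "I", "R", "SI"):
            assert np.max(np.abs(getattr(cm, name) - getattr(mk, name))) < 1e-3 * N

    def test_cm_system_reduces_to_fixed_delay_variant(self, g_powerlaw):
        cm = solve_pairwise_cm(g_powerlaw, BETA, parse_delay_spec("fixed:2"),
                               Z, N, T, H)
        dde = solve_pairwise_fixed_delay(g_powerlaw, BETA, 2.0, Z, N, T, H)
        for name in ("S", "I", "R", "SI"):
            assert np.max(np.abs(getattr(cm, name) - getattr(dde, name))) < 1e-3 * N

    def test_fixed_delay_matches_message_passing(self, g_powerlaw):
        model = DiseaseModel(parse_delay_spec(f"exp:{BETA}"), parse_delay_spec("fixed:2"))
        dde = solve_pairwise_fixed_delay(g_powerlaw, BETA, 2.0, Z, N, T, H).per_capita()
        mp = solve_mp(g_powerlaw, model, Z, T, H)
        assert sup_gap(dde, mp) < 1e-3


class TestRegularVariant:
    def test_ss_edges_never_increase(self):
        st = solve_pairwise_regular(5, BETA, parse_delay_spec("exp:0.5"),
                                    Z, N, T, H)
        assert np.all(np.diff(st.SS) <= 1e-9)
        assert st.SS[0] == pytest.approx(5 * N * Z * Z, abs=1e-9)

    def test_rejects_degree_below_two(self):
        with pytest.raises(ValueError):
            solve_pairwise_regular(1, BETA, parse_delay_spec("exp:0.5"),
                                   Z, N, 2.0, 0.01)


class TestMarkovianVariant:
    def test_peak_agrees_with_ode_reference(self, g_regular5):
        from netsir import solve_mp_markovian_ode
        pw = solve_pairwise_markovian(g_regular5, BETA, 0.5, Z, N, T, H)
        ode = solve_mp_markovian_ode(g_regular5, BETA, 0.5, Z, T, H)
        t_pw, peak_pw = pw.per_capita().peak()
        t_ode, peak_ode = ode.peak()
        assert abs(t_pw - t_ode) <= 2 * H
        assert abs(peak_pw - peak_ode) < 1e-3

    def test_dense_limit_approaches_mass_action(self):
        """k = N-1 with per-edge rate beta/N approaches the classical
        well-mixed SIR model."""
        n_small, beta_m, gamma, z = 500, 1.0, 0.5, 0.95
        gfs = GeneratingFunctionSet(make_degree_distribution("regular", k=n_small - 1))
        pw = solve_pairwise_markovian(gfs, beta_m / n_small, gamma, z,
                                      n_small, 15.0, 0.01).per_capita()

        def mass_action(t, y):
            s, i = y
            return [-beta_m * s * i, beta_m * s * i - gamma * i]

        sol = solve_ivp(mass_action, (0, 15.0), [z, 1 - z], t_eval=pw.t,
                        rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(pw.S - sol.y[0])) < 5e-2
        assert np.max(np.abs(pw.I - sol.y[1])) < 5e-2


class TestFixedDelayVariant:
    def test_no_recovery_before_the_delay(self, g_regular5):
        sigma = 2.0
        st = solve_pairwise_fixed_delay(g_regular5, BETA, sigma, Z, N, T, H)
        before = st.t < sigma
        # up to sigma, dI/dt = beta [SI]: R stays 0
        assert np.allclose(st.R[before], 0.0, atol=1e-6 * N)

    def test_initial_cohort_recovers_impulsively(self, g_regular5):
        sigma = 2.0
        st = solve_pairwise_fixed_delay(g_regular5, BETA, sigma, Z, N, T, H)
        j = int(round(sigma / H))
        drop = st.I[j - 1] - st.I[j]
        smooth = BETA * st.SI[j] * H  # continuous part over one step
        assert drop == pytest.approx(N * (1 - Z), abs=5 * smooth + 1.0)

    def test_lag_must_sit_on_the_grid(self, g_regular5):
        with pytest.raises(ValueError):
            solve_pairwise_fixed_delay(g_regular5, BETA, 2.0005, Z, N, 5.0, 0.01)
        q = parse_delay_spec("fixed:2.0005")
        with pytest.raises(ValueError):
            solve_pairwise_cm(g_regular5, BETA, q, Z, N, 5.0, 0.01)


class TestTransmissionRestriction:
    def test_non_exponential_transmission_is_rejected(self, g_regular5):
        with pytest.raises(UnsupportedModelError):
            solve_pairwise_cm(g_regular5, BETA, parse_delay_spec("exp:0.5"),
                              Z, N, 2.0, 0.01,
                              transmission=parse_delay_spec("gamma:2,1"))
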