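"""Generalized Gillespie engine: couplings, stochastic stepping, exact
fallback, branching, determinism, and the Markov limit."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.stats import kstest, ks_2samp

import rtnet as rt
from rtnet.engine import DeadlockError, arrival_distribution, exact_step


class TestCouplings:
    def test_neutral_feedback_is_identity(self):
        for frac in (0.0, 0.3, 1.0):
            assert rt.coupling_feedback(frac, 2.0, 0.1, 1.0) == pytest.approx(2.0)

    def test_feedback_at_empty_coupled_state(self):
        assert rt.coupling_feedback(0.0, 1.7, 0.1, 5.0) == pytest.approx(1.7)

    def test_feedback_saturated_value(self):
        # (K + eta)/(K + 1) at full conversion
        assert rt.coupling_feedback(1.0, 1.0, 0.1, 5.0) == pytest.approx(5.1 / 1.1)

    def test_gate_blocked_at_zero(self):
        assert rt.coupling_gate(0.0, 1.0, 0.1) == 0.0

    def test_gate_half_saturation(self):
        assert rt.coupling_gate(0.1, 2.0, 0.1) == pytest.approx(1.0)

    def test_gate_saturated_value(self):
        assert rt.coupling_gate(1.0, 1.0, 0.1) == pytest.approx(1.0 / 1.1)

    @pytest.mark.parametrize("frac", [-0.1, 1.2])
    def test_fraction_domain_enforced(self, frac):
        with pytest.raises(ValueError):
            rt.coupling_gate(frac, 1.0, 0.1)
        with pytest.raises(ValueError):
            rt.coupling_feedback(frac, 1.0, 0.1, 2.0)


class TestSimulate:
    def test_gamma_transition_arrivals_match_analytic(self, single_transition_network,
                                                      gamma_10_10):
        traj = rt.simulate(single_transition_network, n_cells=5000, t_max=10.0, seed=1)
        times = traj.first_arrival_times("Sa")
        assert times.size == 5000
        assert kstest(times, gamma_10_10.cdf).statistic < 0.05

    def test_exponential_transition_mean(self):
        lam = 2.0
        net = rt.CommunicationNetwork(
            states=[rt.CellState("S0"), rt.CellState("Sa", is_absorbing=True)],
            transitions=[rt.TransitionSpec("S0", "Sa", law=rt.GammaRT(1.0, lam))],
            initial={"S0": 1.0})
        traj = rt.simulate(net, n_cells=10000, t_max=50.0, seed=2)
        times = traj.first_arrival_times("Sa")
        se = (1.0 / lam) / np.sqrt(times.size)
        assert abs(times.mean() - 1.0 / lam) < 3 * se

    def test_branching_fractions(self):
        net = rt.CommunicationNetwork(
            states=[rt.CellState("S0"), rt.CellState("A", is_absorbing=True),
                    rt.CellState("B", is_absorbing=True)],
            transitions=[
                rt.TransitionSpec("S0", "A", law=rt.GammaRT(3.0, 3.0), branch_prob=0.5),
                rt.TransitionSpec("S0", "B", law=rt.GammaRT(3.0, 3.0), branch_prob=0.5),
            ],
            initial={"S0": 1.0})
        traj = rt.simulate(net, n_cells=10000, t_max=30.0, seed=3)
        frac_a = traj.first_arrival_times("A").size / 10000
        assert frac_a == pytest.approx(0.5, abs=0.02)

    def test_identical_seeds_reproduce_event_log(self, single_transition_network):
        a = rt.simulate(single_transition_network, n_cells=300, t_max=10.0, seed=9)
        b = rt.simulate(single_transition_network, n_cells=300, t_max=10.0, seed=9)
        assert a.events.equals(b.events)

    def test_markov_limit_matches_rate_equation(self):
        # all shapes 1: occupancy means follow dS/dt = -lambda S exactly
        lam = 1.5
        net = rt.CommunicationNetwork(
            states=[rt.CellState("S0"), rt.CellState("Sa", is_absorbing=True)],
            transitions=[rt.TransitionSpec("S0", "Sa", law=rt.GammaRT(1.0, lam))],
            initial={"S0": 1.0})
        traj = rt.simulate(net, n_cells=8000, t_max=6.0, seed=4)
        t = np.linspace(0, 4, 50)
        occ = traj.occupancy(t)["S0"].to_numpy()
        expected = np.exp(-lam * t)
        se = np.sqrt(expected * (1 - expected) / 8000)
        assert np.all(np.abs(occ - expected) <= 3 * se + 1e-3)

    def test_cell_count_conserved(self, single_transition_network):
        traj = rt.simulate(single_transition_network, n_cells=500, t_max=10.0, seed=5)
        occ = traj.occupancy(np.linspace(0, 10, 30))
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)

    def test_force_exact_agrees_with_approximate(self, single_transition_network,
                                                 gamma_10_10):
        exact = rt.simulate(single_transition_network, n_cells=2000, t_max=10.0,
                            seed=6, force_exact=True)
        assert kstest(exact.first_arrival_times("Sa"), gamma_10_10.cdf).statistic < 0.05

    def test_deadlock_names_states(self):
        # gate coupled to a state that can never be populated
        net = rt.CommunicationNetwork(
            states=[rt.CellState("S0"), rt.CellState("never"),
                    rt.CellState("Sa", is_absorbing=True)],
            transitions=[rt.TransitionSpec(
                "S0", "Sa", law=rt.GammaRT(2.0, 1.0),
                coupling=rt.Coupling(state="never", function="gate", K=0.1))],
            initial={"S0": 1.0})
        with pytest.raises(DeadlockError, match="S0"):
            rt.simulate(net, n_cells=100, t_max=10.0, seed=7)


class TestNetworkValidation:
    def test_absorbing_state_cannot_emit(self):
        with pytest.raises(ValueError, match="absorbing"):
            rt.CommunicationNetwork(
                states=[rt.CellState("A", is_absorbing=True), rt.CellState("B")],
                transitions=[rt.TransitionSpec("A", "B", law=rt.GammaRT(1.0, 1.0))],
                initial={"A": 1.0})

    def test_branch_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="branch"):
            rt.CommunicationNetwork(
                states=[rt.CellState("S0"), rt.CellState("A", is_absorbing=True),
                        rt.CellState("B", is_absorbing=True)],
                transitions=[
                    rt.TransitionSpec("S0", "A", law=rt.GammaRT(1.0, 1.0), branch_prob=0.6),
                    rt.TransitionSpec("S0", "B", law=rt.GammaRT(1.0, 1.0), branch_prob=0.3)],
                initial={"S0": 1.0})

    def test_unknown_coupling_state_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            rt.CommunicationNetwork(
                states=[rt.CellState("S0"), rt.CellState("Sa", is_absorbing=True)],
                transitions=[rt.TransitionSpec(
                    "S0", "Sa", law=rt.GammaRT(1.0, 1.0),
                    coupling=rt.Coupling(state="ghost", function="gate", K=0.1))],
                initial={"S0": 1.0})


class TestExactStep:
    def test_single_process_from_zero_clock_samples_the_law(self, rng):
        law = (10.0, 10.0)
        draws = np.array([exact_step(np.array([0.0]), [law], rng)[0]
                          for _ in range(5000)])
        assert kstest(draws, rt.GammaRT(10.0, 10.0).cdf).statistic < 0.05

    def test_exponential_clock_is_irrelevant(self, rng):
        lam = (1.0, 2.0)
        fresh = np.array([exact_step(np.array([0.0]), [lam], rng)[0]
                          for _ in range(4000)])
        aged = np.array([exact_step(np.array([3.7]), [lam], rng)[0]
                         for _ in range(4000)])
        assert ks_2samp(fresh, aged).statistic < 0.05

    def test_competing_processes_match_pairwise_minimum(self, rng):
        laws = [(10.0, 10.0), (10.0, 10.0)]
        draws = np.array([exact_step(np.zeros(2), laws, rng)[0]
                          for _ in range(5000)])
        brute = np.minimum(rt.GammaRT(10.0, 10.0).rvs(5000, rng),
                           rt.GammaRT(10.0, 10.0).rvs(5000, rng))
        assert ks_2samp(draws, brute).statistic < 0.05

    def test_all_blocked_is_deadlock(self, rng):
        with pytest.raises(DeadlockError):
            exact_step(np.zeros(2), [(2.0, 0.0), (2.0, 0.0)], rng)


class TestArrivalDistribution:
    def test_full_normalization_integrates_to_one(self, single_transition_network):
        traj = rt.simulate(single_transition_network, n_cells=2000, t_max=10.0, seed=8)
        emp, reached = arrival_distribution(traj, "Sa", normalize_mode="full")
        assert reached == 1.0
        assert emp.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_branch_normalization_scales_to_reached_fraction(self):
        net = rt.CommunicationNetwork(
            states=[rt.CellState("S0"), rt.CellState("A", is_absorbing=True),
                    rt.CellState("B", is_absorbing=True)],
            transitions=[
                rt.TransitionSpec("S0", "A", law=rt.GammaRT(3.0, 3.0), branch_prob=0.3),
                rt.TransitionSpec("S0", "B", law=rt.GammaRT(3.0, 3.0), branch_prob=0.7)],
            initial={"S0": 1.0})
        traj = rt.simulate(net, n_cells=4000, t_max=30.0, seed=9)
        emp, reached = arrival_distribution(traj, "A", normalize_mode="per_branch")
        assert reached == pytest.approx(0.3, abs=0.03)
        # trapezoid-on-bin-centers loses half a bin at each edge
        assert emp.total_mass == pytest.approx(reached, rel=0.02)

    def test_no_arrivals_signaled(self, single_transition_network):
        traj = rt.simulate(single_transition_network, n_cells=100, t_max=1e-6, seed=10)
        with pytest.raises(ValueError, match="no cell arrived"):
            arrival_distribution(traj, "Sa")


class TestCoupledDynamics:
    def test_positive_feedback_matches_linear_chain_ode(self):
        # the engine's integrated-intensity hazard must reproduce the
        # deterministic linear-chain solution of the feedback motif
        from rtnet.motifs import MotifSpec, solve_motif

        g = np.linspace(0, 8, 1000)
        _, dens = solve_motif(MotifSpec("feedback", shape=10, means=(1.0,),
                                        K=0.1, eta=5.0), g)
        F = cumulative_trapezoid(dens.density, g, initial=0)
        net = rt.CommunicationNetwork(
            states=[rt.CellState("S0"), rt.CellState("Sa", is_absorbing=True)],
            transitions=[rt.TransitionSpec(
                "S0", "Sa", law=rt.GammaRT(10.0, 10.0),
                coupling=rt.Coupling(state="Sa", function="feedback", K=0.1,
                                     eta=5.0, beta_base=10.0))],
            initial={"S0": 1.0})
        traj = rt.simulate(net, n_cells=3000, t_max=8.0, seed=11)
        times = traj.first_arrival_times("Sa")
        # the avalanche front is steep, so compare arrival-time quantiles
        # (robust to tiny horizontal offsets) rather than pointwise CDFs
        qs = np.linspace(0.1, 0.9, 9)
        t_engine = np.quantile(times, qs)
        t_ode = np.interp(qs, F, g)
        assert np.max(np.abs(t_engine - t_ode)) < 0.05

    def test_gate_motif_matches_linear_chain_ode(self):
        from rtnet.motifs import MotifSpec, solve_motif

        g = np.linspace(0, 15, 1000)
        _, dens = solve_motif(MotifSpec("gate", shape=10, means=(1.0, 1.0), K=0.1), g)
        F = cumulative_trapezoid(dens.density, g, initial=0)
        net = rt.CommunicationNetwork(
            states=[rt.CellState("A0"), rt.CellState("A1", is_absorbing=True),
                    rt.CellState("B0"), rt.CellState("Ba", is_absorbing=True)],
            transitions=[
                rt.TransitionSpec("A0", "A1", law=rt.GammaRT(10.0, 10.0)),
                rt.TransitionSpec("B0", "Ba", law=rt.GammaRT(10.0, 10.0),
                                  coupling=rt.Coupling(state="A1", function="gate",
                                                       K=0.1, beta_base=10.0,
                                                       pool_fraction=0.5))],
            initial={"A0": 0.5, "B0": 0.5})
        traj = rt.simulate(net, n_cells=4000, t_max=15.0, seed=12)
        times = traj.first_arrival_times("Ba")
        qs = np.linspace(0.1, 0.9, 9)
        t_engine = np.quantile(times, qs)
        t_ode = np.interp(qs, F, g)
        assert np.max(np.abs(t_engine - t_ode)) < 0.1
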