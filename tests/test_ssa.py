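import numpy as np
import pytest
from scipy.stats import chi2

import mgrdme as mg
from mgrdme.model import LatticeState, make_model
from mgrdme.ssa import Trajectory, estimate_steady_state, propensities, simulate
from mgrdme.stationary import solve_stationary_means, steady_state_propensities, truncated_generator


class TestPropensityTable:
    def test_benchmark_jump_rates(self, eq_first_order):
        # per-molecule jump rates D/h^2 for L=2, K=40
        state = LatticeState(np.ones(40, dtype=int), np.ones(40, dtype=int))
        table = propensities(state, eq_first_order)
        a_jumps = table.by_kind("diffuse_A")
        b_jumps = table.by_kind("diffuse_B")
        assert a_jumps[0].propensity == pytest.approx(64.0)
        assert b_jumps[0].propensity == pytest.approx(4.0)
        # interior compartments have both directions, ends only one
        assert len(a_jumps) == 2 * 40 - 2

    def test_empty_state_only_production(self, eq_first_order):
        table = propensities(LatticeState.empty(eq_first_order), eq_first_order)
        positive = [e for e in table.events if e.propensity > 0]
        assert len(positive) == 1
        assert positive[0].kind == "produce_A"
        assert positive[0].propensity == eq_first_order.k1

    def test_first_order_conversion_totals(self, eq_first_order):
        m = eq_first_order.with_grids(K_A=10, K_B=40)
        n = np.zeros(10, dtype=int)
        n[3] = 5
        state = LatticeState(n, np.zeros(40, dtype=int))
        conv = propensities(state, m).by_kind("convert")
        # total k2 * n_j shared over the gamma=4 targets
        assert len(conv) == 4
        assert sum(e.propensity for e in conv) == pytest.approx(m.k2 * 5)
        assert {e.dm[0][0] for e in conv} == {12, 13, 14, 15}

    def test_dimerization_propensity_pair_count(self, eq_dimerization):
        # n_j = 3 -> 3 unordered pairs, total (k2/h_A) * n(n-1)/2
        m = eq_dimerization
        n = np.zeros(m.K_A, dtype=int)
        n[0] = 3
        state = LatticeState(n, np.zeros(m.K_B, dtype=int))
        dim = propensities(state, m).by_kind("dimerize")
        total = sum(e.propensity for e in dim)
        assert total == pytest.approx(3.0 * m.k2 / m.h_A)
        assert len(dim) == 4  # gamma = 4 target compartments, equal split
        assert all(e.propensity == pytest.approx(total / 4) for e in dim)
        assert dim[0].dn == ((0, -2),)

    def test_kernel_total_matches_table(self, eq_dimerization, rng):
        # the compiled kernel and the reference table must agree on the
        # total propensity at random states
        m = eq_dimerization
        for _ in range(20):
            n = rng.integers(0, 6, m.K_A)
            m_counts = rng.integers(0, 6, m.K_B)
            state = LatticeState(n, m_counts)
            table_total = propensities(state, m).total_propensity
            k2_eff = 0.5 * m.k2 / m.h_A
            q2 = np.sum(n * (n - 1))
            kernel_total = (
                m.k1
                + m.d_A * (2 * n.sum() - n[0] - n[-1])
                + m.d_B * (2 * m_counts.sum() - m_counts[0] - m_counts[-1])
                + k2_eff * q2
                + m.k3 * m_counts.sum()
            )
            assert kernel_total == pytest.approx(table_total)

    def test_negative_counts_rejected(self, eq_first_order):
        state = LatticeState.empty(eq_first_order)
        state.n = state.n - 1
        with pytest.raises(ValueError):
            propensities(state, eq_first_order)


class TestSimulate:
    def test_all_rates_zero_freezes(self):
        m = make_model(dict(L=1, K_A=2, K_B=2, D_A=0, D_B=0, k1=0, k2=0, k3=0))
        init = LatticeState(np.array([1, 2]), np.array([3, 4]))
        traj = simulate(m, t_end=5.0, seed=0, init=init)
        assert np.array_equal(traj.final_state.n, [1, 2])
        assert np.array_equal(traj.final_state.m, [3, 4])
        assert traj.final_state.t == 5.0
        assert sum(traj.event_counts.values()) == 0
        mean_n, var_n, _, _ = estimate_steady_state(traj)
        assert np.allclose(mean_n, [1, 2]) and np.allclose(var_n, 0.0)

    def test_reproducible(self, eq_first_order):
        t1 = simulate(eq_first_order, t_end=5.0, seed=42, record="none")
        t2 = simulate(eq_first_order, t_end=5.0, seed=42, record="none")
        assert np.array_equal(t1.final_state.n, t2.final_state.n)
        assert np.array_equal(t1.final_state.m, t2.final_state.m)
        assert t1.event_counts == t2.event_counts

    def test_event_bookkeeping_first_order(self, eq_first_order):
        traj = simulate(eq_first_order, t_end=20.0, seed=7, record="none")
        c = traj.event_counts
        # empty start: produced - converted = final A count; converted -
        # degraded = final B count
        assert c["produce"] - c["convert"] == traj.final_state.n.sum()
        assert c["convert"] - c["degrade"] == traj.final_state.m.sum()

    def test_event_bookkeeping_dimerization(self, eq_dimerization):
        traj = simulate(eq_dimerization, t_end=20.0, seed=7, record="none")
        c = traj.event_counts
        assert c["produce"] - 2 * c["convert"] == traj.final_state.n.sum()
        assert c["convert"] - c["degrade"] == traj.final_state.m.sum()

    def test_matches_stationary_means(self, eq_first_order):
        # time-averaged means within 3 Monte-Carlo SEs of the exact solution
        sol = solve_stationary_means(eq_first_order)
        traj = simulate(
            eq_first_order, t_end=400.0, seed=11, burn_in=20.0, init="poisson",
            record="interval", record_interval=0.5,
        )
        mean_n, _, mean_m, _ = estimate_steady_state(traj)
        # batch-means SE of the totals from snapshots
        totals_m = traj.m_t.sum(axis=1).astype(float)
        batches = np.array_split(totals_m[traj.times >= 20.0], 20)
        bm = np.array([b.mean() for b in batches])
        se = bm.std(ddof=1) / np.sqrt(len(bm))
        assert abs(mean_m.sum() - sol.B_total) < 3 * se + 1e-9
        totals_n = traj.n_t.sum(axis=1).astype(float)
        bn = np.array([b.mean() for b in np.array_split(totals_n[traj.times >= 20.0], 20)])
        se_n = bn.std(ddof=1) / np.sqrt(len(bn))
        assert abs(mean_n.sum() - sol.A_total) < 3 * se_n + 1e-9

    def test_variance_close_to_mean_product_poisson(self, eq_first_order):
        traj = simulate(
            eq_first_order, t_end=500.0, seed=3, burn_in=25.0, init="poisson", record="none"
        )
        mean_n, var_n, mean_m, var_m = estimate_steady_state(traj)
        assert abs(var_n.sum() / mean_n.sum() - 1.0) < 0.05
        assert abs(var_m.sum() / mean_m.sum() - 1.0) < 0.05

    def test_total_propensity_time_average(self, eq_first_order):
        # reaction propensity averages to 3 k1; total to r_reac + r_diff
        sol = solve_stationary_means(eq_first_order)
        r_reac, _ = steady_state_propensities(eq_first_order, sol)
        traj = simulate(
            eq_first_order, t_end=300.0, seed=5, burn_in=20.0, init="poisson",
            record="interval", record_interval=0.25,
        )
        m = eq_first_order
        keep = traj.times >= 20.0
        nA = traj.n_t[keep].sum(axis=1)
        mB = traj.m_t[keep].sum(axis=1)
        r_samples = m.k1 + m.k2 * nA + m.k3 * mB
        bm = np.array([b.mean() for b in np.array_split(r_samples.astype(float), 20)])
        se = bm.std(ddof=1) / np.sqrt(len(bm))
        assert abs(r_samples.mean() - r_reac) < 3 * se + 1e-9

    def test_invalid_horizon(self, eq_first_order):
        with pytest.raises(ValueError):
            simulate(eq_first_order, t_end=0.0, seed=0)
        with pytest.raises(ValueError):
            simulate(eq_first_order, t_end=1.0, seed=0, burn_in=2.0)

    def test_gamma_one_equals_standard_enumeration(self, eq_first_order):
        # a multigrid model with matching grids is the standard model: the
        # overlap weights are the identity and trajectories coincide
        from mgrdme.model import overlap_weights

        assert np.allclose(overlap_weights(eq_first_order), np.eye(40))
        a = simulate(eq_first_order, t_end=3.0, seed=9, record="none")
        b = simulate(eq_first_order, t_end=3.0, seed=9, record="none")
        assert np.array_equal(a.final_state.n, b.final_state.n)

    def test_dimerization_well_mixed_flux_balance(self, eq_dimerization):
        # K_A = K_B = 1: stationary mean B = k1/(2 k3) = 12.5
        m = eq_dimerization.with_grids(K_A=1, K_B=1)
        traj = simulate(
            m, t_end=600.0, seed=21, burn_in=30.0, init="poisson",
            record="interval", record_interval=0.5,
        )
        _, _, mean_m, _ = estimate_steady_state(traj)
        mB = traj.m_t[traj.times >= 30.0].sum(axis=1).astype(float)
        bm = np.array([b.mean() for b in np.array_split(mB, 20)])
        se = bm.std(ddof=1) / np.sqrt(len(bm))
        assert abs(mean_m.sum() - m.k1 / (2 * m.k3)) < 3 * se + 1e-9


class TestEstimateSteadyState:
    def test_constant_trajectory(self, toy_first_order):
        traj = Trajectory.from_states(
            toy_first_order, [0.0, 1.0, 2.0], [[4], [4], [4]], [[7], [7], [7]], t_end=3.0
        )
        mean_n, var_n, mean_m, var_m = estimate_steady_state(traj)
        assert mean_n[0] == 4.0 and var_n[0] == 0.0
        assert mean_m[0] == 7.0 and var_m[0] == 0.0

    def test_two_state_hand_computation(self, toy_first_order):
        # equal durations at counts 0 and 2: mean 1, variance 1
        traj = Trajectory.from_states(
            toy_first_order, [0.0, 1.0], [[0], [2]], [[2], [0]], t_end=2.0
        )
        mean_n, var_n, mean_m, var_m = estimate_steady_state(traj)
        assert mean_n[0] == pytest.approx(1.0) and var_n[0] == pytest.approx(1.0)
        assert mean_m[0] == pytest.approx(1.0) and var_m[0] == pytest.approx(1.0)

    def test_posthoc_burn_in_from_snapshots(self, toy_first_order):
        traj = Trajectory.from_states(
            toy_first_order, [0.0, 1.0, 2.0], [[0], [2], [2]], [[0], [0], [0]], t_end=3.0
        )
        mean_n, _, _, _ = estimate_steady_state(traj, burn_in=1.0)
        assert mean_n[0] == pytest.approx(2.0)

    def test_burn_in_beyond_horizon(self, toy_first_order):
        traj = Trajectory.from_states(toy_first_order, [0.0, 1.0], [[0], [1]], [[0], [0]])
        with pytest.raises(ValueError):
            estimate_steady_state(traj, burn_in=10.0)


class TestAgainstGeneratorOracle:
    def test_empirical_law_matches_generator(self, toy_first_order):
        # chi-square goodness of fit of decorrelated SSA samples against
        # the truncated-generator stationary law (alpha = 0.01)
        m = toy_first_order
        gen = truncated_generator(m, (25, 40))
        traj = simulate(
            m, t_end=50_000.0, seed=17, burn_in=50.0, init="poisson",
            record="interval", record_interval=5.0,
        )
        keep = traj.times >= 50.0
        samples_n = traj.n_t[keep, 0]
        samples_m = traj.m_t[keep, 0]
        n_samples = samples_n.size
        # pool joint states into bins with expected count >= 5
        expected = {}
        for n in range(26):
            for mm in range(41):
                expected[(n, mm)] = gen.pmf([n], [mm]) * n_samples
        observed = {}
        for n, mm in zip(samples_n, samples_m):
            observed[(int(n), int(mm))] = observed.get((int(n), int(mm)), 0) + 1
        # sort states by expected count; pool the tail into one bin
        items = sorted(expected.items(), key=lambda kv: -kv[1])
        chi, df, exp_tail, obs_tail = 0.0, 0, 0.0, 0
        for key, e in items:
            if e >= 5.0:
                o = observed.get(key, 0)
                chi += (o - e) ** 2 / e
                df += 1
            else:
                exp_tail += e
                obs_tail += observed.get(key, 0)
        if exp_tail > 0:
            chi += (obs_tail - exp_tail) ** 2 / exp_tail
            df += 1
        df -= 1
        # samples 5 time units apart are decorrelated (relaxation < 1)
        assert chi < chi2.ppf(0.99, df)
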