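"""Demographic transition, dispersal kernel and trajectory simulation."""

import math

import numpy as np
import pytest

from dynsdm.ecology import (
    DemographyParams,
    DispersalParams,
    InitialPopulationParams,
    SuitabilityParams,
    apply_dispersal,
    dispersal_matrix,
    fecundity,
    initial_state,
    round_half_away,
    self_regulation_ratio,
    simulate_trajectory,
    step_transition,
    suitability,
)
from dynsdm.lattice import EnvSeries, build_rect_grid


def demog(rho=0.3, phi=200.0, k_hat=3.0, theta=6.0, M=40.0):
    return DemographyParams(rho, phi, k_hat, theta, M)


class TestFecundity:
    @pytest.mark.parametrize("theta,M", [(2.0, 10.0), (9.0, 1000.0)])
    def test_zero_below_maturity(self, theta, M):
        assert fecundity(2, demog(k_hat=3, theta=theta, M=M)) == 0

    def test_half_saturation_at_maturity_age(self):
        # f(k_hat) = floor(M/2) regardless of theta
        for theta in (1.0, 5.0, 9.0):
            assert fecundity(3, demog(k_hat=3, theta=theta, M=1000.0)) == 500

    def test_sigmoid_value_above_maturity(self):
        # 6^9 / (3^9 + 6^9) = 0.998055...; floor(1000 * that) = 998
        assert fecundity(6, demog(k_hat=3, theta=9.0, M=1000.0)) == 998

    def test_literal_mode_keeps_floor_only(self):
        d = demog(k_hat=3, theta=9.0, M=1000.0)
        # below maturity the raw sigmoid is positive for large M
        raw = math.floor(1000.0 * 2.0**9 / (3.0**9 + 2.0**9))
        assert fecundity(2, d, strict_maturity=False) == raw
        assert raw > 0

    def test_monotone_and_saturating(self):
        ages = np.arange(1, 51)
        f = fecundity(ages, demog(M=500.0))
        assert np.all(np.diff(f) >= 0)
        assert f[-1] <= 500.0


class TestDispersalMatrix:
    def test_line_grid_end_column(self):
        grid = build_rect_grid(1, 4)
        disp = dispersal_matrix(grid, DispersalParams(0.2, 0.1),
                                np.full(4, 0.5))
        # D = 1 + 0.2 + 2 * 0.05 = 1.3
        np.testing.assert_allclose(
            disp[:, 0], [1 / 1.3, 0.2 / 1.3, 0.05 / 1.3, 0.05 / 1.3],
            atol=5e-5)

    def test_all_adjacent_grid_without_ld(self):
        grid = build_rect_grid(2, 2)  # all cells mutually adjacent
        disp = dispersal_matrix(grid, DispersalParams(0.5, 0.0),
                                np.zeros(4))
        np.testing.assert_allclose(np.diag(disp), 0.4)
        off = disp[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.2)

    @pytest.mark.parametrize("seed", range(4))
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        grid = build_rect_grid(int(rng.integers(2, 8)), int(rng.integers(2, 8)))
        disp = dispersal_matrix(
            grid,
            DispersalParams(float(rng.uniform(0.05, 1.0)),
                            float(rng.uniform(0.0, 0.3))),
            rng.uniform(0, 1, grid.n_cells))
        np.testing.assert_allclose(disp.sum(axis=0), 1.0, atol=1e-12)

    def test_memory_lean_matches_dense(self):
        rng = np.random.default_rng(7)
        grid = build_rect_grid(6, 5)
        dp = DispersalParams(0.3, 0.08)
        urban = rng.uniform(0, 1, 30)
        seeds = rng.uniform(0, 500, 30)
        dense = dispersal_matrix(grid, dp, urban) @ seeds
        lean = apply_dispersal(grid, dp, urban, seeds)
        np.testing.assert_allclose(lean, dense, rtol=1e-12, atol=1e-9)


class TestSuitability:
    def test_zero_coefficients_give_half(self):
        x = np.zeros((3, 2))
        p = suitability(x, SuitabilityParams(np.zeros(3)))
        np.testing.assert_allclose(p, 0.5)

    def test_saturation_is_stable(self):
        p = suitability(np.array([[40.0]]), SuitabilityParams(np.array([0.0, 1.0])))
        assert abs(p[0] - 1.0) < 1e-12

    def test_dot_product_then_logistic(self):
        # beta = (1, 2) with x = -0.5 -> logistic(0) = 0.5
        p = suitability(np.array([[-0.5]]), SuitabilityParams(np.array([1.0, 2.0])))
        np.testing.assert_allclose(p, 0.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            suitability(np.zeros((2, 3)), SuitabilityParams(np.array([0.0, 1.0])))


class TestSelfRegulation:
    def test_free_slots_over_seed_supply(self):
        assert self_regulation_ratio(100.0, 40.0, 200.0) == pytest.approx(0.3)

    def test_no_free_slots(self):
        assert self_regulation_ratio(100.0, 150.0, 50.0) == 0.0

    def test_no_seeds_full_capacity(self):
        assert self_regulation_ratio(100.0, 0.0, 0.0) == 1.0

    def test_degenerate_zero_over_zero(self):
        assert self_regulation_ratio(0.0, 0.0, 0.0) == 0.0

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        c = self_regulation_ratio(rng.uniform(0, 100, 50),
                                  rng.uniform(0, 100, 50),
                                  rng.uniform(0, 100, 50))
        assert np.all((c >= 0) & (c <= 1))


class TestInitialState:
    def test_binomial_profile_rounded(self):
        init = InitialPopulationParams(np.array([0]), np.array([100.0]),
                                       np.array([0.5]))
        n = initial_state(init, K=4, n_cells=2)
        # 100 * BinomPMF(k; 4, .5) for k=1..4 = (25, 37.5, 25, 6.25)
        np.testing.assert_array_equal(n[0], [25, 38, 25, 6])
        np.testing.assert_array_equal(n[1], 0)

    def test_young_populations_for_small_age_ratio(self):
        init = InitialPopulationParams(np.array([0]), np.array([1000.0]),
                                       np.array([0.02]))
        n = initial_state(init, K=20, n_cells=1)
        ages = np.arange(1, 21)
        mean_age = (n[0] * ages).sum() / n[0].sum()
        assert mean_age < 2.0  # binomial mean K * age_ratio = 0.4

    def test_cell_outside_grid_rejected(self):
        init = InitialPopulationParams(np.array([5]), np.array([10.0]),
                                       np.array([0.3]))
        with pytest.raises(ValueError):
            initial_state(init, K=4, n_cells=3)


def _env_const(C, T, p_logit, urban=0.0):
    return EnvSeries(2000 + np.arange(T), np.full((C, T, 1), p_logit),
                     np.full((C, T), urban))


class TestStepTransition:
    def test_survival_only_no_recruitment(self):
        grid = build_rect_grid(1, 1)
        d = demog(rho=0.5, k_hat=3.0)
        n = np.zeros((1, 5))
        n[0, 0] = 10  # ten age-1 plants, below maturity
        n2 = step_transition(n, np.zeros((1, 1)), np.zeros(1), grid, d,
                             DispersalParams(0.2, 0.0),
                             SuitabilityParams(np.array([0.0, 1.0])))
        expected = np.zeros((1, 5))
        expected[0, 1] = 5  # round(0.5 * 10)
        np.testing.assert_array_equal(n2, expected)

    def test_total_mortality_extinguishes(self):
        grid = build_rect_grid(2, 2)
        d = demog(rho=1.0, k_hat=10.0)  # no survivors, no mature plants
        n = np.full((4, 6), 3.0)
        n2 = step_transition(n, np.zeros((4, 1)), np.zeros(4), grid, d,
                             DispersalParams(0.2, 0.0),
                             SuitabilityParams(np.array([0.0, 1.0])))
        # ages >= k_hat seeds could recruit; use all-young state instead
        n = np.zeros((4, 6))
        n[:, 0] = 5
        n2 = step_transition(n, np.zeros((4, 1)), np.zeros(4), grid, d,
                             DispersalParams(0.2, 0.0),
                             SuitabilityParams(np.array([0.0, 1.0])))
        assert n2.sum() == 0

    def test_rounding_is_half_away_from_zero(self):
        np.testing.assert_array_equal(
            round_half_away(np.array([0.5, 1.5, 2.5, -0.5])),
            [1.0, 2.0, 3.0, -1.0])


class TestTrajectoryProperties:
    def test_capacity_bound_on_simulated_trajectories(self, desk_bundle):
        b = desk_bundle
        from dynsdm.inference import _unpack_params

        init, d, dp, su, _ = _unpack_params(b.truth, b.model_data())
        traj, det = simulate_trajectory(init, b.env, b.grid, d, dp, su,
                                        K=b.config.K, return_details=True)
        tot = traj.sum(axis=2)  # (C, T)
        cap = det.capacity  # (C, T-1), capacity governing year t+1
        assert np.all(tot[:, 1:] <= cap + 1.0)

    def test_confinement_without_dispersal_paths(self, small_setup):
        s = small_setup
        disp = DispersalParams(ds=1e-12, dl=0.0)
        traj = simulate_trajectory(s["init"], s["env"], s["grid"], s["demog"],
                                   disp, s["suit"], K=s["K"])
        occupied = np.where(traj.sum(axis=(1, 2)) > 0)[0]
        np.testing.assert_array_equal(occupied, s["init"].cells)

    def test_zero_suitability_causes_extinction(self, small_setup):
        s = small_setup
        env = _env_const(9, 10, -60.0, urban=0.3)  # p ~ 0
        traj = simulate_trajectory(s["init"], env, s["grid"], s["demog"],
                                   s["disp"], SuitabilityParams(np.array([0.0, 1.0])),
                                   K=s["K"])
        assert traj[:, -1].sum() == 0

    def test_geometric_cohort_survival(self):
        grid = build_rect_grid(1, 1)
        env = _env_const(1, 8, -60.0)
        d = demog(rho=0.25, k_hat=20.0)
        init = InitialPopulationParams(np.array([0]), np.array([4000.0]),
                                       np.array([0.01]))
        traj = simulate_trajectory(init, env, grid, d, DispersalParams(0.1, 0.0),
                                   SuitabilityParams(np.array([0.0, 1.0])), K=30)
        n0 = traj[0, 0, 0]
        for a in range(1, 6):
            expect = n0 * 0.75**a
            assert abs(traj[0, a, a] - expect) <= a  # one rounding unit/step

    def test_more_ld_never_reduces_first_year_occupancy(self):
        grid = build_rect_grid(6, 6, 1.0)
        env = _env_const(36, 3, 2.0, urban=0.5)
        d = demog(rho=0.2, phi=500.0, M=200.0)
        init = InitialPopulationParams(np.array([14]), np.array([50.0]),
                                       np.array([0.3]))
        occ = []
        for dl in (0.0, 0.02, 0.1, 0.4):
            traj = simulate_trajectory(init, env, grid, d,
                                       DispersalParams(0.2, dl),
                                       SuitabilityParams(np.array([2.0, 0.0])),
                                       K=10)
            occ.append(int((traj[:, 1].sum(axis=1) > 0).sum()))
        assert all(b >= a for a, b in zip(occ, occ[1:]))

    def test_saturated_regime_matches_closed_form(self):
        # propagule-saturated, constant environment: the one-step change is
        # p*phi' - (p + rho - p*rho) * N_t within C units of rounding slack
        C = 9
        grid = build_rect_grid(3, 3, 1.0)
        env = _env_const(C, 3, 1.0, urban=0.5)
        d = demog(rho=0.4, phi=150.0, k_hat=2.0, theta=4.0, M=5000.0)
        su = SuitabilityParams(np.array([1.0, 0.0]))
        p = 1.0 / (1.0 + np.exp(-1.0))
        init = InitialPopulationParams(
            cells=np.arange(C), pop_ini=np.full(C, 120.0),
            age_ratio=np.full(C, 0.4))
        traj = simulate_trajectory(init, env, grid, d,
                                   DispersalParams(0.3, 0.1), su, K=10)
        for t in (0, 1):
            n_t = traj[:, t, :]
            # closed form uses plants below the terminal age class
            N_t = n_t[:, :-1].sum()
            phi_prime = p * 1.0 * d.phi * C
            predicted = p * phi_prime - (p + d.rho - p * d.rho) * N_t
            actual = traj[:, t + 1, :].sum() - n_t.sum()
            # require saturation for the formula to apply
            assert abs(actual - predicted) <= C

    def test_dense_and_lean_trajectories_identical(self, small_setup):
        s = small_setup
        a = simulate_trajectory(s["init"], s["env"], s["grid"], s["demog"],
                                s["disp"], s["suit"], K=s["K"],
                                dense_kernel=True)
        b = simulate_trajectory(s["init"], s["env"], s["grid"], s["demog"],
                                s["disp"], s["suit"], K=s["K"],
                                dense_kernel=False)
        np.testing.assert_array_equal(a, b)


class TestKernelProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        n_rows=st.integers(1, 6),
        n_cols=st.integers(1, 6),
        ds=st.floats(0.01, 2.0),
        dl=st.floats(0.0, 0.5),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_columns_always_stochastic(self, n_rows, n_cols, ds, dl, seed):
        grid = build_rect_grid(n_rows, n_cols)
        urban = np.random.default_rng(seed).uniform(0, 1, grid.n_cells)
        disp = dispersal_matrix(grid, DispersalParams(ds, dl), urban)
        np.testing.assert_allclose(disp.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(disp >= 0)

    @given(
        cap=st.floats(0, 1e6),
        surv=st.floats(0, 1e6),
        seeds=st.floats(0, 1e9),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_self_regulation_always_in_unit_interval(self, cap, surv, seeds):
        c = float(self_regulation_ratio(cap, surv, seeds))
        assert 0.0 <= c <= 1.0


def brute_force_trajectory(init, env, grid, d, dp, su, K):
    """Independent straight-loop reimplementation of the yearly update."""
    C, T = grid.n_cells, env.n_years
    # initial state
    n = np.zeros((C, T, K))
    from scipy.stats import binom as sp_binom

    for m, cell in enumerate(init.cells):
        for k in range(1, K + 1):
            pmf = sp_binom.pmf(k, K, init.age_ratio[m])
            v = init.pop_ini[m] * pmf
            n[cell, 0, k - 1] = math.floor(abs(v) + 0.5) * (1 if v >= 0 else -1)
    for t in range(T - 1):
        # survivors
        for i in range(C):
            for k in range(2, K + 1):
                v = (1 - d.rho) * n[i, t, k - 2]
                n[i, t + 1, k - 1] = math.floor(v + 0.5)
        # seed output per source cell
        out = np.zeros(C)
        for i in range(C):
            for k in range(1, K + 1):
                f = math.floor(d.M * k**d.theta / (d.k_hat**d.theta + k**d.theta))
                if k < d.k_hat:
                    f = 0
                out[i] += f * n[i, t, k - 1]
        # kernel entry by entry
        rain = np.zeros(C)
        for src in range(C):
            a = env.urban[src, t]
            n_nb = len(grid.neighbors[src])
            D = (C - 1 - n_nb) * dp.dl * a + n_nb * dp.ds + 1.0
            for tgt in range(C):
                if tgt == src:
                    w = 1.0 / D
                elif tgt in grid.neighbors[src]:
                    w = dp.ds / D
                else:
                    w = dp.dl * a / D
                rain[tgt] += w * out[src]
        # recruits
        for i in range(C):
            z = float(su.beta[0] + su.beta[1:] @ env.covariates[i, t + 1])
            p = 1.0 / (1.0 + math.exp(-z))
            cap = p * grid.terrestrial_prop[i] * d.phi
            surv = n[i, t + 1, 1:].sum()
            denom = max(cap, rain[i])
            c = 0.0 if denom <= 0 else min(max((cap - surv) / denom, 0.0), 1.0)
            n[i, t + 1, 0] = math.floor(rain[i] * c * p + 0.5)
    return n


def test_simulator_matches_brute_force_oracle(small_setup):
    """3x3 grid, 10 years: exact state-by-state equality with a from-scratch
    loop implementation of the same yearly update."""
    s = small_setup
    fast = simulate_trajectory(s["init"], s["env"], s["grid"], s["demog"],
                               s["disp"], s["suit"], K=s["K"])
    slow = brute_force_trajectory(s["init"], s["env"], s["grid"], s["demog"],
                                  s["disp"], s["suit"], s["K"])
    assert fast.sum() > 0  # the scenario is not trivially empty
    np.testing.assert_array_equal(fast, slow)
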