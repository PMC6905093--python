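import math

import numpy as np
import pytest

from neutrogame import (
    CAConfig,
    CellState,
    ITMScheme,
    ParameterTuple,
    Strategy,
    build_payoff_matrix,
    init_lattice,
    moore_neighborhood,
    remaining_itms_ca,
    run,
    sample_parameter_space,
    step,
    strategy_fitness,
    sweep_ca,
)


def _config(data_tuple, **kwargs):
    kwargs.setdefault("itms_initial", 0.0)
    kwargs.setdefault("seed", 1)
    return CAConfig(parameters=data_tuple, **kwargs)


class TestInitLattice:
    def test_all_cells_start_activated(self, data_tuple):
        state = init_lattice(_config(data_tuple, side=50))
        assert state.grid.shape == (50, 50)
        assert np.all(state.grid == CellState.ACTIVATED)
        assert state.activated == 2500

    def test_minimal_lattice(self, data_tuple):
        state = init_lattice(_config(data_tuple, side=2))
        assert state.activated == 4

    def test_pool_transform_flag(self, data_tuple):
        raw = init_lattice(_config(data_tuple, itms_initial=500.0))
        powered = init_lattice(_config(data_tuple, itms_initial=500.0, apply_power_k=True))
        assert raw.global_pool == 500.0
        assert powered.global_pool == pytest.approx(500.0**0.0929, rel=1e-12)
        assert init_lattice(_config(data_tuple, itms_initial=0.0)).global_pool == 0.0


class TestMooreNeighborhood:
    def test_interior_site(self):
        neigh = moore_neighborhood((10, 10), 50)
        assert len(neigh) == 8
        assert (10, 10) not in neigh
        assert all(max(abs(r - 10), abs(c - 10)) == 1 for r, c in neigh)

    def test_corner_wraps_around_torus(self):
        neigh = moore_neighborhood((0, 0), 50)
        assert len(set(neigh)) == 8
        rows = {r for r, _ in neigh}
        cols = {c for _, c in neigh}
        assert rows == {49, 0, 1} and cols == {49, 0, 1}

    def test_three_by_three_torus_reaches_every_other_site(self):
        """Brute-force oracle: toroidal Chebyshev distance <= 1 on a 3x3 grid."""
        for site in [(0, 0), (1, 1), (2, 0)]:
            neigh = set(moore_neighborhood(site, 3))
            brute = {
                (r, c)
                for r in range(3)
                for c in range(3)
                if (r, c) != site
                and max(
                    min(abs(r - site[0]), 3 - abs(r - site[0])),
                    min(abs(c - site[1]), 3 - abs(c - site[1])),
                )
                <= 1
            }
            assert neigh == brute == {
                (r, c) for r in range(3) for c in range(3) if (r, c) != site
            }


class TestRemainingItms:
    def test_global_power_term_before_any_decision(self, constants):
        """With n = 0 the undecided ledger is empty and the transformed pool
        at the fatal dose is 500^k."""
        t = ParameterTuple(alpha=1.0, b_apoptosis=1e-5, c_necrosis=1e-5,
                           m=constants.m_lower_bound, n=0.0)
        cfg = CAConfig(parameters=t, itms_initial=500.0, apply_power_k=True, seed=0)
        state = init_lattice(cfg)
        value = remaining_itms_ca(state, (0, 0), Strategy.APOPTOSIS, cfg)
        assert value == pytest.approx(1.7814, abs=2e-4)

    def test_global_pool_bookkeeping_identity(self, data_tuple):
        cfg = _config(data_tuple, side=10, itms_initial=7.0)
        state = init_lattice(cfg)
        for _ in range(100):
            step(state, cfg)
        expected = (
            cfg.initial_pool
            - data_tuple.m * state.decided_necrotic
            - data_tuple.n * state.decided_apoptotic
        )
        assert state.global_pool == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_local_empty_neighborhood_without_default_booking(self, data_tuple):
        cfg = _config(data_tuple, scheme=ITMScheme.LOCAL, undecided_neutralize=False)
        state = init_lattice(cfg)
        value = remaining_itms_ca(state, (5, 5), Strategy.NECROSIS, cfg)
        assert value == pytest.approx(-data_tuple.m, rel=1e-12)

    def test_local_empty_neighborhood_with_default_booking(self, data_tuple):
        cfg = _config(data_tuple, scheme=ITMScheme.LOCAL)
        state = init_lattice(cfg)
        value = remaining_itms_ca(state, (5, 5), Strategy.NECROSIS, cfg)
        assert value == pytest.approx(-data_tuple.m - 8 * data_tuple.n, rel=1e-12)

    def test_floor_clamps_at_zero(self, data_tuple):
        cfg = _config(data_tuple, scheme=ITMScheme.LOCAL, floor_pool_at_zero=True)
        state = init_lattice(cfg)
        assert remaining_itms_ca(state, (5, 5), Strategy.NECROSIS, cfg) == 0.0


class TestStrategyFitness:
    def test_no_decided_neighbors_zero_payoffs(self, constants):
        t = ParameterTuple(alpha=1.0, b_apoptosis=0.0, c_necrosis=0.0,
                           m=0.0015, n=0.0008)
        cfg = CAConfig(parameters=t, itms_initial=2.0, seed=0)
        state = init_lattice(cfg)
        for strategy in Strategy:
            expected = -math.exp(
                t.alpha * remaining_itms_ca(state, (3, 3), strategy, cfg)
            )
            assert strategy_fitness(state, (3, 3), strategy, cfg) == pytest.approx(
                expected, rel=1e-12
            )

    def test_uniform_apoptotic_neighborhood(self, data_tuple):
        cfg = _config(data_tuple, side=5)
        state = init_lattice(cfg)
        grid = state.grid
        for r, c in moore_neighborhood((2, 2), 5):
            grid[r, c] = CellState.APOPTOTIC
        state.decided_apoptotic = 8
        state.global_pool -= 8 * data_tuple.n
        mat = build_payoff_matrix(data_tuple.payoff_params)
        cost = math.exp(
            data_tuple.alpha
            * remaining_itms_ca(state, (2, 2), Strategy.APOPTOSIS, cfg)
        )
        assert strategy_fitness(state, (2, 2), Strategy.APOPTOSIS, cfg) == pytest.approx(
            8 * mat.D - cost, rel=1e-12
        )

    def test_fitness_difference_identity_on_random_states(self, data_tuple):
        """f(APO) - f(NEC) = (b+c) d + exp(aR_nec) - exp(aR_apo) mid-run."""
        cfg = _config(data_tuple, side=10, itms_initial=3.0, seed=9)
        state = init_lattice(cfg)
        for _ in range(40):
            step(state, cfg)
        flat_candidates = np.flatnonzero(state.grid.ravel() == CellState.ACTIVATED)
        for flat in flat_candidates[:10]:
            site = (int(flat) // 10, int(flat) % 10)
            neigh = state.grid.ravel()[
                [r * 10 + c for r, c in moore_neighborhood(site, 10)]
            ]
            d = int(np.sum(neigh != CellState.ACTIVATED))
            diff = strategy_fitness(state, site, Strategy.APOPTOSIS, cfg) - strategy_fitness(
                state, site, Strategy.NECROSIS, cfg
            )
            expected = (
                data_tuple.bc_sum * d
                + math.exp(
                    data_tuple.alpha
                    * remaining_itms_ca(state, site, Strategy.NECROSIS, cfg)
                )
                - math.exp(
                    data_tuple.alpha
                    * remaining_itms_ca(state, site, Strategy.APOPTOSIS, cfg)
                )
            )
            assert diff == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_overflowing_cost_flagged(self, data_tuple):
        cfg = _config(data_tuple, itms_initial=1e6)
        state = init_lattice(cfg)
        assert strategy_fitness(state, (0, 0), Strategy.NECROSIS, cfg) == -math.inf


class TestStep:
    def test_each_step_resolves_exactly_one_cell(self, data_tuple):
        cfg = _config(data_tuple, side=5)
        state = init_lattice(cfg)
        for expected_left in range(24, -1, -1):
            step(state, cfg)
            assert state.activated == expected_left
        with pytest.raises(Exception):
            step(state, cfg)

    def test_exact_tie_takes_apoptosis(self):
        """b = c = 0 with m = n makes both fitnesses identical everywhere."""
        t = ParameterTuple(alpha=1.0, b_apoptosis=0.0, c_necrosis=0.0, m=0.001, n=0.001)
        cfg = CAConfig(parameters=t, itms_initial=5.0, side=5, seed=3)
        result = run(cfg)
        assert result.percent_apoptosis == 100.0

    def test_fixed_seed_reproduces_decision_sequence(self, data_tuple):
        cfg = _config(data_tuple, side=10, itms_initial=2.0, seed=77)
        r1, r2 = run(cfg), run(cfg)
        assert np.array_equal(r1.final_grid, r2.final_grid)
        assert np.array_equal(
            r1.cumulative_necrotic_per_step, r2.cumulative_necrotic_per_step
        )


class TestRun:
    def test_conservation_at_termination(self, data_tuple):
        for scheme in ITMScheme:
            result = run(_config(data_tuple, side=50, itms_initial=10.0, scheme=scheme))
            necrotic = int(np.sum(result.final_grid == CellState.NECROTIC))
            apoptotic = int(np.sum(result.final_grid == CellState.APOPTOTIC))
            assert necrotic + apoptotic == 2500
            assert result.percent_necrosis + result.percent_apoptosis == pytest.approx(100.0)
            assert len(result.cumulative_necrotic_per_step) == 2500

    def test_cumulative_counts_monotone_with_unit_increments(self, data_tuple):
        result = run(_config(data_tuple, side=20, itms_initial=5.0))
        increments = np.diff(result.cumulative_necrotic_per_step, prepend=0)
        assert set(np.unique(increments)) <= {0, 1}

    def test_snapshots_at_requested_fractions(self, data_tuple):
        cfg = _config(
            data_tuple, side=10, snapshot_fractions=(0.0, 0.25, 0.5, 0.75, 1.0)
        )
        result = run(cfg)
        assert sorted(result.snapshots) == [0, 25, 50, 75, 100]
        assert np.all(result.snapshots[0] == CellState.ACTIVATED)
        assert np.array_equal(result.snapshots[100], result.final_grid)
        assert int(np.sum(result.snapshots[50] != CellState.ACTIVATED)) == 50

    def test_zero_cost_degenerates_to_all_apoptosis(self, data_tuple):
        """Without the ITM cost, apoptosis dominates every decision (the
        deadlock structure plus the tie rule)."""
        result = run(_config(data_tuple, side=20, itms_initial=500.0, zero_cost=True))
        assert result.percent_apoptosis == 100.0

    def test_necrosis_happens_early_under_global_sensing(self, data_tuple):
        """At zero dose the ~17% necrotic commitments all happen at the start;
        at the fatal dose the early rate is at least the late rate."""
        zero = run(_config(data_tuple, side=50, itms_initial=0.0, seed=5))
        quarter = 2500 // 4
        early = zero.cumulative_necrotic_per_step[quarter - 1]
        late = (
            zero.cumulative_necrotic_per_step[-1]
            - zero.cumulative_necrotic_per_step[3 * quarter - 1]
        )
        assert early > late
        fatal = run(_config(data_tuple, side=50, itms_initial=500.0, seed=5))
        early_f = fatal.cumulative_necrotic_per_step[quarter - 1]
        late_f = (
            fatal.cumulative_necrotic_per_step[-1]
            - fatal.cumulative_necrotic_per_step[3 * quarter - 1]
        )
        assert early_f >= late_f


class TestSweep:
    def test_single_run_has_zero_std(self, data_tuple, constants):
        table = sweep_ca([data_tuple], [0.0], [1], constants=constants, side=10)
        assert table.loc[0, "std_percent_necrosis"] == 0.0
        assert table.loc[0, "n_runs"] == 1

    def test_global_dose_response_is_non_decreasing(self, constants):
        tuples = sample_parameter_space(5, seed=2, constants=constants)
        table = sweep_ca(
            tuples, [0.0, 10.0, 100.0, 500.0], [0], scheme=ITMScheme.GLOBAL,
            constants=constants, side=50,
        )
        means = table["mean_percent_necrosis"].to_numpy()
        stds = table["std_percent_necrosis"].to_numpy()
        assert all(
            means[i + 1] >= means[i] - 2 * max(stds[i], stds[i + 1])
            for i in range(len(means) - 1)
        )

    def test_local_scheme_flat_across_doses(self, constants):
        tuples = sample_parameter_space(5, seed=2, constants=constants)
        table = sweep_ca(
            tuples, [0.0, 500.0], [0], scheme=ITMScheme.LOCAL,
            constants=constants, side=50,
        )
        means = table["mean_percent_necrosis"].to_numpy()
        assert abs(means[1] - means[0]) <= 15.0
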