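import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import demicdiff as dd
from demicdiff.ca import CAState

from _oracles import logistic_ode_population, ring_expansion_arrival

K_CELL = 2500.0  # 1 person/km^2 on a 50-km cell


def _state(population, suitable=None, date=4970.0):
    population = np.asarray(population, dtype=float)
    geom = dd.GridGeometry(
        n_rows=population.shape[0], n_cols=population.shape[1]
    )
    if suitable is None:
        suitable = np.ones(population.shape, dtype=bool)
    arrival = np.where(population > 0, 5000.0, np.nan)
    return CAState(
        geometry=geom,
        population=population.copy(),
        arrival=arrival,
        current_date=date,
        suitable=np.asarray(suitable, dtype=bool),
    )


class TestLogisticGrowth:
    def test_fixed_points_at_zero_and_k(self):
        assert dd.logistic_growth(0.0, K_CELL, 0.025, 30.0) == 0.0
        assert dd.logistic_growth(K_CELL, K_CELL, 0.025, 30.0) == K_CELL

    def test_no_growth_when_rate_is_zero(self):
        assert dd.logistic_growth(123.4, K_CELL, 0.0, 30.0) == pytest.approx(
            123.4
        )

    def test_closed_form_matches_ode_integration(self):
        # 0.5/(0.5*exp(-0.75)+0.5) ~ 0.6792 for K=1
        got = dd.logistic_growth(0.5, 1.0, 0.025, 30.0)
        assert got == pytest.approx(0.67918, abs=1e-5)
        assert got == pytest.approx(
            logistic_ode_population(0.5, 1.0, 0.025, 30.0), rel=1e-8
        )

    def test_population_above_k_decays_toward_k(self):
        n1 = dd.logistic_growth(2 * K_CELL, K_CELL, 0.025, 30.0)
        assert K_CELL < n1 < 2 * K_CELL

    @given(st.floats(min_value=1e-3, max_value=2.0))
    def test_monotone_toward_k_from_either_side(self, n0):
        n1 = dd.logistic_growth(n0, 1.0, 0.025, 30.0)
        if n0 < 1.0:
            assert n0 < n1 <= 1.0
        elif n0 > 1.0:
            assert 1.0 <= n1 < n0


class TestEmigrationRate:
    def test_rate_at_carrying_capacity_is_epsilon(self):
        assert dd.emigration_rate(K_CELL, K_CELL, 0.30, 1.0) == 0.30

    def test_linear_density_dependence_at_gamma_one(self):
        assert dd.emigration_rate(K_CELL / 2, K_CELL, 0.30, 1.0) == 0.15

    def test_quadratic_shape(self):
        assert dd.emigration_rate(K_CELL / 2, K_CELL, 0.30, 2.0) == 0.075

    def test_capped_at_one(self):
        assert dd.emigration_rate(10 * K_CELL, K_CELL, 0.30, 1.0) == 1.0


class TestDisperse:
    def test_lone_cell_splits_equally_among_eight_neighbours(self):
        pop = np.zeros((3, 3))
        pop[1, 1] = K_CELL
        state = _state(pop)
        out = dd.disperse(state, dd.CAParams())
        migrants = 0.30 * K_CELL
        expected = migrants / 8
        for cell in [(0, 0), (0, 1), (2, 2), (1, 0)]:
            assert out.population[cell] == pytest.approx(expected)
        assert out.population[1, 1] == pytest.approx(K_CELL - migrants)
        assert out.arrival[0, 0] == state.current_date

    def test_saturated_neighbours_are_skipped(self):
        pop = np.zeros((3, 3))
        pop[1, 1] = K_CELL
        pop[0, 0] = pop[0, 1] = pop[0, 2] = K_CELL  # 3 of 8 saturated
        state = _state(pop)
        out = dd.disperse(state, dd.CAParams())
        migrants = 0.30 * K_CELL
        # row-2 targets receive only the centre cell's flow, one fifth each
        # (the saturated row-0 cells emit too, but only reach row 1)
        for cell in [(2, 0), (2, 1), (2, 2)]:
            assert out.population[cell] == pytest.approx(migrants / 5)
        # saturated cells are not targets: they only lose their own migrants
        assert out.population[1, 1] == pytest.approx(K_CELL - migrants)

    def test_fully_blocked_cell_keeps_its_migrants(self):
        pop = np.full((3, 3), K_CELL)
        state = _state(pop)
        out = dd.disperse(state, dd.CAParams())
        np.testing.assert_array_equal(out.population, pop)

    def test_population_is_conserved(self):
        rng = np.random.default_rng(17)
        pop = rng.uniform(0, K_CELL, size=(8, 8))
        pop[rng.random((8, 8)) < 0.4] = 0.0
        suitable = rng.random((8, 8)) < 0.8
        pop[~suitable] = 0.0
        state = _state(pop, suitable)
        out = dd.disperse(state, dd.CAParams())
        assert out.population.sum() == pytest.approx(pop.sum(), rel=1e-12)
        assert np.all(out.population >= 0)

    def test_no_flow_onto_unsuitable_cells(self):
        pop = np.zeros((3, 3))
        pop[1, 1] = K_CELL
        suitable = np.ones((3, 3), dtype=bool)
        suitable[0, :] = False
        out = dd.disperse(_state(pop, suitable), dd.CAParams())
        assert np.all(out.population[0, :] == 0.0)


class TestLeapfrogTargets:
    def _line_state(self):
        # a single suitable column surrounded by unsuitable terrain,
        # plus a distant suitable cell two columns away (100 km)
        suitable = np.zeros((7, 7), dtype=bool)
        suitable[:, 1] = True
        suitable[3, 3] = True
        pop = np.zeros((7, 7))
        pop[:, 1] = K_CELL  # whole line saturated
        return _state(pop, suitable)

    def test_interior_cell_of_large_block_never_leapfrogs(self):
        suitable = np.ones((7, 7), dtype=bool)
        pop = np.full((7, 7), K_CELL)
        state = _state(pop, suitable)
        assert dd.leapfrog_targets(state, (3, 3), dd.CAParams()) == set()

    def test_blocked_border_cell_jumps_over_the_gap(self):
        state = self._line_state()
        targets = dd.leapfrog_targets(state, (3, 1), dd.CAParams())
        assert targets == {(3, 3)}

    def test_cells_beyond_the_radius_are_not_targets(self):
        suitable = np.zeros((7, 9), dtype=bool)
        suitable[:, 1] = True
        suitable[3, 5] = True  # 4 columns = 200 km away
        pop = np.zeros((7, 9))
        pop[:, 1] = K_CELL
        state = _state(pop, suitable)
        assert dd.leapfrog_targets(state, (3, 1), dd.CAParams()) == set()

    def test_available_neighbour_suppresses_leapfrogging(self):
        state = self._line_state()
        state.population[2, 1] = 0.5 * K_CELL  # an unsaturated neighbour
        assert dd.leapfrog_targets(state, (3, 1), dd.CAParams()) == set()

    def test_disperse_routes_blocked_migrants_through_leapfrog(self):
        state = self._line_state()
        out = dd.disperse(state, dd.CAParams())
        # every line cell is blocked; only (3,1) has the distant target
        assert out.population[3, 3] > 0
        assert out.arrival[3, 3] == state.current_date
        assert out.population.sum() == pytest.approx(
            state.population.sum(), rel=1e-12
        )


class TestApplyEnvironment:
    def test_unchanged_mask_is_identity(self):
        pop = np.zeros((3, 3))
        pop[1, 1] = 100.0
        state = _state(pop)
        out, extinct = dd.apply_environment(
            state, state.suitable.copy(), dd.CAParams()
        )
        np.testing.assert_array_equal(out.population, state.population)
        assert extinct == 0.0

    def test_stranded_population_splits_among_available_neighbours(self):
        pop = np.zeros((3, 3))
        pop[1, 1] = 100.0
        state = _state(pop)
        new_mask = np.zeros((3, 3), dtype=bool)
        new_mask[0, 1] = new_mask[2, 1] = True  # two refuges
        out, extinct = dd.apply_environment(state, new_mask, dd.CAParams())
        assert out.population[1, 1] == 0.0
        assert out.population[0, 1] == pytest.approx(50.0)
        assert out.population[2, 1] == pytest.approx(50.0)
        assert extinct == 0.0

    def test_isolated_population_goes_extinct_and_ledger_balances(self):
        pop = np.zeros((9, 9))
        pop[4, 4] = 321.0
        state = _state(pop)
        new_mask = np.zeros((9, 9), dtype=bool)  # nothing suitable anywhere
        out, extinct = dd.apply_environment(state, new_mask, dd.CAParams())
        assert extinct == pytest.approx(321.0)
        assert out.population.sum() == pytest.approx(0.0)
        # arrival records are never erased
        assert out.arrival[4, 4] == 5000.0

    def test_relocation_falls_back_to_leapfrog(self):
        pop = np.zeros((7, 7))
        pop[3, 1] = 80.0
        suitable = np.zeros((7, 7), dtype=bool)
        suitable[3, 1] = True
        state = _state(pop, suitable)
        new_mask = np.zeros((7, 7), dtype=bool)
        new_mask[3, 3] = True  # only refuge: 100 km away
        out, extinct = dd.apply_environment(state, new_mask, dd.CAParams())
        assert extinct == 0.0
        assert out.population[3, 3] == pytest.approx(80.0)


class TestRunCa:
    def test_null_front_advances_one_cell_per_generation(
        self, homogeneous_series
    ):
        series = homogeneous_series(21)
        params = dd.CAParams(suitable_codes=frozenset({1}))
        result = dd.run_ca(series, params, (10, 10))
        oracle = ring_expansion_arrival(
            np.ones((21, 21), dtype=bool), (10, 10), 5000.0, 500.0, 30.0
        )
        np.testing.assert_array_equal(result.arrival.arrival, oracle)

    def test_front_follows_a_one_cell_line(self):
        geom = dd.GridGeometry(n_rows=3, n_cols=12)
        codes = np.full((3, 12), 2)
        codes[1, :] = 1
        series = dd.LandscapeSeries(
            {5000.0: dd.BiomeRaster(geometry=geom, codes=codes)}
        )
        params = dd.CAParams(suitable_codes=frozenset({1}))
        result = dd.run_ca(series, params, (1, 0))
        got = result.arrival.arrival[1, :]
        np.testing.assert_array_equal(
            got, 5000.0 - 30.0 * np.arange(12)
        )

    def test_runs_are_bit_identical(self, reference):
        again = dd.run_ca(reference.series, reference.params, reference.origin)
        np.testing.assert_array_equal(
            again.arrival.arrival, reference.result.arrival.arrival
        )
        np.testing.assert_array_equal(
            again.population, reference.result.population
        )

    def test_unsuitable_origin_rejected(self, homogeneous_series):
        series = homogeneous_series(5, code=2)
        params = dd.CAParams(suitable_codes=frozenset({1}))
        with pytest.raises(ValueError, match="origin"):
            dd.run_ca(series, params, (2, 2))

    def test_trajectory_tracks_total_population(self, homogeneous_series):
        series = homogeneous_series(9)
        params = dd.CAParams(suitable_codes=frozenset({1}), end=3500.0)
        result = dd.run_ca(series, params, (4, 4))
        assert result.trajectory.iloc[-1]["total_population"] == pytest.approx(
            result.population.sum()
        )
        # while every cell is below K, growth only adds people (dispersal
        # conserves); later the overshoot-and-relax cycle may dip totals
        totals = result.trajectory["total_population"].to_numpy()
        assert np.all(np.diff(totals[:10]) > 0)
        assert np.all(totals > 0)

    def test_arrival_dates_never_predate_the_start(self, reference):
        arr = reference.result.arrival.arrival
        assert np.nanmax(arr) <= reference.params.start
        assert np.nanmin(arr) >= reference.params.end
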