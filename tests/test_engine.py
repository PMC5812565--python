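"""Hopping rules, the recursive two-pass update, and run bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import crowddiff as cd
from crowddiff.engine import step_population_nonrecursive
from conftest import make_population


class TestDirectionSampling:
    @pytest.mark.parametrize(
        "u, expected",
        [(0.10, "left"), (0.25, "right"), (0.49, "right"),
         (0.5, "up"), (0.74, "up"), (0.75, "down"), (0.9999, "down")],
    )
    def test_quartile_boundaries(self, u, expected):
        assert cd.sample_direction(u) == expected

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    def test_matches_quartile_oracle(self, u):
        quartile = min(int(u // 0.25), 3)
        assert cd.sample_direction(u) == ("left", "right", "up", "down")[quartile]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cd.sample_direction(1.0)


class TestEscapeProbability:
    @pytest.mark.parametrize(
        "energy, expected",
        [(0.0, 1.0), (2.0, 0.13534), (6.0, 2.4788e-3), (10.0, 4.5400e-5)],
    )
    def test_boltzmann_factor(self, energy, expected):
        assert cd.escape_probability(energy) == pytest.approx(expected, rel=1e-4)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            cd.escape_probability(-1.0)


class TestAttemptHop:
    def _world(self, cfg, kinds=()):
        fld = cd.build_obstacle_field(cfg, 0.0, 0.0)
        for (r, c, k) in kinds:
            fld.site_kind[r, c] = k
        return fld

    def test_cro_destination_reflects(self, small_cfg):
        fld = self._world(small_cfg, [(2, 3, cd.CRO)])
        pop = make_population(small_cfg, [2], [2], fld)
        out = cd.attempt_hop(0, "right", fld, pop)
        assert not out["moved"] and (pop.rows[0], pop.cols[0]) == (2, 2)

    def test_pro_destination_binds_when_not_reflected(self, small_cfg):
        fld = self._world(small_cfg, [(2, 3, cd.PRO)])
        fld.reflect_probability = 0.5
        pop = make_population(small_cfg, [2], [2], fld)
        out = cd.attempt_hop(0, "right", fld, pop, u_reflect=0.7)
        assert out["moved"] and out["newly_bound"] and bool(pop.bound[0])

    def test_pro_destination_reflects_on_low_variate(self, small_cfg):
        fld = self._world(small_cfg, [(2, 3, cd.PRO)])
        pop = make_population(small_cfg, [2], [2], fld)
        out = cd.attempt_hop(0, "right", fld, pop, u_reflect=0.3)
        assert not out["moved"] and not pop.bound[0]

    def test_pro_with_bound_tracer_acts_as_cro(self, small_cfg):
        fld = self._world(small_cfg, [(2, 3, cd.PRO)])
        pop = make_population(small_cfg, [2, 2], [2, 3], fld)
        assert bool(pop.bound[1])  # occupant of the PRO site starts bound
        out = cd.attempt_hop(0, "right", fld, pop, u_reflect=0.99)
        assert not out["moved"] and out["blocked_by_dt"]

    def test_empty_destination_moves_and_wraps(self, small_cfg, empty_field):
        pop = make_population(small_cfg, [0], [0], empty_field)
        out = cd.attempt_hop(0, "up", empty_field, pop)
        assert out["moved"]
        assert (pop.rows[0], pop.cols[0]) == (small_cfg.n_side - 1, 0)
        assert pop.disp_rows[0] == -1  # unwrapped displacement, not modulo


class TestRecursivePass:
    """The two-neighbour false-blocking configuration and its resolution."""

    def _two_tracers(self, cfg, fld, order):
        # DT1 at (2,2) headed right onto DT2 at (2,3); DT2 headed up.
        if order == "blocked-first":
            pop = make_population(cfg, [2, 2], [2, 3], fld)
            dirs = ["right", "up"]
        else:
            pop = make_population(cfg, [2, 2], [3, 2], fld)
            dirs = ["up", "right"]
        return pop, dirs

    @pytest.mark.parametrize("order", ["blocked-first", "mover-first"])
    def test_both_tracers_move_with_recursion(self, small_cfg, empty_field, order):
        pop, dirs = self._two_tracers(small_cfg, empty_field, order)
        out = cd.step_population_recursive(pop, empty_field, 0, directions=dirs)
        assert np.all(out.moved)
        assert not np.any(out.blocked_by_dt)
        occupied = set(zip(pop.rows.tolist(), pop.cols.tolist()))
        assert occupied == {(1, 3), (2, 3)}  # same set under either order

    def test_single_pass_reproduces_order_artifact(self, small_cfg, empty_field):
        pop, dirs = self._two_tracers(small_cfg, empty_field, "blocked-first")
        out = step_population_nonrecursive(pop, empty_field, 0, directions=dirs)
        assert out.moved.tolist() == [False, True]
        assert out.blocked_by_dt.tolist() == [True, False]

    def test_fully_packed_lattice_is_frozen(self, small_cfg, empty_field):
        n = small_cfg.n_side
        rows, cols = np.divmod(np.arange(n * n), n)
        pop = make_population(small_cfg, rows, cols, empty_field)
        out = cd.step_population_recursive(pop, empty_field, 0)
        assert not np.any(out.moved)
        assert np.all(pop.disp_rows == 0) and np.all(pop.disp_cols == 0)

    def test_pass_two_rebinds_on_vacated_pro(self, small_cfg):
        # DT1 aims at a PRO occupied by bound DT2; DT2 escapes and leaves;
        # in pass two DT1 re-applies partial reflection at the freed PRO.
        fld = cd.build_obstacle_field(small_cfg, 0.0, 0.0)
        fld.site_kind[2, 3] = cd.PRO
        fld.reflect_probability = 0.0  # retry always admitted
        pop = make_population(small_cfg, [2, 2], [2, 3], fld)
        out = cd.step_population_recursive(pop, fld, 0, directions=["right", "up"])
        assert np.all(out.moved)
        assert bool(pop.bound[0]) and not bool(pop.bound[1])


class TestPopulationInvariants:
    def test_exclusion_integrity_and_conservation(self):
        cfg = cd.LatticeConfig.desk(12)
        fld = cd.build_obstacle_field(cfg, a_cro=0.15, a_pro=0.15,
                                      binding_energy=2.0, rng_seed=3)
        pop = cd.place_tracers(cfg, fld, 0.3, True, 4)
        n0 = pop.n_tracers
        rng = np.random.default_rng(5)
        for _ in range(200):
            cd.step_population_recursive(pop, fld, rng)
            sites = pop.rows * cfg.n_side + pop.cols
            assert np.unique(sites).size == n0  # conservation + distinctness
            kinds = fld.site_kind[pop.rows, pop.cols]
            assert np.all(kinds != cd.CRO)
            assert np.array_equal(pop.bound, kinds == cd.PRO)

    def test_independent_tracers_can_share_sites(self, small_cfg, empty_field):
        pop = make_population(small_cfg, [2, 2], [2, 4], empty_field, exclusion=False)
        cd.step_population_independent(pop, empty_field, 0,
                                       directions=["right", "left"])
        assert (pop.rows[0], pop.cols[0]) == (pop.rows[1], pop.cols[1]) == (2, 3)

    def test_zero_tracers_is_noop(self, small_cfg, empty_field):
        pop = make_population(small_cfg, [], [], empty_field, exclusion=False)
        out = cd.step_population_independent(pop, empty_field, 0)
        assert out.moved.size == 0


class TestRunSimulation:
    def test_frame_bookkeeping(self, small_cfg, empty_field):
        pop = cd.place_tracers(small_cfg, empty_field, 0.05, False, 1)
        sched = cd.SimulationSchedule(measure_ms=2.0, record_interval_ms=1.0, seed=1)
        tr = cd.run_simulation(small_cfg, empty_field, pop, sched)
        assert tr.msd.shape == (2,)
        assert np.allclose(tr.times_ms, [1.0, 2.0])

    def test_identical_seed_identical_trajectory(self, small_cfg, empty_field):
        pop = cd.place_tracers(small_cfg, empty_field, 0.05, False, 1)
        sched = cd.SimulationSchedule(measure_ms=5.0, record_interval_ms=0.5, seed=17)
        a = cd.run_simulation(small_cfg, empty_field, pop.copy(), sched)
        b = cd.run_simulation(small_cfg, empty_field, pop.copy(), sched)
        assert np.array_equal(a.msd, b.msd)
        c = cd.run_simulation(small_cfg, empty_field, pop.copy(), sched, seed=18)
        assert not np.array_equal(a.msd, c.msd)

    def test_free_msd_matches_closed_form(self):
        # unobstructed independent tracers: <r^2> = 4 D t within 3 SE
        cfg = cd.LatticeConfig.desk(50)
        fld = cd.build_obstacle_field(cfg, 0, 0)
        pop = cd.place_tracers(cfg, fld, 1000 / cfg.n_sites, False, 2)
        sched = cd.SimulationSchedule(measure_ms=1.0, record_interval_ms=0.1, seed=3)
        tr = cd.run_simulation(cfg, fld, pop, sched)
        d = cfg.step_length_um**2 / (4 * cfg.time_step_ms)
        expected = 4 * d * tr.times_ms
        se = expected / np.sqrt(pop.n_tracers)
        assert np.all(np.abs(tr.msd - expected) < 3 * se)

    def test_bound_fraction_stationary_after_annealing(self):
        cfg = cd.LatticeConfig.desk(60)
        sched = cd.SimulationSchedule(anneal_ms=100.0, measure_ms=1.0,
                                      record_interval_ms=0.1, seed=9)
        fld = cd.build_obstacle_field(cfg, a_pro=0.3, binding_energy=2.0, rng_seed=1)
        pop = cd.place_tracers(cfg, fld, 500 / cfg.n_sites, False, 2)
        tr = cd.run_simulation(cfg, fld, pop, sched)
        ab = tr.anneal_bound_frac
        k = ab.size // 10
        early, late = ab[k:3 * k], ab[-2 * k:]  # skip the initial relaxation
        # equilibrated: drift between windows below sampling noise
        noise = np.sqrt(late.var() / late.size + early.var() / early.size)
        assert abs(late.mean() - early.mean()) < max(4 * noise, 0.02)

    def test_literal_escape_inequality_inverts_dwell_times(self):
        # with the literal reading, strong binding unbinds almost surely,
        # so the bound fraction collapses instead of saturating
        cfg = cd.LatticeConfig.desk(40)
        fld = cd.build_obstacle_field(cfg, a_pro=0.2, binding_energy=6.0, rng_seed=1)
        pop = cd.place_tracers(cfg, fld, 200 / cfg.n_sites, False, 2)
        sched = cd.SimulationSchedule(measure_ms=20.0, record_interval_ms=1.0, seed=4)
        conventional = cd.run_simulation(cfg, fld, pop.copy(), sched)
        literal = cd.run_simulation(cfg, fld, pop.copy(), sched, literal_escape=True)
        assert conventional.bound_frac[-1] > 0.9
        assert literal.bound_frac[-1] < 0.5
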