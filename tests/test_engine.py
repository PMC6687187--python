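import math

import numpy as np
import pytest

from latticetumour import engine
from latticetumour.engine import (
    MUT,
    WT,
    CellRecord,
    apply_treatment,
    gillespie_step,
    growth_curves,
    initialize,
    introduce_driver,
    place_daughter,
    run,
)
from latticetumour.params import ParameterError, SimulationParams

from conftest import small_run


class TestParams:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("grid_extent", 2),
            ("b", 0.0),
            ("d", -0.1),
            ("u", -1.0),
            ("a", 1.5),
            ("s", -0.5),
            ("kill_fraction", 1.0),
            ("driver_mode", "teleport"),
            ("dims", 4),
        ],
    )
    def test_invalid_parameter_rejected_naming_field(self, field, value):
        with pytest.raises(ParameterError) as exc:
            SimulationParams(**{field: value})
        assert field.split("_")[0] in str(exc.value) or field in str(exc.value)

    def test_unknown_field_rejected(self):
        with pytest.raises(ParameterError, match="unknown"):
            SimulationParams.from_dict({"uu": 3})


class TestInitialize:
    def test_founder_at_grid_centre(self):
        st = initialize(SimulationParams(grid_extent=400))
        cell = next(iter(st.cells.values()))
        assert cell.pos == (200, 200)
        assert st.n_cells == 1 and st.t == 0.0 and cell.clone == WT

    def test_smallest_valid_grid(self):
        st = initialize(SimulationParams(grid_extent=3))
        assert next(iter(st.cells.values())).pos == (1, 1)

    def test_founder_carries_no_mutations_by_default(self):
        st = initialize(SimulationParams(u=50.0, seed=1))
        assert st.lineage.next_mut_id == 0

    def test_3d_centre(self):
        st = initialize(SimulationParams(dims=3, grid_extent=21))
        assert next(iter(st.cells.values())).pos == (10, 10, 10)


class TestGillespie:
    def test_no_death_events_when_d_zero(self):
        st = initialize(SimulationParams(seed=5, u=0.0, grid_extent=101))
        labels = {gillespie_step(st) for _ in range(300)}
        assert not any(l.startswith("death") for l in labels)

    def test_event_channel_frequencies_match_propensity_ratio(self):
        # with rates b=1, d=0.5 the probability that the next event is a
        # death is d/(b+d) = 1/3 at every population size
        counts = {"birth": 0, "death": 0}
        n = 0
        for seed in range(20):  # restart if the founder lineage dies out
            st = initialize(SimulationParams(seed=seed, u=0.0, d=0.5, grid_extent=301))
            while n < 30000 and not st.extinct and not st.boundary_reached:
                label = gillespie_step(st)
                n += 1
                if label.startswith("death"):
                    counts["death"] += 1
                else:
                    counts["birth"] += 1
            if n >= 30000:
                break
        frac = counts["death"] / n
        assert abs(frac - 1.0 / 3.0) < 0.012  # ~4 sigma of Binomial(30000, 1/3)

    def test_population_changes_by_at_most_one_per_event(self):
        st = initialize(SimulationParams(seed=3, u=0.0, d=0.3, grid_extent=101))
        for _ in range(800):
            if st.extinct:
                break
            before = st.n_cells
            gillespie_step(st)
            assert abs(st.n_cells - before) <= 1

    def test_clock_is_nondecreasing(self):
        st = initialize(SimulationParams(seed=4, u=0.0, grid_extent=101))
        t = 0.0
        for _ in range(200):
            gillespie_step(st)
            assert st.t >= t
            t = st.t


class TestPlaceDaughter:
    def _state(self, a=1.0, grid=21, push_rule="rim"):
        return initialize(SimulationParams(seed=0, u=0.0, a=a, grid_extent=grid,
                                           push_rule=push_rule))

    def _add(self, st, pos, clone=WT):
        cell = CellRecord(cell_id=st._next_cell_id, pos=pos, clone=clone,
                          node=0, n_divisions=0)
        st._next_cell_id += 1
        st._register(cell)
        return cell

    def test_empty_neighbour_used_without_pushing(self):
        st = self._state()
        parent = next(iter(st.cells.values()))
        site = place_daughter(st, parent)
        assert site is not None
        assert max(abs(site[0] - 10), abs(site[1] - 10)) == 1

    def test_surrounded_parent_pushes_when_a_is_one(self):
        st = self._state(a=1.0)
        parent = next(iter(st.cells.values()))
        ring = [(9, 9), (9, 10), (9, 11), (10, 9), (10, 11), (11, 9), (11, 10), (11, 11)]
        neighbours = [self._add(st, p) for p in ring]
        site = place_daughter(st, parent)
        assert site is not None  # with a=1 every cell can always push
        assert st.grid[site] == 0  # freed for the daughter
        # exactly one ring cell was shifted one site outward
        moved = [c for c, p0 in zip(neighbours, ring) if c.pos != p0]
        assert len(moved) == 1

    def test_interior_cell_outside_rim_fails_division(self):
        # an interior surrounded cell with (R - r) > a*R may not push
        st = self._state(a=0.2)
        parent = next(iter(st.cells.values()))
        for dx in range(-3, 4):
            for dy in range(-3, 4):
                if (dx, dy) != (0, 0):
                    self._add(st, (10 + dx, 10 + dy))
        assert st.R == 3
        assert place_daughter(st, parent) is None  # r=0: (3-0) > 0.2*3

    def test_fully_occupied_ray_to_boundary_aborts_push(self):
        st = self._state(a=1.0, grid=7)
        parent = st.cells[st.grid[3, 3]]
        # occupy every site: any push direction hits the boundary
        for x in range(7):
            for y in range(7):
                if (x, y) != (3, 3):
                    self._add(st, (x, y))
        assert place_daughter(st, parent) is None


class TestDriver:
    def test_birth_increase_rates(self):
        st = initialize(SimulationParams(seed=1, s=3.0, t_driver=0.0, u=0.0,
                                         driver_mode="birth_increase"))
        introduce_driver(st)
        # 1 + s = (b_mut - d_mut)/(b_wt - d_wt) with b=1, d=0, s=3 -> b_mut=4
        assert st.b_mut == pytest.approx(4.0)
        assert st.d_mut == 0.0
        assert st.n_mut == 1 and st.driver_done

    def test_death_decrease_rates(self):
        st = initialize(SimulationParams(seed=1, s=3.0, d=0.8, t_driver=0.0, u=0.0,
                                         driver_mode="death_decrease"))
        introduce_driver(st)
        assert st.b_mut == pytest.approx(1.0)
        assert st.d_mut == pytest.approx(0.2)  # s = (1-0.2)/(1-0.8) - 1 = 3

    def test_push_increase_leaves_rates_and_flags_pushing(self):
        st = initialize(SimulationParams(seed=1, s=1.0, a=0.1, t_driver=0.0, u=0.0,
                                         driver_mode="push_increase"))
        introduce_driver(st)
        assert st.b_mut == st.params.b and st.d_mut == st.params.d
        assert st.mut_always_pushes

    def test_driver_fires_once_at_first_event_past_t_driver(self):
        st = small_run(seed=6, max_cells=300, u=0.0, t_driver=2.0, s=0.0)
        assert st.driver_done and not st.driver_skipped
        assert st.driver_time >= 2.0
        assert st.n_mut >= 1

    def test_driver_skipped_without_wt_cells(self):
        st = initialize(SimulationParams(seed=1, t_driver=0.0, u=0.0))
        st._switch_clone(next(iter(st.cells.values())), MUT)
        with pytest.warns(UserWarning, match="driver skipped"):
            introduce_driver(st)
        assert st.driver_skipped

    def test_neutral_marking_is_exchangeable(self):
        # with s=0 the marked clone is an arbitrary lineage label: its final
        # fraction times the population size at marking has mean 1
        vals = []
        for seed in range(40):
            st = small_run(seed=1000 + seed, max_cells=400, u=0.0,
                           t_driver=2.0, s=0.0)
            if st.driver_skipped or st.extinct:
                continue
            gc = growth_curves(st)
            at_driver = gc[gc.t >= st.driver_time].iloc[0]
            n0 = at_driver.n_total
            vals.append(st.n_mut / st.n_cells * n0)
        assert 0.5 < np.mean(vals) < 1.6


class TestRun:
    def test_exponential_growth_rate_matches_birth_rate(self):
        # log N(t) is linear with slope b - d = 1 under homogeneous growth
        slopes = []
        for seed in range(5):
            st = small_run(seed=30 + seed, max_cells=4000, u=0.0)
            gc = growth_curves(st)
            m = gc[gc.n_total > 100]
            slopes.append(np.polyfit(m.t, np.log(m.n_total), 1)[0])
        assert abs(np.mean(slopes) - 1.0) < 0.1

    def test_boundary_driven_growth_is_polynomial(self):
        # with a small rim the radius grows linearly: N ~ t^2 in 2D
        slopes = []
        for seed in range(3):
            st = small_run(seed=50 + seed, max_cells=2500, u=0.0, a=0.025)
            gc = growth_curves(st)
            m = gc[gc.n_total > 200]
            slopes.append(np.polyfit(np.log(m.t), np.log(m.n_total), 1)[0])
        assert 1.4 < np.mean(slopes) < 2.9
        # and the log-linear (exponential) fit is visibly concave: early
        # apparent growth rate exceeds the late one
        half = len(m) // 2
        early = np.polyfit(m.t[:half], np.log(m.n_total[:half]), 1)[0]
        late = np.polyfit(m.t[half:], np.log(m.n_total[half:]), 1)[0]
        assert early > late

    def test_same_seed_reproduces_run_exactly(self):
        p = dict(seed=7, max_cells=400, u=3.0, t_driver=3.0, s=1.0)
        a = small_run(**p)
        b = small_run(**p)
        assert a.t == b.t and a.n_cells == b.n_cells
        assert np.array_equal(a.grid, b.grid)
        assert a.lineage.parent == b.lineage.parent
        assert a.lineage.mut_n == b.lineage.mut_n

    def test_occupancy_registry_bijection(self, neutral_state):
        st = neutral_state
        occupied = np.argwhere(st.grid > 0)
        assert len(occupied) == st.n_cells
        for cid, cell in st.cells.items():
            assert st.grid[cell.pos] == cid

    def test_mutation_blocks_are_disjoint(self, neutral_state):
        # infinite sites: every mutation id belongs to exactly one lineage edge
        tree = neutral_state.lineage
        assert sum(tree.mut_n) == tree.next_mut_id
        starts = np.asarray(tree.mut_start)
        ends = starts + np.asarray(tree.mut_n)
        order = np.argsort(starts)
        assert np.all(ends[order][:-1] <= starts[order][1:])

    def test_mutation_count_tracks_divisions(self):
        # shared Pois(u) per division: mean mutations per cell = u * mean
        # generation count, within 5% at this population size
        st = small_run(seed=14, max_cells=4000, u=5.0)
        _, _, _, node, ndiv = st.as_arrays()
        cum = np.asarray(st.lineage.cum_mut)
        ratio = cum[node].mean() / (5.0 * ndiv.mean())
        assert abs(ratio - 1.0) < 0.05

    def test_radius_bookkeeping_matches_cell_positions(self, neutral_state):
        _, pos, _, _, _ = neutral_state.as_arrays()
        r = np.abs(pos - np.asarray(neutral_state.origin)).max(axis=1)
        assert neutral_state.R == r.max()


class TestTreatment:
    def test_zero_kill_is_identity(self, neutral_state):
        before = neutral_state.n_cells
        apply_treatment(neutral_state, 0.0)
        assert neutral_state.n_cells == before

    def test_99_percent_kill_and_regrowth(self):
        st = small_run(seed=60, max_cells=3000, u=0.0)
        n0 = st.n_cells
        apply_treatment(st, 0.99, rng=np.random.default_rng(1))
        assert st.n_cells == pytest.approx(0.01 * n0, rel=0.2)
        assert st.n_cells >= 1
        engine.resume(st, max_cells=n0)
        assert st.n_cells >= n0

    def test_treatment_releases_selected_clone(self):
        # killing 99% and regrowing increases the fitter clone's share on
        # average (competitive release)
        deltas = []
        for seed in range(20):
            st = small_run(seed=2000 + seed, max_cells=1200, u=0.0,
                           t_driver=4.5, s=3.0)
            if st.driver_skipped or st.n_mut == 0:
                continue
            before = st.n_mut / st.n_cells
            n0 = st.n_cells
            apply_treatment(st, 0.99)
            if st.n_mut == 0:  # clone wiped out by the bottleneck
                deltas.append(-before)
                continue
            engine.resume(st, max_cells=n0)
            deltas.append(st.n_mut / st.n_cells - before)
        assert np.mean(deltas) > 0


class TestGrowthCurves:
    def test_selected_clone_share_rises_after_driver(self, selective_state):
        gc = growth_curves(selective_state)
        post = gc[gc.n_mut > 0]
        share = (post.n_mut / post.n_total).to_numpy()
        # rising in trend: late mean share well above early mean share
        k = len(share) // 4
        assert share[-k:].mean() > share[:k].mean()

    def test_doubling_time_scaling(self, neutral_state):
        gc = growth_curves(neutral_state)
        m = gc[gc.n_total > 100]
        slope_doublings = np.polyfit(m.t / math.log(2), np.log2(m.n_total), 1)[0]
        assert slope_doublings == pytest.approx(1.0, rel=0.15)
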