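"""Model compilation, static/growing integration, events, snapshots."""

import numpy as np
import pytest

import tissuesim as ts
from tissuesim.division import DivisionSpec
from tissuesim.engine import (
    EngineError, ModelSpec, SpeciesDef, compile, run_growing, run_static,
    snapshot,
)
from tissuesim.intercellular import DiffusionArrow
from tissuesim.mechanics import GrowthSpec
from tissuesim.arrows import MassAction, parse_arrow


class TestCompile:
    def test_state_count_static(self, hex19):
        model = ts.brusselator_model(init_noise=0)
        sys = compile(model, hex19)
        assert sys.n_state == 2 * 19

    def test_state_count_growing(self, hex19):
        model = ModelSpec(reactions=ts.parse_arrow("A -> B", rate=MassAction(1.0)),
                          growth=GrowthSpec(pressure=0.1))
        sys = compile(model, hex19, mode="growing")
        assert sys.n_state == 2 * 19 + 2 * hex19.n_vertices + hex19.n_edges

    def test_fixed_species_excluded_from_state(self, hex19):
        model = ModelSpec(
            intercellular=[DiffusionArrow("Y", P_I=1.0)],
            species=[SpeciesDef("Y", initial=1.0, fixed="boundary")])
        sys = compile(model, hex19)
        n_boundary = int(sys.boundary_cells.sum())
        assert n_boundary == 12          # 2-ring hexagonal tissue
        assert sys.n_state == 19 - n_boundary

    def test_grow_arrow_rejected_in_static_mode(self, hex19):
        model = ModelSpec(growth=GrowthSpec(pressure=0.1))
        with pytest.raises(EngineError):
            compile(model, hex19, mode="static")

    def test_unresolved_symbol_raises(self, hex19):
        model = ModelSpec(reactions=parse_arrow("A -> B", rate=MassAction("k")))
        sys = compile(model, hex19)
        with pytest.raises(Exception):
            sys.rhs(0.0, np.zeros(sys.n_state))


class TestRunStatic:
    def test_empty_model_state_constant(self, hex19, rng):
        model = ModelSpec(species=[SpeciesDef("A")])
        init = rng.uniform(0, 1, (19, 1))
        traj = run_static(compile(model, hex19), (0, 10), init=init)
        assert np.allclose(traj.final().conc, init)

    def test_reversible_pair_equilibrates(self, unit_square):
        model = ModelSpec(reactions=parse_arrow("A <-> B", rate=(1.0, 1.0)),
                          species=[SpeciesDef("A", 1.0), SpeciesDef("B", 0.0)])
        traj = run_static(compile(model, unit_square), (0, 30))
        assert traj.final().conc[0] == pytest.approx([0.5, 0.5], abs=1e-6)
        sums = [s.conc.sum() for s in traj.samples]
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_dirichlet_fixed_species_stays_fixed(self, hex19):
        model = ModelSpec(
            reactions=parse_arrow("Y -> 0", rate=MassAction(1.0)),
            intercellular=[DiffusionArrow("Y", P_I=1.0)],
            species=[SpeciesDef("Y", initial=2.0, fixed="boundary")])
        sys = compile(model, hex19)
        traj = run_static(sys, (0, 20))
        Y = traj.field("Y")
        assert np.allclose(Y[sys.boundary_cells], 2.0)
        inner = ~sys.boundary_cells
        assert np.all(Y[inner] > 0) and np.all(Y[inner] < 2.0)

    def test_per_cell_bound_reaction(self, two_squares):
        model = ModelSpec(reactions=parse_arrow("0 -> A[1]", rate=MassAction(1.0)),
                          species=[SpeciesDef("A", 0.0)])
        traj = run_static(compile(model, two_squares), (0, 2.0))
        assert traj.final().conc[:, 0] == pytest.approx([0.0, 2.0], abs=1e-8)


class TestRunGrowing:
    def test_subthreshold_equilibrium_never_divides(self, unit_square):
        # P < 2k: perimeter caps at 8, area at 4; threshold above that
        model = ModelSpec(growth=GrowthSpec(pressure=1.0, spring=1.0),
                          division=DivisionSpec(mean=5.0, sd=0.0))
        traj = run_growing(model, unit_square, (0, 60), seed=0)
        assert traj.n_divisions() == 0
        assert traj.final().tissue.n_cells == 1

    def test_single_crossing_divides_once(self, unit_square):
        model = ModelSpec(growth=GrowthSpec(pressure=1.0, spring=1.0),
                          division=DivisionSpec(mean=2.0, sd=0.0))
        traj = run_growing(model, unit_square, (0, 25), seed=0,
                           max_divisions=1)
        assert traj.n_divisions() == 1
        assert traj.final().tissue.n_cells == 2
        rec = traj.lineage[0]
        assert rec.parent == 0 and rec.daughters == (1, 2)
        # event located where the area trajectory crosses the threshold
        pre = [s for s in traj.samples if s.tissue.n_cells == 1]
        areas = np.array([ts.compute_geometry(s.tissue).areas[0] for s in pre])
        assert areas.max() <= 2.0 + 1e-6

    def test_division_time_matches_area_crossing(self, unit_square):
        """Event location agrees with bisection on the closed-form area."""
        from scipy.optimize import brentq
        from scipy.integrate import solve_ivp
        model = ModelSpec(growth=GrowthSpec(pressure=1.0, spring=1.0),
                          division=DivisionSpec(mean=2.0, sd=0.0))
        traj = run_growing(model, unit_square, (0, 25), seed=0, max_divisions=1)
        t_div = traj.lineage[0].time
        cf = ts.square_cell_closed_form(1.0, 1.0, 4.0)
        sol = solve_ivp(lambda t, L: cf.perimeter_rate(L), (0, 25), [4.0],
                        dense_output=True, rtol=1e-12, atol=1e-12)
        t_oracle = brentq(lambda t: (sol.sol(t)[0] / 4) ** 2 - 2.0, 0.1, 25)
        assert t_div == pytest.approx(t_oracle, abs=1e-4)

    def test_identical_seeds_identical_lineage(self, unit_square):
        model = ModelSpec(growth=GrowthSpec(pressure=1.0, spring=1.0),
                          division=DivisionSpec(mean=1.5, sd=0.1))
        a = run_growing(model, unit_square, (0, 40), seed=42, max_divisions=4)
        b = run_growing(model, unit_square, (0, 40), seed=42, max_divisions=4)
        assert len(a.lineage) == len(b.lineage) == 4
        for ra, rb in zip(a.lineage, b.lineage):
            assert ra.time == rb.time
            assert ra.daughters == rb.daughters
            assert ra.thresholds == rb.thresholds
            assert np.array_equal(ra.wall, rb.wall)
        assert np.array_equal(a.final().tissue.V, b.final().tissue.V)

    def test_amount_conserved_through_divisions(self, unit_square):
        """A passive species' total amount survives growth + division."""
        model = ModelSpec(growth=GrowthSpec(pressure=1.0, spring=1.0),
                          division=DivisionSpec(mean=1.3, sd=0.0),
                          species=[SpeciesDef("X", initial=2.0)])
        traj = run_growing(model, unit_square, (0, 40), seed=1, max_divisions=5)
        assert traj.n_divisions() == 5
        fin = traj.final()
        g = ts.compute_geometry(fin.tissue)
        # no reactions: amount sum A_i [X_i] equals the initial 2.0 * 1.0
        assert (g.areas * fin.conc[:, 0]).sum() == pytest.approx(2.0, rel=1e-4)

    def test_recompilation_preserves_state_across_event(self, unit_square):
        """Daughters inherit the mother's (diluted) concentration unchanged:
        at the division event the area has grown from 1 to 2, so the passive
        species has diluted from 1.5 to 0.75, and both daughters carry it."""
        model = ModelSpec(growth=GrowthSpec(pressure=1.0, spring=1.0),
                          division=DivisionSpec(mean=2.0, sd=0.0),
                          species=[SpeciesDef("X", initial=1.5)])
        traj = run_growing(model, unit_square, (0, 25), seed=0, max_divisions=1)
        post = traj.final()
        assert post.tissue.n_cells == 2
        assert np.allclose(post.conc[:, 0], 0.75, atol=1e-4)
        g = ts.compute_geometry(post.tissue)
        assert (g.areas * post.conc[:, 0]).sum() == pytest.approx(1.5, rel=1e-4)

    def test_event_storm_aborts(self, unit_square):
        # threshold far below the current area: endless immediate redivision
        model = ModelSpec(growth=GrowthSpec(pressure=1.0, spring=1.0),
                          division=DivisionSpec(mean=1e-4, sd=0.0,
                                                floor_frac=1.0))
        with pytest.raises(EngineError):
            run_growing(model, unit_square, (0, 10), seed=0)


class TestSnapshot:
    def test_roundtrip_through_mesh_loader(self, tmp_path, unit_square):
        model = ModelSpec(growth=GrowthSpec(pressure=1.0, spring=1.0),
                          division=DivisionSpec(mean=1.5, sd=0.0),
                          species=[SpeciesDef("X", initial=1.0)])
        traj = run_growing(model, unit_square, (0, 30), seed=0,
                           max_divisions=3)
        paths = snapshot(traj, [0.0, 30.0], tmp_path, prefix="s")
        tis = ts.load_tissue(tmp_path / "s_t0.tissue.csv", "FLAT")
        assert tis.n_cells == 1
        g0 = ts.compute_geometry(tis)
        assert g0.areas[0] == pytest.approx(1.0)
        # concentration table row count equals the cell count at that time
        rows = (tmp_path / "s_t0.conc.csv").read_text().strip().splitlines()
        assert len(rows) - 1 == tis.n_cells

    def test_lineage_traces_to_root(self, tmp_path, unit_square):
        model = ModelSpec(growth=GrowthSpec(pressure=1.0, spring=1.0),
                          division=DivisionSpec(mean=1.3, sd=0.05))
        traj = run_growing(model, unit_square, (0, 40), seed=3,
                           max_divisions=6)
        parent_of = {}
        for rec in traj.lineage:
            for d in rec.daughters:
                parent_of[d] = rec.parent
        for uid in traj.final().cell_uids:
            u = int(uid)
            seen = set()
            while u in parent_of:
                assert u not in seen
                seen.add(u)
                u = parent_of[u]
            assert u == 0   # every cell descends from the single root cell

    def test_sample_times_strictly_increasing(self, unit_square):
        model = ModelSpec(growth=GrowthSpec(pressure=1.0, spring=1.0),
                          division=DivisionSpec(mean=1.4, sd=0.0))
        traj = run_growing(model, unit_square, (0, 30), seed=0,
                           max_divisions=3)
        assert np.all(np.diff(traj.times) > 0)


class TestSolverRobustness:
    def test_tolerance_independence_on_pattern(self, hex19):
        """Default vs tight tolerances agree on the final diffusion state."""
        init = np.zeros((19, 1))
        init[0, 0] = 1.0
        model = ModelSpec(intercellular=[DiffusionArrow("X", P_I=0.5)],
                          species=[SpeciesDef("X")])
        a = run_static(compile(model, hex19), (0, 50), init=init)
        b = run_static(compile(model, hex19), (0, 50), init=init,
                       rtol=1e-9, atol=1e-12)
        assert np.allclose(a.final().conc, b.final().conc, rtol=1e-3)
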