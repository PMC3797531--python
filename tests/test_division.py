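"""Wall placement (Errera and potential models) and mesh surgery."""

import numpy as np
import pytest

from conftest import random_convex_polygon

import tissuesim as ts
from tissuesim.division import (
    DivisionError, DivisionSpec, PolygonBoundary, _bisecting_s2,
    chord_candidate, divide_cell, errera_wall, extension_axis, growth_axis,
    min_center_diameter, potential_components, potential_wall,
    sample_threshold,
)

SQUARE = np.array([[0., 0.], [1., 0.], [1., 1.], [0., 1.]])
RECT21 = np.array([[0., 0.], [2., 0.], [2., 1.], [0., 1.]])
RECT41 = np.array([[0., 0.], [4., 0.], [4., 1.], [0., 1.]])


def brute_force_bisector_min(poly, n=1000):
    """Independent oracle: dense scan of area-bisecting chords."""
    B = PolygonBoundary(poly)
    best = np.inf
    for s1 in np.linspace(0, B.perimeter / 2, n, endpoint=False):
        s2 = _bisecting_s2(B, s1)
        d = float(np.hypot(*(B.point_at(s2) - B.point_at(s1))))
        best = min(best, d)
    return best


class TestThreshold:
    def test_zero_sd_is_deterministic(self, rng):
        spec = DivisionSpec(mean=2.0, sd=0.0)
        assert all(sample_threshold(spec, rng) == 2.0 for _ in range(10))

    def test_sample_mean_clt(self):
        rng = np.random.default_rng(7)
        spec = DivisionSpec(mean=5.0, sd=1.0)
        n = 100_000
        draws = np.array([sample_threshold(spec, rng) for _ in range(n)])
        assert abs(draws.mean() - 5.0) < 3.0 / np.sqrt(n)

    def test_negative_draws_clamped_to_floor(self):
        rng = np.random.default_rng(0)
        spec = DivisionSpec(mean=1.0, sd=100.0)
        with pytest.warns(UserWarning):
            draws = [sample_threshold(spec, rng) for _ in range(200)]
        assert min(draws) == pytest.approx(0.01)   # 1% of the mean


class TestErrera:
    def test_unit_square_mid_edge_chord(self, rng):
        w = errera_wall(SQUARE, rng=rng)
        assert w.d == pytest.approx(1.0, abs=1e-6)
        assert w.A1 == pytest.approx(0.5, rel=1e-6)
        # endpoints at midpoints of opposite sides: one coordinate is 1/2,
        # the other sits on the boundary
        for p in w.endpoints:
            assert min(abs(p[0] - 0.5), abs(p[1] - 0.5)) < 1e-6
            assert min(abs(p[0]), abs(p[0] - 1), abs(p[1]), abs(p[1] - 1)) < 1e-9

    def test_square_tie_break_uniform_over_two_minima(self):
        rng = np.random.default_rng(3)
        orientations = set()
        for _ in range(12):
            w = errera_wall(SQUARE, rng=rng)
            v = w.endpoints[1] - w.endpoints[0]
            orientations.add("h" if abs(v[0]) > abs(v[1]) else "v")
        assert orientations == {"h", "v"}

    def test_rectangle_short_midline(self, rng):
        w = errera_wall(RECT21, rng=rng)
        assert w.d == pytest.approx(1.0, abs=1e-6)
        assert w.endpoints[0][0] == pytest.approx(1.0, abs=1e-6)
        assert w.endpoints[1][0] == pytest.approx(1.0, abs=1e-6)

    def test_bisection_constraint(self, rng):
        for _ in range(5):
            poly = random_convex_polygon(rng, 9)
            w = errera_wall(poly, rng=rng)
            assert w.A1 == pytest.approx(w.A2, rel=1e-6)

    def test_oracle_equivalence_random_convex(self, rng):
        """errera_wall never beats nor trails the brute-force scan minimum."""
        for _ in range(8):
            poly = random_convex_polygon(rng, 8)
            w = errera_wall(poly, rng=rng)
            oracle = brute_force_bisector_min(poly, n=400)
            assert w.d <= oracle + 1e-3
            assert w.d >= oracle - 1e-3 * PolygonBoundary(poly).perimeter


class TestAxes:
    def test_rectangle_principal_axis(self):
        e = extension_axis(RECT41)
        assert abs(e @ np.array([1.0, 0.0])) == pytest.approx(1.0)

    def test_regular_hexagon_degenerate(self):
        hexv = np.array([[np.cos(a), np.sin(a)]
                         for a in np.pi / 3 * np.arange(6)])
        assert extension_axis(hexv) is None

    def test_uniform_dilation_velocities_degenerate(self):
        hexv = np.array([[np.cos(a), np.sin(a)]
                         for a in np.pi / 3 * np.arange(6)])
        assert growth_axis(1.7 * hexv) is None

    def test_sign_normalized(self, rng):
        for _ in range(5):
            poly = random_convex_polygon(rng, 10)
            e = extension_axis(poly)
            if e is not None:
                assert e[0] >= 0


class TestPotentialComponents:
    def test_equal_area_wall_zero_area_potential(self, rng):
        w = errera_wall(SQUARE, rng=rng)
        V_A, V_L, V_e, V_g = potential_components(SQUARE, None, w)
        assert V_A == pytest.approx(0.0, abs=1e-10)

    def test_perp_term_vanishes_through_center_perpendicular(self):
        B = PolygonBoundary(RECT41)
        # vertical wall through the center: W = (0, 1), e = (1, 0)
        cand = chord_candidate(B, 2.0, B.perimeter - 3.0)
        assert cand.delta_center == pytest.approx(0.0, abs=1e-12)
        _, _, V_e, _ = potential_components(RECT41, None, cand)
        assert V_e == pytest.approx(0.0, abs=1e-10)

    def test_perp_term_is_one_for_parallel_wall_through_center(self):
        B = PolygonBoundary(RECT41)
        # horizontal wall through the center: W parallel to e
        s1 = 4.0 + 0.5            # midpoint of right short side
        s2 = 4.0 + 1.0 + 4.0 + 0.5  # midpoint of left short side
        cand = chord_candidate(B, s1, s2)
        assert cand.delta_center == pytest.approx(0.0, abs=1e-12)
        _, _, V_e, _ = potential_components(RECT41, None, cand, orientation=-1)
        V_e2 = potential_components(RECT41, None, cand, orientation=+1)[2]
        assert max(V_e, V_e2) == pytest.approx(1.0, abs=1e-10)

    def test_min_center_diameter_rectangle(self):
        assert min_center_diameter(PolygonBoundary(RECT21)) == pytest.approx(
            1.0, abs=1e-6)

    def test_zero_length_candidate_rejected(self):
        B = PolygonBoundary(SQUARE)
        cand = chord_candidate(B, 0.5, 0.5)
        with pytest.raises(DivisionError):
            potential_components(SQUARE, None, cand)


class TestPotentialWall:
    def test_area_length_weights_find_short_midline(self, rng):
        spec = DivisionSpec(model="potential", weights=(1, 1, 0, 0))
        w = potential_wall(RECT21, None, spec, rng=rng)
        assert w.d == pytest.approx(1.0, abs=1e-3)
        assert abs(w.endpoints[0][0] - 1.0) < 1e-2

    def test_extension_weight_prefers_perpendicular_wall(self, rng):
        spec = DivisionSpec(model="potential", weights=(0, 0, 1, 0))
        w = potential_wall(RECT41, None, spec, rng=rng)
        direction = (w.endpoints[1] - w.endpoints[0]) / w.d
        assert abs(direction @ np.array([1.0, 0.0])) < 1e-2   # wall ⟂ long axis

    def test_area_only_with_random_tie_break(self):
        rng = np.random.default_rng(11)
        spec = DivisionSpec(model="potential", weights=(1, 0, 0, 0))
        angles = []
        for _ in range(6):
            w = potential_wall(SQUARE, None, spec, rng=rng)
            assert w.A1 == pytest.approx(w.A2, rel=1e-2)
            v = (w.endpoints[1] - w.endpoints[0]) / w.d
            angles.append(round(np.arctan2(abs(v[1]), v[0]) / np.pi * 8))
        assert len(set(angles)) > 1    # orientation varies over equal minima

    def test_recovers_errera_on_convex_cells(self, rng):
        """With area+length weights and eps_L -> 0 the potential wall
        approximates the Errera wall: it bisects the area, and its length
        agrees up to the (small) gap between the shortest bisecting chord
        and the shortest through-center chord, which V_L targets."""
        for _ in range(3):
            poly = random_convex_polygon(rng, 8)
            we = errera_wall(poly, rng=rng)
            spec = DivisionSpec(model="potential", weights=(10, 1, 0, 0),
                                eps_L=1e-9)
            wp = potential_wall(poly, None, spec, rng=rng)
            assert wp.A1 == pytest.approx(wp.A2, rel=1e-2)
            assert wp.d == pytest.approx(we.d, rel=5e-2)
            assert wp.d >= we.d - 1e-3   # never shorter than the optimum

    def test_degenerate_axis_dropped_with_warning(self, rng):
        hexv = np.array([[np.cos(a), np.sin(a)]
                         for a in np.pi / 3 * np.arange(6)])
        spec = DivisionSpec(model="potential", weights=(1, 0, 1, 0))
        with pytest.warns(UserWarning):
            w = potential_wall(hexv, None, spec, rng=rng)
        assert w.A1 == pytest.approx(w.A2, rel=1e-2)


class TestSurgery:
    def test_unit_square_midline_split(self, unit_square, rng):
        w = errera_wall(unit_square.cell_polygon(0), rng=rng)
        out = divide_cell(unit_square, 0, w)
        ts.validate_tissue(unit_square)
        g = ts.compute_geometry(unit_square)
        assert unit_square.n_cells == 2
        assert g.areas.sum() == pytest.approx(1.0, rel=1e-9)
        assert sorted(g.areas) == pytest.approx([0.5, 0.5], rel=1e-6)

    def test_neighbor_gains_one_vertex_and_stays_valid(self, two_squares, rng):
        loops_before = [len(lp) for lp in two_squares.vertex_loops()]
        # split cell 0 horizontally so the shared vertical wall (s in (1,2)
        # along its boundary) is cut at its midpoint
        B = PolygonBoundary(two_squares.cell_polygon(0))
        w = chord_candidate(B, 1.5, _bisecting_s2(B, 1.5))
        divide_cell(two_squares, 0, w)
        ts.validate_tissue(two_squares)
        assert two_squares.n_cells == 3
        # the untouched neighbor is now a pentagon (one extra vertex)
        assert len(two_squares.vertex_loops()[1]) == loops_before[1] + 1

    def test_concentration_amounts_partition_with_area(self, unit_square, rng):
        w = errera_wall(unit_square.cell_polygon(0), rng=rng)
        conc = np.array([[3.0]])
        out = divide_cell(unit_square, 0, w)
        g = ts.compute_geometry(unit_square)
        # daughters inherit [X]=3 unchanged; amounts 3*A1 and 3*A2
        da, db = out.daughters
        amounts = 3.0 * g.areas
        assert amounts.sum() == pytest.approx(3.0, rel=1e-9)

    def test_rest_length_partition(self, unit_square, rng):
        g0 = ts.compute_geometry(unit_square)
        delta0 = 0.8 * g0.edge_lengths
        w = errera_wall(unit_square.cell_polygon(0), rng=rng)
        out = divide_cell(unit_square, 0, w, delta=delta0.copy())
        assert len(out.delta) == unit_square.n_edges
        # new wall starts at rest
        wall_len = np.hypot(*(out.wall_endpoints[1] - out.wall_endpoints[0]))
        assert out.delta[out.wall_edge] == pytest.approx(wall_len)
        # split halves sum to the original rest length
        for old_e, new_e in out.split_edges:
            assert out.delta[old_e] + out.delta[new_e] == pytest.approx(0.8)

    def test_endpoint_snapping_to_existing_vertex(self, unit_square):
        B = PolygonBoundary(unit_square.cell_polygon(0))
        # endpoints a hair away from corners 0 and 2: diagonal split
        cand = chord_candidate(B, 1e-12, 2.0 + 1e-12)
        divide_cell(unit_square, 0, cand)
        assert unit_square.n_vertices == 4     # no new vertices created
        assert unit_square.n_cells == 2
        ts.validate_tissue(unit_square)

    def test_zero_area_daughter_aborts(self, unit_square):
        B = PolygonBoundary(unit_square.cell_polygon(0))
        cand = chord_candidate(B, 0.2, 0.2 + 1e-12)
        with pytest.raises(DivisionError):
            divide_cell(unit_square, 0, cand)

    def test_random_division_audit(self, rng):
        """Many random divisions keep the mesh valid and conserve area
        and chemical amount to 1e-9 relative."""
        t = ts.voronoi_template("circle", 24, seed=5, radius=3.0)
        conc = rng.uniform(0.5, 2.0, (t.n_cells, 1))
        g = ts.compute_geometry(t)
        total_area0 = g.areas.sum()
        total_amount0 = (g.areas * conc[:, 0]).sum()
        delta = g.edge_lengths.copy()
        for _ in range(40):
            ci = int(rng.integers(t.n_cells))
            w = errera_wall(t.cell_polygon(ci), rng=rng)
            out = divide_cell(t, ci, w, delta=delta)
            delta = out.delta
            conc = np.vstack([conc, conc[ci][None, :]])
            ts.validate_tissue(t)
        g = ts.compute_geometry(t)
        assert g.areas.sum() == pytest.approx(total_area0, rel=1e-9)
        assert (g.areas * conc[:, 0]).sum() == pytest.approx(total_amount0,
                                                             rel=1e-9)
        assert len(delta) == t.n_edges
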