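"""Cell division: thresholds, wall placement (Errera / potential), mesh surgery.

A cell divides when its area (or a configured constituent) passes a
threshold drawn at birth from N(mean, sd).  The new wall is a straight
chord across the cell, placed either by the modern interpretation of
Errera's rule — the *shortest* wall that bisects the cell area — or by
minimizing a weighted potential

    V(theta1, theta2) = w_A V_A + w_L V_L + w_e V_e + w_g V_g

over the central angles theta1, theta2 of the wall endpoints as seen from
the cell centroid, where V_A penalizes unequal daughter areas, V_L long
walls far from the shortest central diameter, and V_e / V_g walls not
perpendicular to the axis of maximal cell extension / instantaneous
growth (principal eigenvectors of the vertex position / velocity
covariance).

Mesh surgery inserts the wall endpoints as new vertices (splitting the
boundary walls they land on, including in the neighboring cells), adds
the wall edge, and replaces the mother by two daughters that inherit her
concentrations unchanged — amounts are therefore proportional to area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

from .mesh import Tissue, _signed_area


class DivisionError(RuntimeError):
    """Division could not be carried out on this cell."""


@dataclass
class DivisionSpec:
    """Division model configuration.

    ``variable`` is ``"area"`` or a species name; thresholds are drawn
    from N(mean, sd) truncated below at ``floor_frac * mean``.  ``weights``
    = (w_A, w_L, w_e, w_g) are the potential-model weights; ``eps_L`` and
    ``eps_perp`` regularize walls away from the cell center.
    """

    model: str = "errera"  # "errera" | "potential"
    variable: str = "area"
    mean: float = 1.0
    sd: float = 0.0
    weights: tuple[float, float, float, float] = (1.0, 1.0, 0.0, 0.0)
    eps_L: float = 0.1
    eps_perp: float = 0.1
    floor_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("threshold sd must be >= 0")
        if self.model not in ("errera", "potential"):
            raise ValueError(f"unknown division model {self.model!r}")
        if self.model == "potential":
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("weights must be >= 0 with at least one positive")


@dataclass
class LineageRecord:
    parent: int
    daughters: tuple[int, int]
    time: float
    wall: tuple[tuple[float, float], tuple[float, float]]
    thresholds: tuple[float, float]


def sample_threshold(spec: DivisionSpec, rng: np.random.Generator) -> float:
    """Draw a division threshold, truncating negative draws at the floor."""
    x = rng.normal(spec.mean, spec.sd)
    floor = spec.floor_frac * spec.mean
    if x < floor:
        warnings.warn("division threshold draw below floor; clamped")
        return floor
    return float(x)


# ---------------------------------------------------------------------------
# Polygon boundary parameterization and wall candidates
# ---------------------------------------------------------------------------

class PolygonBoundary:
    """Arc-length parameterization of a simple CCW polygon boundary."""

    def __init__(self, poly: np.ndarray):
        self.P = np.asarray(poly, dtype=float).reshape(-1, 2)
        d = np.roll(self.P, -1, axis=0) - self.P
        self.seg_len = np.hypot(d[:, 0], d[:, 1])
        self.cum = np.concatenate([[0.0], np.cumsum(self.seg_len)])
        self.perimeter = float(self.cum[-1])
        self.area = abs(_signed_area(self.P))
        self.centroid = self.P.mean(axis=0)

    def locate(self, s: float) -> tuple[int, float]:
        """(segment index, fraction along segment) for arc position s."""
        s = s % self.perimeter
        i = int(np.searchsorted(self.cum, s, side="right")) - 1
        i = min(i, len(self.P) - 1)
        return i, (s - self.cum[i]) / self.seg_len[i]

    def point_at(self, s: float) -> np.ndarray:
        i, f = self.locate(s)
        j = (i + 1) % len(self.P)
        return (1 - f) * self.P[i] + f * self.P[j]

    def subpolygon(self, s1: float, s2: float) -> np.ndarray:
        """Vertices of the region bounded by the boundary arc s1 -> s2 (CCW)
        and the straight chord back from s2 to s1."""
        p1, p2 = self.point_at(s1), self.point_at(s2)
        i1, _ = self.locate(s1)
        n = len(self.P)
        pts = [p1]
        s1m, s2m = s1 % self.perimeter, s2 % self.perimeter
        span = (s2m - s1m) % self.perimeter
        k = (i1 + 1) % n
        while True:
            off = (self.cum[k] - s1m) % self.perimeter
            if off >= span or off == 0.0:
                break
            pts.append(self.P[k])
            k = (k + 1) % n
            if len(pts) > n + 1:  # safety
                break
        pts.append(p2)
        return np.asarray(pts)


@dataclass
class WallCandidate:
    """A straight candidate wall across a cell."""

    s1: float
    s2: float
    theta1: float
    theta2: float
    endpoints: tuple[np.ndarray, np.ndarray]
    d: float
    delta_center: float
    A1: float
    A2: float


def _segment_point_distance(a: np.ndarray, b: np.ndarray, p: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.hypot(*(p - a)))
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    return float(np.hypot(*(p - (a + t * ab))))


def chord_candidate(B: PolygonBoundary, s1: float, s2: float) -> WallCandidate:
    """Build the wall candidate for boundary positions (s1, s2)."""
    p1, p2 = B.point_at(s1), B.point_at(s2)
    sub = B.subpolygon(s1, s2)
    A1 = abs(_signed_area(sub))
    A2 = B.area - A1
    r1, r2 = p1 - B.centroid, p2 - B.centroid
    return WallCandidate(
        s1=s1 % B.perimeter, s2=s2 % B.perimeter,
        theta1=float(np.arctan2(r1[1], r1[0])),
        theta2=float(np.arctan2(r2[1], r2[0])),
        endpoints=(p1, p2),
        d=float(np.hypot(*(p2 - p1))),
        delta_center=_segment_point_distance(p1, p2, B.centroid),
        A1=A1, A2=A2)


# ---------------------------------------------------------------------------
# Errera's rule: shortest area-bisecting wall
# ---------------------------------------------------------------------------

def _bisecting_s2(B: PolygonBoundary, s1: float) -> float:
    """Solve for s2 such that the arc s1 -> s2 encloses half the cell area.

    The enclosed area is monotone increasing in s2, so the root is
    bracketed on (s1, s1 + perimeter)."""
    half = 0.5 * B.area
    eps = 1e-9 * B.perimeter

    def f(s2):
        return abs(_signed_area(B.subpolygon(s1, s2))) - half

    return brentq(f, s1 + eps, s1 + B.perimeter - eps, xtol=1e-12 * B.perimeter)


def errera_wall(poly: np.ndarray, rng: np.random.Generator | None = None,
                n_scan: int = 256, tie_tol: float = 1e-6) -> WallCandidate:
    """Shortest straight wall bisecting the cell area (Errera's rule).

    Both endpoints are scanned along the perimeter; for each position of
    the first endpoint the equal-area constraint fixes the second by
    monotone root bracketing, and the chord length is then locally
    refined around the scan minima.  Ties between global minima within
    ``tie_tol`` (relative to the perimeter; symmetric cells) are broken
    uniformly at random.
    """
    B = PolygonBoundary(poly)
    if B.area <= 0:
        raise DivisionError("cannot divide a zero-area or non-simple polygon")
    rng = rng if rng is not None else np.random.default_rng()

    def chord_len(s1: float) -> float:
        s2 = _bisecting_s2(B, s1)
        return float(np.hypot(*(B.point_at(s2) - B.point_at(s1))))

    ss = np.linspace(0.0, B.perimeter, n_scan, endpoint=False)
    lens = np.array([chord_len(s) for s in ss])
    h = B.perimeter / n_scan
    # refine every local minimum of the scan, then keep the global set
    local_min = [i for i in range(n_scan)
                 if lens[i] <= lens[(i - 1) % n_scan] and lens[i] <= lens[(i + 1) % n_scan]]
    refined: list[tuple[float, float]] = []
    for i in local_min:
        res = minimize_scalar(chord_len, bounds=(ss[i] - h, ss[i] + h),
                              method="bounded", options={"xatol": 1e-10 * B.perimeter})
        refined.append((float(res.fun), float(res.x)))
    if not refined:
        raise DivisionError("no bisecting chord found")
    best = min(f for f, _ in refined)
    ties = [s for f, s in refined if f <= best + tie_tol * B.perimeter]
    # deduplicate walls that are the same chord traversed from either end
    distinct: list[float] = []
    for s in ties:
        c = chord_candidate(B, s, _bisecting_s2(B, s))
        dup = False
        for s0 in distinct:
            c0 = chord_candidate(B, s0, _bisecting_s2(B, s0))
            pairs = (np.hypot(*(c.endpoints[0] - c0.endpoints[0]))
                     + np.hypot(*(c.endpoints[1] - c0.endpoints[1])),
                     np.hypot(*(c.endpoints[0] - c0.endpoints[1]))
                     + np.hypot(*(c.endpoints[1] - c0.endpoints[0])))
            if min(pairs) < 1e-5 * B.perimeter:
                dup = True
                break
        if not dup:
            distinct.append(s)
    s1 = distinct[int(rng.integers(len(distinct)))] if len(distinct) > 1 else distinct[0]
    return chord_candidate(B, s1, _bisecting_s2(B, s1))


# ---------------------------------------------------------------------------
# Potential model
# ---------------------------------------------------------------------------

def extension_axis(vertices: np.ndarray, degeneracy_tol: float = 1e-6
                   ) -> np.ndarray | None:
    """Principal axis of the vertex-position covariance (None if isotropic).

    The covariance M = X^T X / (n-1) of the centered coordinates is
    decomposed; the unit eigenvector of the larger eigenvalue is returned,
    sign-normalized to non-negative x (positive y on the x-axis-free
    boundary case).  Equal eigenvalues (symmetric cells) are degenerate.
    """
    X = np.asarray(vertices, dtype=float).reshape(-1, 2)
    if len(X) < 3:
        raise DivisionError("need at least 3 points for an axis")
    Xc = X - X.mean(axis=0)
    M = Xc.T @ Xc / (len(X) - 1)
    evals, evecs = np.linalg.eigh(M)
    spread = evals[1] - evals[0]
    scale = max(evals[1], 1e-300)
    if spread / scale < degeneracy_tol:
        return None
    v = evecs[:, 1]
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    return v


def growth_axis(velocities: np.ndarray, degeneracy_tol: float = 1e-6
                ) -> np.ndarray | None:
    """Principal axis of the vertex-velocity covariance (None if isotropic)."""
    return extension_axis(velocities, degeneracy_tol)


def min_center_diameter(B: PolygonBoundary, n_scan: int = 180) -> float:
    """Length of the shortest chord through the cell center."""

    def diam(phi: float) -> float:
        u = np.array([np.cos(phi), np.sin(phi)])
        r_fwd = _ray_hit(B, B.centroid, u)
        r_bwd = _ray_hit(B, B.centroid, -u)
        if r_fwd is None or r_bwd is None:
            return np.inf
        return r_fwd[2] + r_bwd[2]

    phis = np.linspace(0, np.pi, n_scan, endpoint=False)
    vals = np.array([diam(p) for p in phis])
    i = int(np.argmin(vals))
    h = np.pi / n_scan
    res = minimize_scalar(diam, bounds=(phis[i] - h, phis[i] + h), method="bounded")
    return float(min(res.fun, vals[i]))


def _ray_hit(B: PolygonBoundary, origin: np.ndarray, u: np.ndarray
             ) -> tuple[np.ndarray, float, float] | None:
    """First boundary intersection of the ray origin + r*u, r > 0.

    Returns (point, arc position s, ray distance r), or None.
    """
    best = None
    n = len(B.P)
    for i in range(n):
        a, b = B.P[i], B.P[(i + 1) % n]
        e = b - a
        den = u[0] * (-e[1]) - u[1] * (-e[0])
        if abs(den) < 1e-300:
            continue
        w = a - origin
        r = (w[0] * (-e[1]) - w[1] * (-e[0])) / den
        tt = (u[0] * w[1] - u[1] * w[0]) / den
        if r > 1e-12 and -1e-12 <= tt <= 1 + 1e-12:
            if best is None or r < best[2]:
                f = float(np.clip(tt, 0.0, 1.0))
                s = float(B.cum[i] + f * B.seg_len[i])
                best = (a + f * e, s, float(r))
    return best


def candidate_from_angles(B: PolygonBoundary, theta1: float, theta2: float
                          ) -> WallCandidate | None:
    """Wall candidate whose endpoints are the boundary hits of centroid rays."""
    h1 = _ray_hit(B, B.centroid, np.array([np.cos(theta1), np.sin(theta1)]))
    h2 = _ray_hit(B, B.centroid, np.array([np.cos(theta2), np.sin(theta2)]))
    if h1 is None or h2 is None:
        return None
    if np.hypot(*(h1[0] - h2[0])) < 1e-9 * B.perimeter:
        return None
    return chord_candidate(B, h1[1], h2[1])


def potential_components(cell: np.ndarray, velocities: np.ndarray | None,
                         candidate: WallCandidate,
                         eps_L: float = 0.1, eps_perp: float = 0.1,
                         d_min: float | None = None,
                         orientation: int = +1
                         ) -> tuple[float, float, float | None, float | None]:
    """(V_A, V_L, V_e, V_g) of a candidate wall.

    ``orientation`` selects the sign of the wall direction W used in the
    perpendicularity terms; the minimizer evaluates both.  V_e / V_g are
    None when the corresponding axis is degenerate (or velocities absent).
    """
    if candidate.d <= 0:
        raise DivisionError("degenerate candidate wall of zero length")
    B = PolygonBoundary(cell)
    A = candidate.A1 + candidate.A2
    V_A = ((candidate.A1 - candidate.A2) / A) ** 2
    dm = min_center_diameter(B) if d_min is None else d_min
    V_L = ((candidate.d - dm) ** 2 + eps_L * candidate.delta_center ** 2) \
        / (candidate.d + dm) ** 2
    W = orientation * (candidate.endpoints[1] - candidate.endpoints[0]) / candidate.d

    def vperp(v):
        return float(v @ W) + eps_perp * candidate.delta_center / candidate.d

    e = extension_axis(cell)
    V_e = vperp(e) if e is not None else None
    g = None
    if velocities is not None:
        g = growth_axis(np.asarray(velocities, dtype=float))
    V_g = vperp(g) if g is not None else None
    return V_A, V_L, V_e, V_g


def potential_wall(cell: np.ndarray, velocities: np.ndarray | None,
                   spec: DivisionSpec, rng: np.random.Generator | None = None,
                   n_grid: int = 64) -> WallCandidate:
    """Minimize the weighted division potential over the endpoint angles.

    A coarse ``n_grid`` x ``n_grid`` angular grid is scanned and the best
    basins refined with a local simplex search; equivalent global minima
    (within tolerance) are broken uniformly at random.  Degenerate
    extension/growth axes drop their term with a warning.
    """
    rng = rng if rng is not None else np.random.default_rng()
    wA, wL, we, wg = spec.weights
    B = PolygonBoundary(cell)
    dm = min_center_diameter(B) if wL > 0 else None
    e_axis = extension_axis(cell) if we > 0 else None
    if we > 0 and e_axis is None:
        warnings.warn("extension axis degenerate; dropping V_e for this division")
        we = 0.0
    g_axis = None
    if wg > 0:
        if velocities is None:
            raise DivisionError("V_g weight requires vertex velocities")
        g_axis = growth_axis(np.asarray(velocities, dtype=float))
        if g_axis is None:
            warnings.warn("growth axis degenerate; dropping V_g for this division")
            wg = 0.0
    if wA + wL + we + wg == 0:
        raise DivisionError("all potential terms degenerate; division aborted")

    def total(th: Sequence[float]) -> float:
        c = candidate_from_angles(B, th[0], th[1])
        if c is None or c.d < 1e-6 * B.perimeter:
            return np.inf
        V = wA * ((c.A1 - c.A2) / B.area) ** 2
        if wL > 0:
            V += wL * ((c.d - dm) ** 2 + spec.eps_L * c.delta_center ** 2) \
                / (c.d + dm) ** 2
        if we > 0 or wg > 0:
            # both orientations of W are evaluated; a candidate is scored by
            # the orientation with non-negative alignment, so V_perp is
            # minimal for walls perpendicular to the axis
            W = (c.endpoints[1] - c.endpoints[0]) / c.d
            dot = (we * float(e_axis @ W) if we > 0 else 0.0) \
                + (wg * float(g_axis @ W) if wg > 0 else 0.0)
            V += abs(dot) + (we + wg) * spec.eps_perp * c.delta_center / c.d
        return V

    th = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    vals = np.full((n_grid, n_grid), np.inf)
    for i1 in range(n_grid):
        for i2 in range(n_grid):
            if i1 == i2:
                continue
            vals[i1, i2] = total((th[i1], th[i2]))
    best = np.nanmin(vals)
    if not np.isfinite(best):
        raise DivisionError("all candidate walls degenerate; division aborted")
    # refine every basin: local minima of the periodic grid, best first
    mins = []
    for i1 in range(n_grid):
        for i2 in range(n_grid):
            v = vals[i1, i2]
            if not np.isfinite(v):
                continue
            nb = [vals[(i1 + d1) % n_grid, (i2 + d2) % n_grid]
                  for d1 in (-1, 0, 1) for d2 in (-1, 0, 1)
                  if (d1, d2) != (0, 0)]
            if v <= min(nb):
                mins.append((v, i1, i2))
    mins.sort()
    idxs = [(i1, i2) for v, i1, i2 in mins if v <= best + 0.25 * abs(best) + 1e-6]
    results = []
    for i1, i2 in idxs[:12]:
        res = minimize(total, x0=[th[i1], th[i2]], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 400})
        results.append((float(res.fun), tuple(res.x)))
    fbest = min(f for f, _ in results)
    ties = [x for f, x in results if f <= fbest + 1e-9]
    # deduplicate (theta1, theta2) vs (theta2, theta1) and 2pi wraps
    distinct: list[tuple[float, float]] = []
    for x in ties:
        c = candidate_from_angles(B, *x)
        dup = False
        for x0 in distinct:
            c0 = candidate_from_angles(B, *x0)
            pairs = (np.hypot(*(c.endpoints[0] - c0.endpoints[0]))
                     + np.hypot(*(c.endpoints[1] - c0.endpoints[1])),
                     np.hypot(*(c.endpoints[0] - c0.endpoints[1]))
                     + np.hypot(*(c.endpoints[1] - c0.endpoints[0])))
            if min(pairs) < 1e-4 * B.perimeter:
                dup = True
                break
        if not dup:
            distinct.append(x)
    choice = distinct[int(rng.integers(len(distinct)))] if len(distinct) > 1 else distinct[0]
    return candidate_from_angles(B, *choice)


def place_wall(cell: np.ndarray, spec: DivisionSpec,
               velocities: np.ndarray | None = None,
               rng: np.random.Generator | None = None) -> WallCandidate:
    """Dispatch to the configured wall-placement model."""
    if spec.model == "errera":
        return errera_wall(cell, rng=rng)
    return potential_wall(cell, velocities, spec, rng=rng)


# ---------------------------------------------------------------------------
# Mesh surgery
# ---------------------------------------------------------------------------

@dataclass
class DivisionOutcome:
    """Result of dividing one cell (the tissue is modified in place)."""

    daughters: tuple[int, int]        # cell indices: mother's slot, appended
    wall_edge: int                    # edge index of the new wall
    wall_endpoints: tuple[np.ndarray, np.ndarray]
    delta: np.ndarray | None          # updated per-edge rest lengths
    split_edges: list[tuple[int, int]] = field(default_factory=list)


def divide_cell(t: Tissue, ci: int, wall: WallCandidate,
                delta: np.ndarray | None = None,
                snap_tol: float = 1e-7) -> DivisionOutcome:
    """Split cell ``ci`` of ``t`` along ``wall`` (computed on its polygon).

    The tissue is modified in place: wall endpoints become new vertices
    (splitting the boundary edges they land on and patching any neighbor
    cell that shares them), a straight wall edge is added, and the mother
    cell is replaced by two daughters (one in the mother's slot, one
    appended).  ``delta`` rest lengths, if given, are partitioned
    proportionally over split edges; the new wall starts at rest
    (delta = current length).  Endpoints within ``snap_tol`` (relative to
    the perimeter) of an existing vertex snap to it.
    """
    loop = t.vertex_loops()[ci].copy()
    poly = t.V[loop]
    B = PolygonBoundary(poly)
    A = B.area
    if min(wall.A1, wall.A2) <= 1e-9 * A:
        raise DivisionError(f"wall would create a zero-area daughter in cell {ci}")
    tol = snap_tol * B.perimeter

    if delta is not None:
        delta = np.asarray(delta, dtype=float).copy()
    edge_of = {frozenset(map(int, t.E[e])): e for cc in t.C for e in cc}
    n0 = len(loop)
    split_records: list[tuple[int, int]] = []

    prior_splits: dict[int, tuple[int, float]] = {}  # orig segment -> (vertex, frac)

    def resolve_endpoint(s: float) -> int:
        """Vertex id for boundary position s, splitting an edge if needed."""
        nonlocal delta
        i, f = B.locate(s)
        u, v = int(loop[i]), int(loop[(i + 1) % n0])
        if f * B.seg_len[i] < tol:
            return u
        if (1 - f) * B.seg_len[i] < tol:
            return v
        if i in prior_splits:
            # this original segment was already split by the other endpoint
            w0, f0 = prior_splits[i]
            if abs(f - f0) * B.seg_len[i] < tol:
                return w0
            if f < f0:
                v, f = w0, f / f0
            else:
                u, f = w0, (f - f0) / (1 - f0)
        else:
            prior_splits[i] = (t.n_vertices, f)
        w = t.n_vertices
        t.V = np.vstack([t.V, B.point_at(s)[None, :]])
        e = edge_of[frozenset((u, v))]
        # edge e becomes (u, w); new edge (w, v) appended
        new_e = t.n_edges
        t.E[e] = (u, w)
        t.E = np.vstack([t.E, np.array([[w, v]])])
        for cc in range(t.n_cells):
            if e in t.C[cc]:
                t.C[cc].append(new_e)
        edge_of[frozenset((u, w))] = e
        edge_of[frozenset((w, v))] = new_e
        del edge_of[frozenset((u, v))]
        if delta is not None:
            d0 = delta[e]
            delta[e] = d0 * f
            delta = np.append(delta, d0 * (1 - f))
        split_records.append((e, new_e))
        return w

    w1 = resolve_endpoint(wall.s1)
    w2 = resolve_endpoint(wall.s2)
    if w1 == w2:
        raise DivisionError(f"wall endpoints coincide in cell {ci}")

    # rebuild the mother's vertex loop including any inserted vertices
    t.invalidate()
    loop2 = [int(x) for x in t.vertex_loops()[ci]]
    p1, p2 = loop2.index(w1), loop2.index(w2)
    if (p1 - p2) % len(loop2) in (0,):
        raise DivisionError("wall endpoints coincide after snapping")
    arc_a = loop2[p1:p2 + 1] if p1 < p2 else loop2[p1:] + loop2[:p2 + 1]
    arc_b = loop2[p2:p1 + 1] if p2 < p1 else loop2[p2:] + loop2[:p1 + 1]
    if len(arc_a) < 2 or len(arc_b) < 2:
        raise DivisionError("degenerate daughter loop")

    wall_e = t.n_edges
    t.E = np.vstack([t.E, np.array([[w1, w2]])])
    edge_of[frozenset((w1, w2))] = wall_e
    if delta is not None:
        delta = np.append(delta, float(np.hypot(*(t.V[w2] - t.V[w1]))))

    def edges_of_arc(arc: list[int]) -> list[int]:
        out = [edge_of[frozenset((arc[i], arc[i + 1]))] for i in range(len(arc) - 1)]
        out.append(wall_e)
        return out

    cell_a, cell_b = edges_of_arc(arc_a), edges_of_arc(arc_b)
    if len(cell_a) < 3 or len(cell_b) < 3:
        raise DivisionError("daughter cell with fewer than 3 edges")
    t.C[ci] = cell_a
    t.C.append(cell_b)
    t.invalidate()
    return DivisionOutcome(daughters=(ci, t.n_cells - 1), wall_edge=wall_e,
                           wall_endpoints=(t.V[w1].copy(), t.V[w2].copy()),
                           delta=delta, split_edges=split_records)
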