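"""Polygonal tissue meshes: data structure, geometry, CSV I/O, templates.

A tissue is a planar polygonal lattice in which every polygon is one
biological cell.  It is stored as three collections:

* ``V`` — vertices, an ``(n_v, 2)`` float array of (x, y) positions;
* ``E`` — edges, an ``(n_e, 2)`` integer array of vertex-index pairs;
* ``C`` — cells, each an ordered list of edge indices tracing a closed,
  simple polygon.

Two CSV dialects are supported: ``VEC`` (three tables: vertices, edges,
cells) and ``FLAT`` (one table, each row a cell as an x1,y1,x2,y2,...
vertex sequence; edges are reconstructed on load, deduplicating walls
shared between neighboring cells).  Indices are 0-based in memory and
1-based on disk.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import QhullError, Voronoi, cKDTree
import shapely
from shapely.geometry import Polygon as ShPolygon
from shapely.geometry.polygon import orient as sh_orient


class TissueValidationError(ValueError):
    """Raised when a mesh violates the tissue invariants."""


# ---------------------------------------------------------------------------
# Core data structure
# ---------------------------------------------------------------------------

@dataclass
class Tissue:
    """Polygonal tissue: vertices, edges (vertex pairs), cells (edge loops)."""

    V: np.ndarray
    E: np.ndarray
    C: list[list[int]]
    _loops: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float).reshape(-1, 2)
        self.E = np.asarray(self.E, dtype=int).reshape(-1, 2)
        self.C = [list(map(int, c)) for c in self.C]

    @property
    def n_vertices(self) -> int:
        return len(self.V)

    @property
    def n_edges(self) -> int:
        return len(self.E)

    @property
    def n_cells(self) -> int:
        return len(self.C)

    def vertex_loops(self) -> list[np.ndarray]:
        """Ordered vertex-index loop of each cell (counterclockwise)."""
        if self._loops is None or len(self._loops) != len(self.C):
            self._loops = [self._loop_of(ci) for ci in range(len(self.C))]
        return self._loops

    def _loop_of(self, ci: int) -> np.ndarray:
        edges = self.C[ci]
        if len(edges) < 3:
            raise TissueValidationError(f"cell {ci} has fewer than 3 edges")
        loop = _chain_edges([tuple(self.E[e]) for e in edges], ci)
        if _signed_area(self.V[loop]) < 0:
            # normalize winding to counterclockwise
            loop = loop[::-1]
            self.C[ci] = list(reversed(edges))
        return np.asarray(loop, dtype=int)

    def cell_polygon(self, ci: int) -> np.ndarray:
        """Vertex coordinates of cell ``ci`` in counterclockwise order."""
        return self.V[self.vertex_loops()[ci]]

    def copy(self) -> "Tissue":
        return Tissue(self.V.copy(), self.E.copy(), [list(c) for c in self.C])

    def invalidate(self) -> None:
        """Drop cached vertex loops (call after topology surgery)."""
        self._loops = None


def _chain_edges(pairs: list[tuple[int, int]], ci: int) -> list[int]:
    """Order the vertex pairs of a cell's edges into a closed vertex loop."""
    a, b = pairs[0]
    loop = [int(a), int(b)]
    remaining = list(pairs[1:])
    while remaining:
        cur = loop[-1]
        for idx, (u, v) in enumerate(remaining):
            if u == cur:
                loop.append(int(v))
                break
            if v == cur:
                loop.append(int(u))
                break
        else:
            raise TissueValidationError(f"cell {ci}: edge loop is not connected")
        remaining.pop(idx)
    if loop[0] != loop[-1]:
        raise TissueValidationError(f"cell {ci}: edge loop does not close")
    loop = loop[:-1]
    if len(set(loop)) != len(loop):
        raise TissueValidationError(f"cell {ci}: edge loop revisits a vertex")
    return loop


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_is_simple(poly: np.ndarray) -> bool:
    return ShPolygon(poly).is_valid


def validate_tissue(t: Tissue) -> None:
    """Check all tissue invariants; raise :class:`TissueValidationError`.

    Invariants: edges reference existing vertices; each cell is a closed,
    simple, positive-area loop of edges; every edge belongs to one cell
    (boundary) or two (interior wall).
    """
    if t.n_edges and (t.E.min() < 0 or t.E.max() >= t.n_vertices):
        raise TissueValidationError("edge references a nonexistent vertex")
    if t.n_edges and np.any(t.E[:, 0] == t.E[:, 1]):
        raise TissueValidationError("degenerate edge with identical endpoints")
    use_count = np.zeros(t.n_edges, dtype=int)
    bad: list[int] = []
    for ci, edges in enumerate(t.C):
        if any(e < 0 or e >= t.n_edges for e in edges):
            raise TissueValidationError(f"cell {ci} references a nonexistent edge")
        use_count[edges] += 1
        poly = t.cell_polygon(ci)  # raises on open loops
        if _signed_area(poly) <= 0 or not _polygon_is_simple(poly):
            bad.append(ci)
    if bad:
        raise TissueValidationError(
            f"cells with self-intersecting or zero-area polygons: {bad}"
        )
    if np.any(use_count > 2):
        raise TissueValidationError("an edge belongs to more than two cells")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

BOUNDARY = -1  #: sentinel cell index for the exterior side of a boundary edge


@dataclass
class GeometryCache:
    """Derived geometry of a tissue.

    ``edge_cells[k] = (a, b)`` gives the cells on either side of edge ``k``
    (``b == BOUNDARY`` for boundary walls).  ``normals[(ci, k)]`` is the
    unit normal of edge ``k`` pointing out of cell ``ci``.
    """

    areas: np.ndarray
    centroids: np.ndarray
    edge_lengths: np.ndarray
    edge_cells: np.ndarray
    normals: dict[tuple[int, int], np.ndarray]

    def neighbors(self, ci: int) -> list[int]:
        """Cells sharing a wall with ``ci``."""
        out = []
        for a, b in self.edge_cells:
            if a == ci and b != BOUNDARY:
                out.append(int(b))
            elif b == ci and a != BOUNDARY:
                out.append(int(a))
        return out


def edge_cell_adjacency(t: Tissue) -> np.ndarray:
    """(n_e, 2) array of cells adjacent to each edge, BOUNDARY-padded."""
    adj = np.full((t.n_edges, 2), BOUNDARY, dtype=int)
    for ci, edges in enumerate(t.C):
        for e in edges:
            if adj[e, 0] == BOUNDARY:
                adj[e, 0] = ci
            elif adj[e, 1] == BOUNDARY:
                adj[e, 1] = ci
            else:
                raise TissueValidationError(f"edge {e} used by more than two cells")
    return adj


def compute_geometry(t: Tissue) -> GeometryCache:
    """Areas (shoelace), centroids (vertex mean), lengths, adjacency, normals."""
    loops = t.vertex_loops()
    areas = np.empty(t.n_cells)
    centroids = np.empty((t.n_cells, 2))
    normals: dict[tuple[int, int], np.ndarray] = {}
    for ci, loop in enumerate(loops):
        poly = t.V[loop]
        a = _signed_area(poly)
        if abs(a) <= 0.0:
            raise TissueValidationError(f"cell {ci} has zero area")
        areas[ci] = abs(a)
        centroids[ci] = poly.mean(axis=0)
        # CCW traversal u->v: outward normal is the right-hand normal
        vids = {frozenset(t.E[e]): e for e in t.C[ci]}
        n = len(loop)
        for i in range(n):
            u, v = loop[i], loop[(i + 1) % n]
            e = vids[frozenset((int(u), int(v)))]
            d = t.V[v] - t.V[u]
            ln = float(np.hypot(*d))
            if ln == 0.0:
                raise TissueValidationError(f"zero-length edge {e}")
            normals[(ci, e)] = np.array([d[1], -d[0]]) / ln
    dv = t.V[t.E[:, 1]] - t.V[t.E[:, 0]] if t.n_edges else np.zeros((0, 2))
    lengths = np.hypot(dv[:, 0], dv[:, 1])
    return GeometryCache(areas, centroids, lengths, edge_cell_adjacency(t), normals)


# ---------------------------------------------------------------------------
# Building from polygon soup (FLAT loader, templates)
# ---------------------------------------------------------------------------

def tissue_from_polygons(polys: list[np.ndarray], tol: float | None = None) -> Tissue:
    """Build a tissue from per-cell vertex polygons, merging shared walls.

    Vertices closer than ``tol`` (default 1e-9 of the bounding-box
    diagonal) are identified, so walls shared between adjacent polygons
    collapse to single edges.
    """
    polys = [np.asarray(p, dtype=float).reshape(-1, 2) for p in polys]
    if not polys:
        return Tissue(np.zeros((0, 2)), np.zeros((0, 2), dtype=int), [])
    allpts = np.concatenate(polys)
    if tol is None:
        lo, hi = allpts.min(axis=0), allpts.max(axis=0)
        diag = float(np.hypot(*(hi - lo)))
        tol = 1e-9 * (diag if diag > 0 else 1.0)
    # union-find over coincident points
    tree = cKDTree(allpts)
    parent = np.arange(len(allpts))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(tol):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(len(allpts))])
    uniq, inverse = np.unique(roots, return_inverse=True)
    V = np.array([allpts[roots == r].mean(axis=0) for r in uniq])

    edge_index: dict[frozenset[int], int] = {}
    E: list[tuple[int, int]] = []
    C: list[list[int]] = []
    k = 0
    for poly in polys:
        vids = [int(inverse[k + i]) for i in range(len(poly))]
        k += len(poly)
        # drop consecutive duplicates from snapping
        vids = [v for i, v in enumerate(vids) if v != vids[(i + 1) % len(vids)]]
        cell = []
        for i, u in enumerate(vids):
            v = vids[(i + 1) % len(vids)]
            key = frozenset((u, v))
            if key not in edge_index:
                edge_index[key] = len(E)
                E.append((u, v))
            cell.append(edge_index[key])
        C.append(cell)
    t = Tissue(V, np.asarray(E, dtype=int), C)
    validate_tissue(t)
    return t


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def save_tissue(t: Tissue, path: str | Path, dialect: str = "VEC") -> list[Path]:
    """Write a tissue to CSV.  ``dialect`` is ``"VEC"`` or ``"FLAT"``.

    VEC writes ``<path>.vertices.csv``, ``<path>.edges.csv`` and
    ``<path>.cells.csv``; FLAT writes the single file ``path``.  Indices
    on disk are 1-based.  Returns the paths written.
    """
    path = Path(path)
    if dialect.upper() == "VEC":
        pv, pe, pc = (Path(f"{path}.{s}.csv") for s in ("vertices", "edges", "cells"))
        with open(pv, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["id", "x", "y"])
            for i, (x, y) in enumerate(t.V):
                w.writerow([i + 1, _fmt(x), _fmt(y)])
        with open(pe, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["id", "v1", "v2"])
            for i, (u, v) in enumerate(t.E):
                w.writerow([i + 1, u + 1, v + 1])
        with open(pc, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["id"])
            for i, edges in enumerate(t.C):
                w.writerow([i + 1] + [e + 1 for e in edges])
        return [pv, pe, pc]
    if dialect.upper() == "FLAT":
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["x1", "y1", "..."])
            for ci in range(t.n_cells):
                poly = t.cell_polygon(ci)
                w.writerow([_fmt(v) for v in poly.ravel()])
        return [path]
    raise ValueError(f"unknown dialect {dialect!r}")


def load_tissue(path: str | Path, dialect: str = "VEC") -> Tissue:
    """Read a tissue saved by :func:`save_tissue` (or any conforming CSV)."""
    path = Path(path)
    if dialect.upper() == "VEC":
        with open(f"{path}.vertices.csv", newline="") as f:
            rows = list(csv.reader(f))[1:]
        V = np.array([[float(r[1]), float(r[2])] for r in rows]).reshape(-1, 2)
        with open(f"{path}.edges.csv", newline="") as f:
            rows = list(csv.reader(f))[1:]
        E = np.array([[int(r[1]) - 1, int(r[2]) - 1] for r in rows], dtype=int)
        E = E.reshape(-1, 2)
        with open(f"{path}.cells.csv", newline="") as f:
            rows = list(csv.reader(f))[1:]
        C = [[int(e) - 1 for e in r[1:]] for r in rows]
        t = Tissue(V, E, C)
        validate_tissue(t)
        return t
    if dialect.upper() == "FLAT":
        with open(path, newline="") as f:
            rows = [r for r in csv.reader(f) if r]
        polys = []
        for r in rows[1:]:
            vals = np.array([float(v) for v in r])
            polys.append(vals.reshape(-1, 2))
        return tissue_from_polygons(polys)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def hex_template(rings: int, side: float = 1.0) -> Tissue:
    """Centered hexagonal array: one central cell surrounded by ``rings`` shells.

    Cells are regular hexagons with circumradius ``side`` (which is also
    the wall length); the cell count is the centered hexagonal number
    3·rings·(rings+1)+1.
    """
    if rings < 0:
        raise ValueError("rings must be >= 0")
    s = float(side)
    ang = np.pi / 6 + np.pi / 3 * np.arange(6)
    hexagon = s * np.column_stack([np.cos(ang), np.sin(ang)])
    polys = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if max(abs(q), abs(r), abs(q + r)) > rings:
                continue
            c = np.array([math.sqrt(3) * s * (q + r / 2.0), 1.5 * s * r])
            polys.append(c + hexagon)
    return tissue_from_polygons(polys, tol=1e-9 * s * max(1, rings))


def hex_grid_template(cols: int, rows: int, side: float = 1.0) -> Tissue:
    """Rectangular slab of regular hexagonal cells (``cols`` × ``rows``)."""
    if cols < 1 or rows < 1:
        raise ValueError("cols and rows must be >= 1")
    s = float(side)
    ang = np.pi / 6 + np.pi / 3 * np.arange(6)
    hexagon = s * np.column_stack([np.cos(ang), np.sin(ang)])
    polys = []
    for r in range(rows):
        for qc in range(cols):
            q = qc - r // 2  # offset -> axial, keeps rows horizontally aligned
            c = np.array([math.sqrt(3) * s * (q + r / 2.0), 1.5 * s * r])
            polys.append(c + hexagon)
    return tissue_from_polygons(polys, tol=1e-9 * s * max(cols, rows))


def region_polygon(region: str | np.ndarray | ShPolygon,
                   radius: float = 1.0,
                   parabola_a: float = 1.0,
                   parabola_h: float = 1.0,
                   n_arc: int = 256) -> ShPolygon:
    """Shapely polygon for a named template region.

    ``region`` may be ``"circle"`` (radius ``radius``), ``"semicircle"``
    (upper half-disk), ``"parabola"`` ({y >= a x^2, y <= h}), an
    ``(n, 2)`` coordinate array, or an existing shapely polygon.  Curved
    boundaries are discretized with ``n_arc`` segments.
    """
    if isinstance(region, ShPolygon):
        return region
    if isinstance(region, np.ndarray) or isinstance(region, (list, tuple)):
        return sh_orient(ShPolygon(np.asarray(region, dtype=float)))
    R = float(radius)
    if region == "circle":
        th = 2 * np.pi * np.arange(n_arc) / n_arc
        return ShPolygon(np.column_stack([R * np.cos(th), R * np.sin(th)]))
    if region == "semicircle":
        th = np.pi * np.arange(n_arc + 1) / n_arc
        pts = np.column_stack([R * np.cos(th), R * np.sin(th)])
        return ShPolygon(pts)
    if region == "parabola":
        a, h = float(parabola_a), float(parabola_h)
        xmax = math.sqrt(h / a)
        x = np.linspace(-xmax, xmax, n_arc + 1)
        pts = np.column_stack([x, a * x * x])[::-1]
        return ShPolygon(pts)
    raise ValueError(f"unknown region {region!r}")


def voronoi_template(region: str | np.ndarray | ShPolygon = "circle",
                     n_centers: int = 100,
                     seed: int | np.random.Generator | None = 0,
                     lloyd: int = 0, min_edge: float | None = None,
                     **region_kwargs) -> Tissue:
    """Voronoi tessellation of uniform random centers inside a region.

    The tessellation is clipped to the region boundary, giving exactly one
    cell per center; the result is reproducible given ``seed``.  ``lloyd``
    rounds of centroidal (Lloyd) relaxation regularize the cells — useful
    for mechanics, where sliver cells from raw random centers make the
    equations of motion needlessly stiff.  ``min_edge`` collapses walls
    shorter than that length by merging their endpoints (same purpose).
    """
    if n_centers < 1:
        raise ValueError("n_centers must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    poly = region_polygon(region, **region_kwargs)
    minx, miny, maxx, maxy = poly.bounds
    span = max(maxx - minx, maxy - miny)
    pts = np.empty((n_centers, 2))
    got = 0
    while got < n_centers:
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(4 * (n_centers - got) + 8, 2))
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        take = cand[inside][: n_centers - got]
        pts[got: got + len(take)] = take
        got += len(take)
    if n_centers == 1:
        ring = np.asarray(poly.exterior.coords)[:-1]
        return tissue_from_polygons([ring])
    # ghost points far outside bound every region of interest
    cx, cy = poly.centroid.x, poly.centroid.y
    th = 2 * np.pi * np.arange(24) / 24
    ghosts = np.column_stack([cx + 10 * span * np.cos(th), cy + 10 * span * np.sin(th)])

    def clip_cells(pts: np.ndarray) -> list:
        for attempt in range(5):
            try:
                vor = Voronoi(np.vstack([pts, ghosts]))
                break
            except QhullError:
                warnings.warn("degenerate Voronoi centers; retrying with jitter")
                pts = pts + rng.normal(scale=1e-9 * span, size=pts.shape)
        else:  # pragma: no cover
            raise RuntimeError("Voronoi construction failed after jitter retries")
        cells = []
        for i in range(n_centers):
            reg = vor.regions[vor.point_region[i]]
            clipped = ShPolygon(vor.vertices[reg]).intersection(poly)
            if clipped.geom_type == "MultiPolygon":  # non-convex user region
                clipped = max(clipped.geoms, key=lambda g: g.area)
            cells.append(sh_orient(clipped))
        return cells

    cells = clip_cells(pts)
    for _ in range(lloyd):
        pts = np.array([[c.centroid.x, c.centroid.y] for c in cells])
        cells = clip_cells(pts)
    polys = [np.asarray(c.exterior.coords)[:-1] for c in cells]
    tol = max(1e-9 * span, min_edge) if min_edge else 1e-9 * span
    return tissue_from_polygons(polys, tol=tol)
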