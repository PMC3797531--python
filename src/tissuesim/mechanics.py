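"""Spring-pressure vertex mechanics, wall growth, and dilution.

Each tissue edge carries a Hookean spring with rest length delta and
spring constant k; each cell exerts an outward pressure P on its walls.
Vertex motion is overdamped (velocity proportional to force):

    dx_i/dt = sum_edges k_r (x_j - x_i)(1 - delta_r / l_r)
            + sum_(edge, owning cell) 1/2 P_a l_r n_{a,r}

where n_{a,r} is the outward unit normal of wall r with respect to cell a
and the pressure force of each wall is split evenly between its two
endpoints.  Extended springs pull their endpoints together; pressure
drives expansion.  Irreversible wall growth raises the rest length at a
rate proportional to the extension beyond rest:

    d delta_r/dt = mu_r * max(l_r - delta_r, 0)

With mu = 0 the tissue relaxes sigmoidally to a finite size whenever
P < 2k (shown exactly for a square cell below); with mu > 0 growth is
sustained.  Concentrations in growing cells are diluted by the area
change: each species receives the correction term -[X] (dA/dt)/A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .arrows import ODETermSet
from .mesh import BOUNDARY, GeometryCache, Tissue


def theta_plus(x):
    """Ramp function (x + |x|)/2: identity for x >= 0, zero otherwise."""
    x = np.asarray(x, dtype=float)
    out = 0.5 * (x + np.abs(x))
    return out if out.ndim else float(out)


def _per_edge(value, n_edges: int, env=None) -> np.ndarray:
    if callable(value):
        value = value(env)
    return np.broadcast_to(np.asarray(value, dtype=float), (n_edges,)).copy()


def _per_cell(value, n_cells: int, env=None) -> np.ndarray:
    if callable(value):
        value = value(env)
    return np.broadcast_to(np.asarray(value, dtype=float), (n_cells,)).copy()


@dataclass
class MechState:
    """Mechanical state/parameters of a tissue.

    ``delta``: per-edge rest lengths.  ``k_spring``, ``pressure`` and
    ``mu`` may each be a scalar, a per-edge/per-cell array, or a callable
    of the simulation environment returning one (this is how constituent
    feedback such as P[i] = p0 + p1 W[i] enters).
    """

    delta: np.ndarray
    k_spring: float | np.ndarray | Callable = 1.0
    pressure: float | np.ndarray | Callable = 0.0
    mu: float | np.ndarray | Callable = 0.0

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.delta <= 0):
            raise ValueError("rest lengths must be positive")


def linear_feedback(base: float, coeff: float, species: str, *, pair: bool = False):
    """Constituent feedback law ``base + coeff * [S]``.

    With ``pair=True`` (for per-edge laws) the species term is the sum
    over the cells abutting the edge, ``base + coeff ([S_p] + [S_q])``;
    boundary edges use their single abutting cell.
    """

    def law(env):
        w = env.conc(species)
        if not pair:
            return base + coeff * w
        ec = env.geom.edge_cells
        a = np.where(ec[:, 0] == BOUNDARY, ec[:, 1], ec[:, 0])
        b = ec[:, 1]
        wb = np.where(b == BOUNDARY, 0.0, w[np.clip(b, 0, None)])
        return base + coeff * (w[a] + wb)

    return law


@dataclass
class GrowthSpec:
    """Growth-arrow parameters: pressure, rest-length growth rate, spring law."""

    pressure: float | Callable = 0.0
    growth_rate: float | Callable = 0.0
    spring: float | Callable = 1.0


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------

def vertex_velocities(t: Tissue, g: GeometryCache, m: MechState,
                      env=None) -> np.ndarray:
    """Overdamped vertex velocities from spring and pressure forces."""
    if np.any(g.edge_lengths <= 0):
        raise ValueError("zero-length edge: singular geometry")
    vel = np.zeros_like(t.V)
    k = _per_edge(m.k_spring, t.n_edges, env)
    P = _per_cell(m.pressure, t.n_cells, env)
    i, j = t.E[:, 0], t.E[:, 1]
    dx = t.V[j] - t.V[i]
    coef = (k * (1.0 - m.delta / g.edge_lengths))[:, None]
    np.add.at(vel, i, coef * dx)
    np.add.at(vel, j, -coef * dx)
    for (ci, e), n in g.normals.items():
        f = 0.5 * P[ci] * g.edge_lengths[e] * n
        vel[t.E[e, 0]] += f
        vel[t.E[e, 1]] += f
    return vel


def rest_length_rates(m: MechState, g: GeometryCache, env=None) -> np.ndarray:
    """d delta/dt = mu * max(l - delta, 0) per edge."""
    mu = _per_edge(m.mu, len(m.delta), env)
    return mu * theta_plus(g.edge_lengths - m.delta)


def area_rates(t: Tissue, velocities: np.ndarray) -> np.ndarray:
    """dA/dt per cell: time derivative of the shoelace formula."""
    out = np.empty(t.n_cells)
    for ci, loop in enumerate(t.vertex_loops()):
        x, y = t.V[loop, 0], t.V[loop, 1]
        vx, vy = velocities[loop, 0], velocities[loop, 1]
        xb, yb = np.roll(x, -1), np.roll(y, -1)
        vxb, vyb = np.roll(vx, -1), np.roll(vy, -1)
        out[ci] = 0.5 * np.sum(vx * yb + x * vyb - vxb * y - xb * vy)
    return out


def dilution_terms(species: Iterable[str], t: Tissue, g: GeometryCache,
                   velocities: np.ndarray) -> ODETermSet:
    """Concentration corrections -[X_i] (dA_i/dt)/A_i due to area change."""
    dA = area_rates(t, velocities)
    rel = dA / g.areas
    ts = ODETermSet()
    for name in species:
        for ci in range(t.n_cells):
            def fn(state, tt, name=name, ci=ci, r=float(rel[ci])):
                return -state[(name, ci)] * r

            ts.add((name, ci), fn)
    return ts


# ---------------------------------------------------------------------------
# Square-cell closed form (analytic oracle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SquareCellGrowth:
    """Exact perimeter dynamics of a single square cell with mu = 0.

    Summing the spring and pressure forces over the four vertices of a
    square with uniform spring constant k, pressure P and total rest
    length Delta gives the relative perimeter growth rate

        (1/L) dL/dt = P - 2k + 2 k Delta / L.

    For P < 2k this relaxes sigmoidally to the finite equilibrium
    L* = 2 k Delta / (2k - P); for P >= 2k growth is unbounded.
    """

    k: float
    P: float
    Delta: float

    @property
    def bounded(self) -> bool:
        return self.P < 2.0 * self.k

    @property
    def equilibrium_perimeter(self) -> float | None:
        if not self.bounded:
            return None
        return 2.0 * self.k * self.Delta / (2.0 * self.k - self.P)

    def relative_growth_rate(self, L):
        return self.P - 2.0 * self.k + 2.0 * self.k * self.Delta / np.asarray(L, float)

    def perimeter_rate(self, L):
        return np.asarray(L, float) * self.relative_growth_rate(L)


def square_cell_closed_form(k: float, P: float, Delta: float) -> SquareCellGrowth:
    """Analytic square-cell growth law; see :class:`SquareCellGrowth`."""
    return SquareCellGrowth(float(k), float(P), float(Delta))


def spring_energy(t: Tissue, g: GeometryCache, m: MechState, env=None) -> float:
    """Total Hookean potential 1/2 sum k (delta - l)^2 over edges."""
    k = _per_edge(m.k_spring, t.n_edges, env)
    return float(0.5 * np.sum(k * (m.delta - g.edge_lengths) ** 2))
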