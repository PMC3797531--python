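"""Simulation engine: model compilation, static and growing runs, trajectories.

A :class:`ModelSpec` (reactions + intercellular arrows + optional growth
and division arrows) is compiled against a tissue into one ODE system:
every single-cell reaction is replicated into every cell, intercellular
arrows are expanded over the wall topology, and in growing mode the
vertex positions and wall rest lengths become state variables alongside
the concentrations, with dilution corrections applied to every non-fixed
species.  Fixed species (Dirichlet boundary conditions) are excluded
from the state vector but visible to every rate expression.

Integration uses ``scipy.integrate.solve_ivp`` with LSODA by default,
which switches between a non-stiff Adams method and a stiff BDF method.
In growing mode, cell division is located by the integrator's event
root-finding on (threshold variable - per-cell threshold); at each event
the triggering cells are divided in cell-index order, the system is
recompiled for the new topology, daughter thresholds are drawn from one
seed-keyed RNG stream, and integration resumes.  Lineage is recorded as
(parent, daughters, time, wall) tuples keyed by persistent cell uids.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .arrows import ArrowError, MassAction, Reaction, reaction_flux
from .division import DivisionSpec, LineageRecord, divide_cell, place_wall, \
    sample_threshold
from .intercellular import DiffusionArrow, IGRNArrow, TransportArrow, \
    IntercellularArrow, _wall_fn
from .mesh import BOUNDARY, Tissue, edge_cell_adjacency, save_tissue
from .mechanics import GrowthSpec


class EngineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class SpeciesDef:
    """Declared species: initial condition and (possibly per-cell) fixedness.

    ``initial`` may be a scalar, a per-cell array, or a callable
    ``(tissue, geom_env) -> array``.  ``fixed`` may be a bool, the string
    ``"boundary"`` (fixed in cells owning a tissue-boundary wall), or a
    callable returning a per-cell bool mask.
    """

    name: str
    initial: float | np.ndarray | Callable = 0.0
    fixed: bool | str | Callable = False


@dataclass
class ModelSpec:
    """A complete model: arrows, parameters, species, indicators."""

    reactions: list[Reaction] = dc_field(default_factory=list)
    intercellular: list[IntercellularArrow] = dc_field(default_factory=list)
    growth: GrowthSpec | None = None
    division: DivisionSpec | None = None
    parameters: dict[str, float] = dc_field(default_factory=dict)
    species: list[SpeciesDef] = dc_field(default_factory=list)
    indicators: dict[str, Callable] = dc_field(default_factory=dict)

    def species_names(self) -> list[str]:
        names = [sd.name for sd in self.species]
        for rxn in self.reactions:
            for sp in rxn.species():
                if sp.name not in names:
                    names.append(sp.name)
        for arrow in self.intercellular:
            for nm in _arrow_species(arrow):
                if nm not in names:
                    names.append(nm)
        return names


def _arrow_species(arrow: IntercellularArrow) -> list[str]:
    if isinstance(arrow, (DiffusionArrow, TransportArrow)):
        return [arrow.species]
    return [arrow.source, arrow.target]


# ---------------------------------------------------------------------------
# Evaluation environment
# ---------------------------------------------------------------------------

class _GeomArrays:
    """Vectorized geometry snapshot used inside the RHS."""

    __slots__ = ("areas", "edge_lengths", "edge_cells", "centroids")

    def __init__(self, areas, edge_lengths, edge_cells, centroids):
        self.areas = areas
        self.edge_lengths = edge_lengths
        self.edge_cells = edge_cells
        self.centroids = centroids


class Env:
    """Read-only view of the current simulation state for rate expressions."""

    def __init__(self, system: "ODESystem", t: float, C: np.ndarray,
                 geom: _GeomArrays):
        self.system = system
        self.t = t
        self.C = C
        self.geom = geom
        self.tissue = system.tissue

    def conc(self, name: str) -> np.ndarray:
        return self.C[:, self.system.species_index[name]]

    def indicator(self, name: str) -> np.ndarray:
        return self.system.indicator_values[name]

    def param(self, name: str) -> float:
        return self.system.model.parameters[name]

    def __getitem__(self, key):
        # mapping-style access used by intercellular wall callables
        name, ci = key
        return self.C[ci, self.system.species_index[name]]


# ---------------------------------------------------------------------------
# Compiled system
# ---------------------------------------------------------------------------

class ODESystem:
    """A model compiled against one tissue topology."""

    def __init__(self, model: ModelSpec, tissue: Tissue, mode: str = "static"):
        if mode not in ("static", "growing"):
            raise EngineError(f"unknown mode {mode!r}")
        if mode == "static" and (model.growth is not None or model.division is not None):
            raise EngineError("grow/divide arrows are not allowed in static mode")
        if mode == "growing" and model.growth is None:
            raise EngineError("growing mode requires a growth specification")
        self.model = model
        self.tissue = tissue
        self.mode = mode
        self.species_names = model.species_names()
        self.species_index = {n: i for i, n in enumerate(self.species_names)}
        self.n_cells = tissue.n_cells
        self.n_species = len(self.species_names)
        self._build_topology_arrays()
        self._build_indicators()
        self._build_fixed_and_initial()
        self._compile_reactions()
        self._compile_intercellular()
        nf = len(self.free_flat)
        self.n_conc_state = nf
        if mode == "growing":
            self.n_state = nf + 2 * tissue.n_vertices + tissue.n_edges
        else:
            self.n_state = nf
            self._static_geom = self._geometry(tissue.V)

    # -- construction ------------------------------------------------------

    def _build_topology_arrays(self) -> None:
        t = self.tissue
        loops = t.vertex_loops()
        pu, pv, pcell, pedge = [], [], [], []
        edge_of = {frozenset(map(int, t.E[e])): e for c in t.C for e in c}
        for ci, loop in enumerate(loops):
            n = len(loop)
            for i in range(n):
                u, v = int(loop[i]), int(loop[(i + 1) % n])
                pu.append(u)
                pv.append(v)
                pcell.append(ci)
                pedge.append(edge_of[frozenset((u, v))])
        self.pu = np.asarray(pu, dtype=int)
        self.pv = np.asarray(pv, dtype=int)
        self.pcell = np.asarray(pcell, dtype=int)
        self.pedge = np.asarray(pedge, dtype=int)
        self.edge_cells = edge_cell_adjacency(t)
        inter = (self.edge_cells != BOUNDARY).all(axis=1)
        self.interior_edges = np.where(inter)[0]
        self.boundary_edges = np.where(~inter)[0]
        self.boundary_owner = np.where(
            self.edge_cells[self.boundary_edges, 0] != BOUNDARY,
            self.edge_cells[self.boundary_edges, 0],
            self.edge_cells[self.boundary_edges, 1])
        bcells = np.zeros(t.n_cells, dtype=bool)
        bcells[self.boundary_owner] = True
        self.boundary_cells = bcells

    def _geometry(self, V: np.ndarray) -> _GeomArrays:
        x, y = V[:, 0], V[:, 1]
        cross = x[self.pu] * y[self.pv] - x[self.pv] * y[self.pu]
        areas = 0.5 * np.bincount(self.pcell, cross, minlength=self.n_cells)
        dv = V[self.tissue.E[:, 1]] - V[self.tissue.E[:, 0]]
        lengths = np.hypot(dv[:, 0], dv[:, 1])
        counts = np.bincount(self.pcell, minlength=self.n_cells)
        cx = np.bincount(self.pcell, x[self.pu], minlength=self.n_cells) / counts
        cy = np.bincount(self.pcell, y[self.pu], minlength=self.n_cells) / counts
        return _GeomArrays(areas, lengths, self.edge_cells,
                           np.column_stack([cx, cy]))

    def _build_indicators(self) -> None:
        geom = self._geometry(self.tissue.V)
        self.indicator_values = {
            name: np.asarray(fn(self.tissue, geom), dtype=float)
            for name, fn in self.model.indicators.items()}

    def _build_fixed_and_initial(self) -> None:
        n_c, n_s = self.n_cells, self.n_species
        geom = self._geometry(self.tissue.V)
        self.fixed_mask = np.zeros((n_c, n_s), dtype=bool)
        self.initial_conc = np.zeros((n_c, n_s))
        declared = {sd.name: sd for sd in self.model.species}
        for name, si in self.species_index.items():
            sd = declared.get(name)
            if sd is None:
                continue
            init = sd.initial
            if callable(init):
                init = init(self.tissue, geom)
            self.initial_conc[:, si] = np.broadcast_to(
                np.asarray(init, dtype=float), (n_c,))
            fx = sd.fixed
            if fx == "boundary":
                mask = self.boundary_cells
            elif callable(fx):
                mask = np.asarray(fx(self.tissue, geom), dtype=bool)
            else:
                mask = np.full(n_c, bool(fx))
            self.fixed_mask[:, si] = mask
        self.free_flat = np.where(~self.fixed_mask.ravel())[0]

    def _compile_reactions(self) -> None:
        self.compiled_rxns = []
        for rxn in self.model.reactions:
            cells = {sp.cell_index for sp in rxn.species()}
            if len(cells - {None}) > 1:
                raise EngineError("a reaction may bind species to at most one cell")
            cell = next(iter(cells - {None}), None)
            changes = []
            from .arrows import stoichiometric_changes
            for sp, coeff in stoichiometric_changes(rxn).items():
                changes.append((self.species_index[sp.name], coeff))
            self.compiled_rxns.append((rxn, cell, changes))

    def _compile_intercellular(self) -> None:
        params = self.model.parameters
        self.compiled_arrows = []
        ii = self.interior_edges
        ia, ib = self.edge_cells[ii, 0], self.edge_cells[ii, 1]
        for arrow in self.model.intercellular:
            if isinstance(arrow, DiffusionArrow):
                si = self.species_index[arrow.species]
                PI = arrow.P_I if callable(arrow.P_I) else None
                PIc = None if callable(arrow.P_I) else float(
                    params.get(arrow.P_I, arrow.P_I) if isinstance(arrow.P_I, str)
                    else arrow.P_I)
                PO = arrow.P_O
                if PO is not None and isinstance(PO, str):
                    PO = float(params[PO])
                self.compiled_arrows.append(
                    ("diff", si, PIc, _wall_fn(arrow.P_I, params) if PI else None, PO))
            elif isinstance(arrow, TransportArrow):
                si = self.species_index[arrow.species]
                self.compiled_arrows.append(
                    ("trans", si, _wall_fn(arrow.f_out, params),
                     _wall_fn(arrow.f_in, params)))
            elif isinstance(arrow, IGRNArrow):
                self.compiled_arrows.append(
                    ("igrn", self.species_index[arrow.source],
                     self.species_index[arrow.target], arrow))
            else:
                raise EngineError(f"unknown intercellular arrow {arrow!r}")
        self._ia, self._ib = ia, ib

    # -- state packing -----------------------------------------------------

    def pack(self, conc: np.ndarray, V: np.ndarray | None = None,
             delta: np.ndarray | None = None) -> np.ndarray:
        parts = [conc.ravel()[self.free_flat]]
        if self.mode == "growing":
            parts.extend([V.ravel(), delta])
        return np.concatenate(parts) if len(parts) > 1 else parts[0].copy()

    def unpack(self, y: np.ndarray):
        conc = self.initial_conc.copy()
        conc[self.fixed_mask] = self._fixed_values
        conc.ravel()[self.free_flat] = y[:self.n_conc_state]
        if self.mode != "growing":
            return conc, None, None
        nv = self.tissue.n_vertices
        V = y[self.n_conc_state:self.n_conc_state + 2 * nv].reshape(nv, 2)
        delta = y[self.n_conc_state + 2 * nv:]
        return conc, V, delta

    @property
    def _fixed_values(self) -> np.ndarray:
        return self.initial_conc[self.fixed_mask]

    # -- right-hand side ---------------------------------------------------

    def _chem_rhs(self, env: Env, dC: np.ndarray) -> None:
        C = env.C
        sidx = self.species_index
        for rxn, cell, changes in self.compiled_rxns:
            if cell is None:
                conc = lambda sp: C[:, sidx[sp.name]]
            else:
                conc = lambda sp, cell=cell: C[cell, sidx[sp.name]]
            flux = reaction_flux(rxn, conc, self.model.parameters,
                                 env.t, rate_env=env)
            if cell is None:
                for sj, coeff in changes:
                    dC[:, sj] += coeff * flux
            else:
                for sj, coeff in changes:
                    dC[cell, sj] += coeff * flux

    def _intercellular_rhs(self, env: Env, dC: np.ndarray) -> None:
        geom = env.geom
        ii, ia, ib = self.interior_edges, self._ia, self._ib
        L, A = geom.edge_lengths, geom.areas
        for entry in self.compiled_arrows:
            kind = entry[0]
            if kind == "diff":
                _, si, PIc, PIf, PO = entry
                X = env.C[:, si]
                if PIf is None:
                    beta = PIc
                else:
                    beta = np.array([PIf(int(a), int(b), int(k), env)
                                     for k, a, b in zip(ii, ia, ib)])
                flux = beta * L[ii] * (X[ib] - X[ia])  # amount per unit depth
                np.add.at(dC[:, si], ia, flux / A[ia])
                np.add.at(dC[:, si], ib, -flux / A[ib])
                if PO is not None:
                    be, bo = self.boundary_edges, self.boundary_owner
                    if callable(PO):
                        bb = np.array([PO(int(c), BOUNDARY, int(k))
                                       for k, c in zip(be, bo)])
                    else:
                        bb = PO
                    np.add.at(dC[:, si], bo, -bb * L[be] * X[bo] / A[bo])
            elif kind == "trans":
                _, si, f_out, f_in = entry
                for k, a, b in zip(ii, ia, ib):
                    k, a, b = int(k), int(a), int(b)
                    fo_ab, fo_ba = f_out(a, b, k, env), f_out(b, a, k, env)
                    fi_ab, fi_ba = f_in(a, b, k, env), f_in(b, a, k, env)
                    if min(fo_ab, fo_ba, fi_ab, fi_ba) < 0:
                        raise ArrowError("transport fluxes must be non-negative")
                    net = fi_ab - fo_ab - fi_ba + fo_ba
                    dC[a, si] += L[k] / A[a] * net
                    dC[b, si] -= L[k] / A[b] * net
            else:  # igrn
                _, si, ti, arrow = entry
                from .arrows import CONTROL_FUNCTIONS
                ctrl = CONTROL_FUNCTIONS[arrow.control]
                X = env.C[:, si]
                v = arrow.v if not isinstance(arrow.v, str) \
                    else self.model.parameters[arrow.v]
                for a, b in ((ia, ib), (ib, ia)):
                    contrib = v * ctrl(arrow.h + arrow.T * X[a] ** arrow.n)
                    np.add.at(dC[:, ti], b, contrib)

    def _mech_rates(self, env: Env, V: np.ndarray, delta: np.ndarray):
        """(vertex velocities, rest-length rates, per-cell dA/dt)."""
        g = self.model.growth
        geom = env.geom
        t = self.tissue
        k = g.spring(env) if callable(g.spring) else g.spring
        P = g.pressure(env) if callable(g.pressure) else g.pressure
        mu = g.growth_rate(env) if callable(g.growth_rate) else g.growth_rate
        k = np.broadcast_to(np.asarray(k, dtype=float), (t.n_edges,))
        P = np.broadcast_to(np.asarray(P, dtype=float), (self.n_cells,))
        mu = np.broadcast_to(np.asarray(mu, dtype=float), (t.n_edges,))
        vel = np.zeros_like(V)
        i, j = t.E[:, 0], t.E[:, 1]
        dx = V[j] - V[i]
        coef = (k * (1.0 - delta / geom.edge_lengths))[:, None]
        np.add.at(vel, i, coef * dx)
        np.add.at(vel, j, -coef * dx)
        # pressure: 1/2 P_a * l * n == 1/2 P_a * (dy, -dx) along CCW traversal
        du = V[self.pv] - V[self.pu]
        f = 0.5 * P[self.pcell, None] * np.column_stack([du[:, 1], -du[:, 0]])
        np.add.at(vel, self.pu, f)
        np.add.at(vel, self.pv, f)
        ddelta = mu * np.maximum(geom.edge_lengths - delta, 0.0)
        x, y_ = V[:, 0], V[:, 1]
        vx, vy = vel[:, 0], vel[:, 1]
        dcross = (vx[self.pu] * y_[self.pv] + x[self.pu] * vy[self.pv]
                  - vx[self.pv] * y_[self.pu] - x[self.pv] * vy[self.pu])
        dA = 0.5 * np.bincount(self.pcell, dcross, minlength=self.n_cells)
        return vel, ddelta, dA

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        conc, V, delta = self.unpack(y)
        C = np.maximum(conc, 0.0)
        if V is not None:
            geom = self._geometry(V)
            self.tissue.V = V  # keep tissue coordinates current for callables
        else:
            geom = self._static_geom
        env = Env(self, t, C, geom)
        dC = np.zeros_like(C)
        self._chem_rhs(env, dC)
        self._intercellular_rhs(env, dC)
        if self.mode == "growing":
            vel, ddelta, dA = self._mech_rates(env, V, delta)
            dC -= C * (dA / geom.areas)[:, None]
            dC[self.fixed_mask] = 0.0
            return np.concatenate([dC.ravel()[self.free_flat], vel.ravel(), ddelta])
        dC[self.fixed_mask] = 0.0
        return dC.ravel()[self.free_flat]

    def jac_sparsity(self):
        """Conservative Jacobian sparsity pattern for sparse-aware solvers.

        Chemistry couples all species within a cell; intercellular arrows
        couple vertex-sharing cells; in growing mode, geometry factors and
        dilution couple each cell's concentrations to the positions of its
        (extended) vertex neighborhood, the rest lengths of incident walls,
        and the concentrations of vertex-sharing cells (pressure/spring/
        growth feedback is assumed local to the abutting cells, as with
        :func:`~tissuesim.mechanics.linear_feedback`).
        """
        from scipy.sparse import lil_matrix
        t = self.tissue
        n = self.n_state
        S = lil_matrix((n, n), dtype=bool)
        idx_map = np.full((self.n_cells, self.n_species), -1, dtype=int)
        idx_map.ravel()[self.free_flat] = np.arange(len(self.free_flat))
        loops = t.vertex_loops()
        # cells sharing at least one vertex
        cells_of_vertex: dict[int, set[int]] = {}
        for ci, loop in enumerate(loops):
            for v in loop:
                cells_of_vertex.setdefault(int(v), set()).add(ci)
        vertex_cells_ext = [set() for _ in range(self.n_cells)]
        for v, cs in cells_of_vertex.items():
            for ci in cs:
                vertex_cells_ext[ci] |= cs

        def conc_block(ci, cj):
            ii = idx_map[ci][idx_map[ci] >= 0]
            jj = idx_map[cj][idx_map[cj] >= 0]
            for a in ii:
                S[a, jj] = True

        for ci in range(self.n_cells):
            for cj in vertex_cells_ext[ci]:
                conc_block(ci, cj)
        if self.mode != "growing":
            return S.tocsc()
        nv, ne = t.n_vertices, t.n_edges
        base_v = self.n_conc_state
        base_d = base_v + 2 * nv
        # vertex 1-ring adjacency and incident edges
        vnbrs: dict[int, set[int]] = {v: {v} for v in range(nv)}
        vedges: dict[int, set[int]] = {v: set() for v in range(nv)}
        for r, (a, b) in enumerate(t.E):
            a, b = int(a), int(b)
            vnbrs[a].add(b)
            vnbrs[b].add(a)
            vedges[a].add(r)
            vedges[b].add(r)

        def vel_deps(v):
            """State indices the velocity of vertex v depends on."""
            idx = []
            ring = set().union(*(vnbrs[u] for u in vnbrs[v]))
            cells = set()
            for u in vnbrs[v]:
                cells |= cells_of_vertex.get(u, set())
            # pressure laws may read cell areas (anti-collapse terms), so
            # include the full vertex loops of every incident cell
            for cc in cells:
                ring |= set(int(x) for x in loops[cc])
                idx += list(idx_map[cc][idx_map[cc] >= 0])
            for u in ring:
                idx += [base_v + 2 * u, base_v + 2 * u + 1]
            edges = set().union(*(vedges[u] for u in vnbrs[v]))
            idx += [base_d + r for r in edges]
            return idx

        for v in range(nv):
            deps = vel_deps(v)
            S[base_v + 2 * v, deps] = True
            S[base_v + 2 * v + 1, deps] = True
        for r, (a, b) in enumerate(t.E):
            deps = [base_d + r,
                    base_v + 2 * int(a), base_v + 2 * int(a) + 1,
                    base_v + 2 * int(b), base_v + 2 * int(b) + 1]
            for cc in cells_of_vertex.get(int(a), set()) | \
                    cells_of_vertex.get(int(b), set()):
                deps += list(idx_map[cc][idx_map[cc] >= 0])
            S[base_d + r, deps] = True
        # dilution and geometry factors: conc rows of cell ci follow the
        # velocities of its loop vertices
        for ci, loop in enumerate(loops):
            rows = idx_map[ci][idx_map[ci] >= 0]
            deps: set[int] = set()
            for v in loop:
                deps.update(vel_deps(int(v)))
            deps = sorted(deps)
            for a in rows:
                S[a, deps] = True
        return S.tocsc()

    def threshold_variable(self, y: np.ndarray, spec: DivisionSpec) -> np.ndarray:
        conc, V, _ = self.unpack(y)
        if spec.variable == "area":
            return self._geometry(V).areas
        return conc[:, self.species_index[spec.variable]]


def compile(model: ModelSpec, tissue: Tissue, mode: str = "static") -> ODESystem:
    """Compile a model against a tissue into an integrable ODE system."""
    return ODESystem(model, tissue, mode)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Sample:
    t: float
    tissue: Tissue
    conc: np.ndarray            # (n_cells, n_species), full (incl. fixed)
    delta: np.ndarray | None
    cell_uids: np.ndarray


@dataclass
class Trajectory:
    species: list[str]
    samples: list[Sample] = dc_field(default_factory=list)
    lineage: list[LineageRecord] = dc_field(default_factory=list)
    events: list[dict] = dc_field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    def final(self) -> Sample:
        return self.samples[-1]

    def field(self, name: str, sample: int = -1) -> np.ndarray:
        si = self.species.index(name)
        return self.samples[sample].conc[:, si]

    def n_divisions(self) -> int:
        return len(self.lineage)


def _snap(system: ODESystem, t: float, y: np.ndarray,
          uids: np.ndarray) -> Sample:
    conc, V, delta = system.unpack(y)
    tis = Tissue((V if V is not None else system.tissue.V).copy(),
                 system.tissue.E.copy(), [list(c) for c in system.tissue.C])
    return Sample(float(t), tis, conc.copy(),
                  None if delta is None else delta.copy(), uids.copy())


# ---------------------------------------------------------------------------
# Runners
# ---------------------------------------------------------------------------

_DEFAULT_RTOL, _DEFAULT_ATOL = 1e-6, 1e-9


def _check_negative(y: np.ndarray, n_conc: int) -> None:
    m = y[:n_conc].min(initial=0.0)
    if m < -1e-9:
        warnings.warn(f"integrator produced negative concentration ({m:.2e}); "
                      "clipped to 0 in rate evaluations")


def run_static(system: ODESystem, t_span: tuple[float, float],
               init: np.ndarray | None = None, *, method: str = "LSODA",
               rtol: float = _DEFAULT_RTOL, atol: float = _DEFAULT_ATOL,
               n_samples: int = 51, t_eval: Sequence[float] | None = None
               ) -> Trajectory:
    """Integrate a compiled static system; tissue geometry stays fixed."""
    if system.mode != "static":
        raise EngineError("run_static needs a system compiled in static mode")
    conc0 = system.initial_conc if init is None else np.asarray(init, dtype=float)
    y0 = system.pack(conc0)
    if t_eval is None:
        t_eval = np.linspace(*t_span, n_samples)
    sol = solve_ivp(system.rhs, t_span, y0, method=method, rtol=rtol, atol=atol,
                    t_eval=np.asarray(t_eval, dtype=float))
    if not sol.success:
        raise EngineError(f"integration failed at t={sol.t[-1] if len(sol.t) else t_span[0]}: "
                          f"{sol.message}")
    _check_negative(sol.y.min(axis=1), system.n_conc_state)
    uids = np.arange(system.n_cells)
    traj = Trajectory(species=list(system.species_names))
    for k, t in enumerate(sol.t):
        traj.samples.append(_snap(system, t, sol.y[:, k], uids))
    return traj


def run_growing(model: ModelSpec, tissue: Tissue, t_span: tuple[float, float],
                seed: int = 0, *, method: str = "BDF",
                rtol: float = _DEFAULT_RTOL, atol: float = _DEFAULT_ATOL,
                n_samples: int = 51, max_divisions: int | None = None,
                max_events_per_time: float = 200.0,
                initial_delta_factor: float = 1.0) -> Trajectory:
    """Integrate a growing simulation with threshold-triggered division.

    Deterministic given ``seed``: one RNG stream supplies all threshold
    draws and wall tie-breaks in event order.  Stops at ``t_span[1]`` or
    after ``max_divisions`` divisions, whichever comes first.  An event
    storm (more than ``max_events_per_time`` divisions per unit time,
    averaged over a 10-division window) aborts with a diagnostic.

    The default solver is the stiff BDF method with the system's sparse
    Jacobian pattern (growing systems couple chemistry to hundreds of
    mechanical variables, which makes dense finite-difference Jacobians
    the dominant cost); pass ``method="LSODA"`` for the dense
    Adams/BDF-switching integrator used in static runs.
    """
    if model.growth is None:
        raise EngineError("growing run requires model.growth")
    spec = model.division
    rng = np.random.default_rng(seed)
    tissue = tissue.copy()
    system = compile(model, tissue, mode="growing")
    conc = system.initial_conc.copy()
    delta = None
    geom0 = system._geometry(tissue.V)
    delta = geom0.edge_lengths * initial_delta_factor
    uids = np.arange(tissue.n_cells)
    next_uid = tissue.n_cells
    thresholds = (np.array([sample_threshold(spec, rng)
                            for _ in range(tissue.n_cells)])
                  if spec is not None else None)
    traj = Trajectory(species=list(system.species_names))
    sample_times = np.linspace(*t_span, n_samples)
    t = t_span[0]
    y = system.pack(conc, tissue.V, delta)
    traj.samples.append(_snap(system, t, y, uids))
    recent_events: list[float] = []

    def do_divisions(t_now: float, y_now: np.ndarray):
        """Divide cells at/above threshold, lowest cell index first.

        One cell per pass: the system is recompiled after every division
        so velocities and geometry stay consistent, then the remaining
        over-threshold cells (including any daughter born above its own
        threshold) are re-examined.
        """
        nonlocal system, tissue, conc, delta, uids, next_uid, thresholds
        for _round in range(100_000):
            var = system.threshold_variable(y_now, spec)
            over = np.where(var >= thresholds - 1e-12)[0]
            if len(over) == 0:
                return y_now
            ci = int(over.min())
            conc_now, V_now, delta_now = system.unpack(y_now)
            tissue.V = V_now.copy()
            tissue.invalidate()
            velocities = None
            if spec.model == "potential" and spec.weights[3] > 0:
                envg = Env(system, t_now, np.maximum(conc_now, 0.0),
                           system._geometry(V_now))
                vel_all, _, _ = system._mech_rates(envg, V_now, delta_now)
                velocities = vel_all[tissue.vertex_loops()[ci]]
            poly = tissue.V[tissue.vertex_loops()[ci]]
            wall = place_wall(poly, spec, velocities=velocities, rng=rng)
            out = divide_cell(tissue, ci, wall, delta=delta_now)
            delta_now = out.delta
            conc_now = np.vstack([conc_now, conc_now[ci][None, :]])
            th_a, th_b = sample_threshold(spec, rng), sample_threshold(spec, rng)
            thresholds = np.append(thresholds, th_b)
            thresholds[ci] = th_a
            uid_a, uid_b = next_uid, next_uid + 1
            parent_uid = int(uids[ci])
            uids = np.append(uids, uid_b)
            uids[ci] = uid_a
            next_uid += 2
            traj.lineage.append(LineageRecord(
                parent=parent_uid, daughters=(uid_a, uid_b), time=float(t_now),
                wall=(tuple(out.wall_endpoints[0]), tuple(out.wall_endpoints[1])),
                thresholds=(th_a, th_b)))
            traj.events.append({"type": "division", "t": float(t_now),
                                "parent": parent_uid,
                                "daughters": [uid_a, uid_b]})
            recent_events.append(float(t_now))
            if len(recent_events) >= 10:
                window = recent_events[-1] - recent_events[-10]
                if window > 0 and 10.0 / window > max_events_per_time:
                    raise EngineError(
                        f"event storm: {10/window:.1f} divisions per unit time "
                        f"at t={t_now}")
                if window == 0 and len(recent_events) > 64:
                    raise EngineError(f"event storm at t={t_now}")
            system = compile(model, tissue, mode="growing")
            conc = conc_now
            delta = delta_now
            # new species rows keep the mother's values; fixed cells refresh
            y_now = system.pack(conc_now, tissue.V, delta_now)
            if max_divisions is not None and len(traj.lineage) >= max_divisions:
                return y_now
        raise EngineError("division cascade did not settle")

    if spec is not None:
        y = do_divisions(t, y)

    def append_sample(s: Sample) -> None:
        if traj.samples and s.t <= traj.samples[-1].t + 1e-12:
            traj.samples[-1] = s
        else:
            traj.samples.append(s)

    while t < t_span[1] - 1e-12:
        if spec is not None:
            def event(tt, yy):
                return float(np.max(system.threshold_variable(yy, spec)
                                    - thresholds))
            event.terminal = True
            event.direction = 1
            events = [event]
        else:
            events = None
        mask = (sample_times > t + 1e-12) & (sample_times < t_span[1] - 1e-12)
        t_eval = np.append(sample_times[mask], t_span[1])
        extra = {}
        if method == "BDF":
            if getattr(system, "_sparsity", None) is None:
                system._sparsity = system.jac_sparsity()
            extra["jac_sparsity"] = system._sparsity
        sol = solve_ivp(system.rhs, (t, t_span[1]), y, method=method,
                        rtol=rtol, atol=atol, t_eval=t_eval, events=events,
                        **extra)
        if not sol.success:
            raise EngineError(f"integration failed at t={t}: {sol.message}")
        for k, ts in enumerate(sol.t):
            append_sample(_snap(system, ts, sol.y[:, k], uids))
        if sol.status == 1:  # division event
            t = float(sol.t_events[0][0])
            y = sol.y_events[0][0]
            _check_negative(y, system.n_conc_state)
            y = do_divisions(t, y)
            append_sample(_snap(system, t, y, uids))
            if max_divisions is not None and len(traj.lineage) >= max_divisions:
                break
        else:
            t = t_span[1]
            y = sol.y[:, -1]
            break
    if not traj.samples or traj.samples[-1].t < t - 1e-12:
        traj.samples.append(_snap(system, t, y, uids))
    return traj


# ---------------------------------------------------------------------------
# Snapshots / export
# ---------------------------------------------------------------------------

def snapshot(trajectory: Trajectory, times: Sequence[float],
             outdir: str | Path, prefix: str = "snap") -> list[Path]:
    """Export FLAT tissue CSVs and concentration tables at selected times.

    For each requested time the nearest stored sample is written as
    ``<prefix>_t<time>.tissue.csv`` (FLAT dialect) and
    ``<prefix>_t<time>.conc.csv`` (one row per cell, one column per
    species, with the persistent cell uid).  The lineage is written once
    as ``<prefix>.lineage.csv`` and the event log as ``<prefix>.events.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ts = trajectory.times
    written = []
    for want in times:
        k = int(np.argmin(np.abs(ts - want)))
        s = trajectory.samples[k]
        tag = f"{prefix}_t{s.t:g}"
        p1 = outdir / f"{tag}.tissue.csv"
        save_tissue(s.tissue, p1, dialect="FLAT")
        p2 = outdir / f"{tag}.conc.csv"
        import csv as _csv
        with open(p2, "w", newline="") as f:
            w = _csv.writer(f)
            w.writerow(["cell", "uid"] + trajectory.species)
            for ci in range(s.tissue.n_cells):
                w.writerow([ci, int(s.cell_uids[ci])]
                           + [format(v, ".10g") for v in s.conc[ci]])
        written += [p1, p2]
    import csv as _csv
    pl = outdir / f"{prefix}.lineage.csv"
    with open(pl, "w", newline="") as f:
        w = _csv.writer(f)
        w.writerow(["parent", "daughter1", "daughter2", "time",
                    "x1", "y1", "x2", "y2"])
        for r in trajectory.lineage:
            w.writerow([r.parent, r.daughters[0], r.daughters[1],
                        format(r.time, ".10g")]
                       + [format(v, ".10g")
                          for v in (*r.wall[0], *r.wall[1])])
    pe = outdir / f"{prefix}.events.json"
    pe.write_text(json.dumps(trajectory.events, indent=1))
    return written + [pl, pe]
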