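"""Intercellular arrows: diffusion, facilitated transport, action at a distance.

These arrow forms couple the per-cell reaction networks across the tissue
topology.  Transmembrane diffusion follows Fick's law: the flux through a
wall of length l between cells i and j with permeability beta contributes
``(l/A_i) * beta * ([X_j] - [X_i])`` to cell i (and the mirror image to
cell j), so amounts ``A_i [X_i]`` are conserved across interior walls.
Boundary walls optionally exchange with a zero-concentration exterior at
permeability ``P_O``; omitting ``P_O`` closes the boundary.

Facilitated transport supplies directed wall fluxes ``f_out``/``f_in``
(defined positive), and IGRN ("intercellular gene regulatory network")
arrows let a constituent in one cell regulate production in adjacent
cells through a saturating response, skipping intermediates.

Permeabilities and fluxes may be numbers or callables ``f(i, j, k)`` /
``f(i, j, k, state)`` of (cell, neighbor, wall index); the 4-argument
form receives read-only access to current concentrations, enabling
concentration-dependent permeability.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .arrows import CONTROL_FUNCTIONS, ArrowError, ODETermSet, Param, resolve_param
from .mesh import BOUNDARY, GeometryCache, Tissue


@dataclass(frozen=True)
class DiffusionArrow:
    """``X -> X`` diffusion with interior permeability ``P_I`` and optional
    boundary permeability ``P_O`` (None = impermeable tissue boundary)."""

    species: str
    P_I: Param | Callable
    P_O: Param | Callable | None = None


@dataclass(frozen=True)
class TransportArrow:
    """Directed transmembrane transport with positive fluxes f_out/f_in."""

    species: str
    f_out: Param | Callable = 0.0
    f_in: Param | Callable = 0.0


@dataclass(frozen=True)
class IGRNArrow:
    """[X in cell i] regulates [Y in adjacent cell j]: v * ctrl(h + T [X_i]^n)."""

    source: str
    target: str
    v: Param
    T: float
    n: float = 1.0
    h: float = 0.0
    control: str = "logistic"


IntercellularArrow = DiffusionArrow | TransportArrow | IGRNArrow


def _wall_fn(p, params: Mapping[str, float] | None):
    """Normalize a wall coefficient to a callable (i, j, k, state) -> value."""
    if callable(p):
        nargs = len(inspect.signature(p).parameters)
        if nargs == 3:
            return lambda i, j, k, state: p(i, j, k)
        if nargs == 4:
            return p
        raise ArrowError("wall callables take (i, j, k) or (i, j, k, state)")
    val = resolve_param(p, params)
    return lambda i, j, k, state: val


def interior_walls(g: GeometryCache) -> list[tuple[int, int, int]]:
    """(wall index, cell a, cell b) for every interior wall."""
    return [(k, int(a), int(b)) for k, (a, b) in enumerate(g.edge_cells)
            if a != BOUNDARY and b != BOUNDARY]


def boundary_walls(g: GeometryCache) -> list[tuple[int, int]]:
    """(wall index, owning cell) for every tissue-boundary wall."""
    return [(k, int(a if a != BOUNDARY else b))
            for k, (a, b) in enumerate(g.edge_cells)
            if (a == BOUNDARY) != (b == BOUNDARY)]


def expand_diffusion(arrow: DiffusionArrow, t: Tissue, g: GeometryCache,
                     params: Mapping[str, float] | None = None) -> ODETermSet:
    """Fickian diffusion terms of one species over the tissue topology."""
    X = arrow.species
    beta = _wall_fn(arrow.P_I, params)
    ts = ODETermSet()
    for ci in range(t.n_cells):
        ts.declare((X, ci))
    for k, i, j in interior_walls(g):
        coef_i = g.edge_lengths[k] / g.areas[i]
        coef_j = g.edge_lengths[k] / g.areas[j]

        def fi(state, tt, i=i, j=j, k=k, c=coef_i):
            return c * beta(i, j, k, state) * (state[(X, j)] - state[(X, i)])

        def fj(state, tt, i=i, j=j, k=k, c=coef_j):
            return c * beta(j, i, k, state) * (state[(X, i)] - state[(X, j)])

        ts.add((X, i), fi)
        ts.add((X, j), fj)
    if arrow.P_O is not None:
        beta_o = _wall_fn(arrow.P_O, params)
        for k, i in boundary_walls(g):
            coef = g.edge_lengths[k] / g.areas[i]

            def fb(state, tt, i=i, k=k, c=coef):
                # exterior concentration is 0
                return -c * beta_o(i, BOUNDARY, k, state) * state[(X, i)]

            ts.add((X, i), fb)
    return ts


def expand_transport(arrow: TransportArrow, t: Tissue, g: GeometryCache,
                     params: Mapping[str, float] | None = None) -> ODETermSet:
    """Facilitated-transport terms: (l/A_i)(f_in(i,j,k) - f_out(i,j,k)
    - f_in(j,i,k) + f_out(j,i,k)) summed over interior walls."""
    X = arrow.species
    f_out = _wall_fn(arrow.f_out, params)
    f_in = _wall_fn(arrow.f_in, params)

    def pos(f, i, j, k, state):
        v = f(i, j, k, state)
        if np.any(np.asarray(v) < 0):
            raise ArrowError("transport fluxes must be non-negative")
        return v

    ts = ODETermSet()
    for ci in range(t.n_cells):
        ts.declare((X, ci))
    for k, i, j in interior_walls(g):
        for a, b in ((i, j), (j, i)):
            coef = g.edge_lengths[k] / g.areas[a]

            def sink(state, tt, a=a, b=b, k=k, c=coef):
                return -c * (pos(f_out, a, b, k, state) + pos(f_in, b, a, k, state))

            def source(state, tt, a=a, b=b, k=k, c=coef):
                return c * (pos(f_in, a, b, k, state) + pos(f_out, b, a, k, state))

            ts.add((X, a), sink)
            ts.add((X, a), source)
    return ts


def expand_igrn(arrow: IGRNArrow, t: Tissue, g: GeometryCache,
                params: Mapping[str, float] | None = None) -> ODETermSet:
    """Action-at-a-distance terms: every adjacent pair (i, j) adds a
    saturating production of the target in j driven by the source in i."""
    X, Y = arrow.source, arrow.target
    v = resolve_param(arrow.v, params)
    ctrl = CONTROL_FUNCTIONS[arrow.control]
    ts = ODETermSet()
    for ci in range(t.n_cells):
        ts.declare((Y, ci))
    for k, i, j in interior_walls(g):
        for a, b in ((i, j), (j, i)):  # directed pairs: source a -> target b
            def fn(state, tt, a=a):
                return v * ctrl(arrow.h + arrow.T * state[(X, a)] ** arrow.n)

            ts.add((Y, b), fn)
    return ts


def diffusion_matrix(arrow: DiffusionArrow, t: Tissue, g: GeometryCache,
                     params: Mapping[str, float] | None = None) -> np.ndarray:
    """Dense diffusion operator L with d[X]/dt = L @ [X] (constant beta only).

    In the amounts basis M = diag(A) L diag(A)^-1 this is a (negated)
    graph Laplacian: symmetric off-diagonal fluxes and zero column sums
    for a closed tissue, hence non-positive eigenvalues.
    """
    n = t.n_cells
    L = np.zeros((n, n))
    for k, i, j in interior_walls(g):
        b = arrow.P_I if not callable(arrow.P_I) else arrow.P_I(i, j, k)
        b = resolve_param(b, params)
        L[i, i] -= g.edge_lengths[k] / g.areas[i] * b
        L[i, j] += g.edge_lengths[k] / g.areas[i] * b
        L[j, j] -= g.edge_lengths[k] / g.areas[j] * b
        L[j, i] += g.edge_lengths[k] / g.areas[j] * b
    if arrow.P_O is not None:
        for k, i in boundary_walls(g):
            b = arrow.P_O if not callable(arrow.P_O) else arrow.P_O(i, BOUNDARY, k)
            L[i, i] -= g.edge_lengths[k] / g.areas[i] * resolve_param(b, params)
    return L
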