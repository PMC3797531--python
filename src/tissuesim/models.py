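"""Demonstration models, cell-layer indicators, pattern analysis, rendering.

Three ready-to-run models exercise the full simulator:

* :func:`brusselator_model` — a diffusible Brusselator, the classic
  two-species reaction network that oscillates when well mixed and forms
  stationary spatial patterns when the inhibitor diffuses much faster
  than the activator.
* :func:`wus_model` — a stem-cell-niche model for the shoot apical
  meristem: a Brusselator supplies a patterning activator A, a signal Y
  held fixed in the epidermal boundary cells diffuses inward and
  represses the organizer marker W, yielding a single central W domain
  in the intact tissue and twin lateral domains after ablating the
  central cells.
* :func:`organizer_growth_model` — a growing meristem in which tip- and
  epidermis-localized sources (U, V), a self-activating organizer W and
  a diffusible feedback species X maintain a localized W domain while
  W itself feeds back on wall pressure and growth rate, with
  Errera-rule division.

Layer indicators: L1 = cells owning a tissue-boundary wall (epidermis),
L2 = cells adjacent to L1 but not in it, TIP = cells whose centroid lies
in a configurable apex band at the top of the bounding box.  Indicators
are pure functions of topology/geometry and are re-evaluated after every
division.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import networkx as nx

from .arrows import GRN, MassAction, parse_arrow
from .division import DivisionSpec
from .engine import ModelSpec, SpeciesDef
from .intercellular import DiffusionArrow, interior_walls
from .mesh import BOUNDARY, GeometryCache, Tissue, compute_geometry, \
    edge_cell_adjacency, tissue_from_polygons, voronoi_template
from .mechanics import GrowthSpec, linear_feedback


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------

@dataclass
class IndicatorSet:
    """Boolean cell-location indicators (mutually exclusive L1/L2)."""

    L1: np.ndarray
    L2: np.ndarray
    TIP: np.ndarray


def _boundary_cells(t: Tissue) -> np.ndarray:
    adj = edge_cell_adjacency(t)
    mask = np.zeros(t.n_cells, dtype=bool)
    for a, b in adj:
        if (a == BOUNDARY) != (b == BOUNDARY):
            mask[a if a != BOUNDARY else b] = True
    return mask


def adjacency_graph(t: Tissue) -> nx.Graph:
    """Cell-adjacency graph (nodes = cell indices, edges = shared walls)."""
    g = nx.Graph()
    g.add_nodes_from(range(t.n_cells))
    adj = edge_cell_adjacency(t)
    for a, b in adj:
        if a != BOUNDARY and b != BOUNDARY:
            g.add_edge(int(a), int(b))
    return g


def classify_layers(t: Tissue, geom=None, tip_fraction: float = 0.1
                    ) -> IndicatorSet:
    """L1/L2/TIP indicators for the current tissue.

    L1 cells own at least one boundary wall; L2 cells touch an L1 cell
    without being one; TIP cells have their centroid within the top
    ``tip_fraction`` of the tissue's bounding-box height.
    """
    L1 = _boundary_cells(t)
    g = adjacency_graph(t)
    L2 = np.zeros(t.n_cells, dtype=bool)
    for ci in range(t.n_cells):
        if not L1[ci] and any(L1[nb] for nb in g.neighbors(ci)):
            L2[ci] = True
    if geom is not None and hasattr(geom, "centroids"):
        cent = np.asarray(geom.centroids)
    else:
        cent = np.array([t.cell_polygon(ci).mean(axis=0) for ci in range(t.n_cells)])
    ymax = t.V[:, 1].max()
    ymin = t.V[:, 1].min()
    cut = ymax - tip_fraction * (ymax - ymin)
    TIP = cent[:, 1] >= cut
    return IndicatorSet(L1=L1, L2=L2, TIP=TIP)


def indicator_functions(tip_fraction: float = 0.1,
                        graded_tip: bool = False) -> dict[str, Callable]:
    """Indicator callables for :class:`~tissuesim.engine.ModelSpec`.

    With ``graded_tip`` the TIP indicator is a smooth logistic profile of
    centroid height (half-maximal at the band edge, soft over half the
    band width) instead of a 0/1 membership.  Sharp membership changes
    discontinuously when an apex cell divides, which makes any signal
    produced proportionally to it jump by the weight of a whole cell; the
    graded profile changes continuously through divisions.
    """

    def make(which: str):
        def fn(t, geom):
            return getattr(classify_layers(t, geom, tip_fraction), which
                           ).astype(float)
        return fn

    def tip_graded(t, geom):
        cent = np.asarray(geom.centroids)
        ymax, ymin = t.V[:, 1].max(), t.V[:, 1].min()
        band = tip_fraction * (ymax - ymin)
        cut = ymax - band
        w = max(0.5 * band, 1e-9)
        from scipy.special import expit
        return expit((cent[:, 1] - cut) / w)

    return {"L1": make("L1"), "L2": make("L2"),
            "TIP": tip_graded if graded_tip else make("TIP")}


# ---------------------------------------------------------------------------
# Pattern analysis
# ---------------------------------------------------------------------------

@dataclass
class PatternSummary:
    """Counts of strict local maxima and connected high-expression domains."""

    n_maxima: int
    maxima_cells: list[int]
    n_domains: int
    threshold: float


def pattern_summary(values: np.ndarray, t: Tissue,
                    high_threshold: float | None = None,
                    rel_threshold: float = 0.5) -> PatternSummary:
    """Summarize a per-cell field: strict local maxima over the adjacency
    graph and connected components of {value >= threshold}.

    ``high_threshold`` defaults to ``rel_threshold`` of the way from the
    field minimum to its maximum (so it is meaningful for fields with a
    nonzero baseline).
    """
    values = np.asarray(values, dtype=float)
    if len(values) != t.n_cells:
        raise ValueError("field length must equal the cell count")
    g = adjacency_graph(t)
    maxima = [ci for ci in range(t.n_cells)
              if g.degree(ci) > 0
              and all(values[ci] > values[nb] for nb in g.neighbors(ci))]
    if t.n_cells == 1:
        maxima = [0]
    thr = (values.min() + rel_threshold * (values.max() - values.min())
           if high_threshold is None else float(high_threshold))
    high = [ci for ci in range(t.n_cells) if values[ci] >= thr]
    sub = g.subgraph(high)
    n_domains = nx.number_connected_components(sub) if high else 0
    return PatternSummary(len(maxima), maxima, n_domains, thr)


# ---------------------------------------------------------------------------
# Demonstration models
# ---------------------------------------------------------------------------

def _noise_init(base: float, amplitude: float, seed: int) -> Callable:
    def init(t, geom):
        rng = np.random.default_rng(seed)
        return base * (1.0 + amplitude * rng.uniform(-1, 1, t.n_cells))
    return init


def brusselator_model(a: float = 0.1, beta: float = 0.1, b: float = 0.9,
                      c: float = 0.1, D_A: float = 0.0, D_B: float = 0.5,
                      *, open_boundary: bool = True,
                      init_noise: float = 0.05, seed: int = 0) -> ModelSpec:
    """Diffusible Brusselator: {0 <-> A (a, beta)}, {2A+B -> 3A, c},
    {A -> B, b}, A and B diffusing with equal interior and boundary
    permeabilities (``open_boundary=False`` closes the tissue boundary
    instead, making every cell topologically equivalent under uniform
    initial conditions).

    The homogeneous fixed point is [A]* = a/beta, [B]* = b/(c [A]*).
    Initial conditions perturb it multiplicatively by up to
    ``init_noise`` (set 0 for the exactly uniform start used in
    symmetry tests).
    """
    A_star = a / beta
    B_star = b / (c * A_star)
    reactions = []
    reactions += parse_arrow("0 <-> A", rate=(a, beta))
    reactions += parse_arrow("2A + B -> 3A", rate=MassAction(c))
    reactions += parse_arrow("A -> B", rate=MassAction(b))
    species = [
        SpeciesDef("A", initial=(A_star if init_noise == 0
                                 else _noise_init(A_star, init_noise, seed))),
        SpeciesDef("B", initial=(B_star if init_noise == 0
                                 else _noise_init(B_star, init_noise, seed + 1))),
    ]
    PO_A = D_A if open_boundary else None
    PO_B = D_B if open_boundary else None
    inter = [DiffusionArrow("A", P_I=D_A, P_O=PO_A),
             DiffusionArrow("B", P_I=D_B, P_O=PO_B)]
    return ModelSpec(reactions=reactions, intercellular=inter, species=species,
                     parameters={"a": a, "beta": beta, "b": b, "c": c,
                                 "D_A": D_A, "D_B": D_B})


def wus_model(v: float = 0.1, T_WY: float = -25.0, T_WA: float = 0.5,
              h: float = 0.0, k_w: float = 0.1, k_y: float = 0.1,
              d: float = 0.5, D_Y: float = 2.0, D_A: float = 1.5,
              D_B: float = 15.0, *, a: float = 0.1, beta: float = 0.1,
              b: float = 0.19, c: float = 0.1, Y_boundary: float = 0.1,
              open_boundary: bool = False,
              init_noise: float = 0.05, seed: int = 0) -> ModelSpec:
    """WUS stem-cell-niche model driven by a Brusselator activator.

    The signal Y is held fixed at ``Y_boundary`` in the epidermal
    (boundary) cells and diffuses inward, repressing both the activator A
    (through the degradation reaction A + Y -> Y) and the organizer W
    (through its strongly negative GRN weight), so W peaks centrally.
    The GRN controlling W uses the algebraic sigma control function.

    By default the tissue boundary is treated as impermeable (the section
    boundary stands in for the epidermis): with an open boundary the
    fast-diffusing Brusselator inhibitor B drains into the
    zero-concentration exterior and the patterning instability that
    creates the central activator maximum is lost.  Set
    ``open_boundary=True`` for leaky boundary walls with permeability
    equal to the interior one.
    """
    m = brusselator_model(a, beta, b, c, D_A, D_B,
                          init_noise=init_noise, seed=seed)
    if not open_boundary:
        m.intercellular = [DiffusionArrow("A", P_I=D_A),
                           DiffusionArrow("B", P_I=D_B)]
    m.reactions += parse_arrow(
        "Y + A |-> W", rate=GRN(v=v, T=(T_WY, T_WA), n=1.0, h=h, control="sigma"))
    m.reactions += parse_arrow("W -> 0", rate=MassAction(k_w))
    m.reactions += parse_arrow("Y -> 0", rate=MassAction(k_y))
    m.reactions += parse_arrow("A + Y -> Y", rate=MassAction(d))
    m.intercellular.append(DiffusionArrow(
        "Y", P_I=D_Y, P_O=None if not open_boundary else D_Y))

    def y_init(t, geom):
        return np.where(_boundary_cells(t), Y_boundary, 0.0)

    m.species += [SpeciesDef("W", initial=0.0),
                  SpeciesDef("Y", initial=y_init, fixed="boundary")]
    m.parameters.update({"v": v, "T_WY": T_WY, "T_WA": T_WA, "h": h,
                         "k_w": k_w, "k_y": k_y, "d": d, "D_Y": D_Y,
                         "Y_boundary": Y_boundary})
    return m


def wus_fixture_tissue() -> Tissue:
    """Packaged meristem-section fixture for the stem-cell-niche model:
    a semicircular Voronoi template (radius 10, 160 cells, fixed seed)."""
    return voronoi_template("semicircle", 160, seed=11, radius=10.0)


WUS_ABLATION_RADIUS = 2.0   # central-cell removal radius for the ablation run


def organizer_fixture_tissue() -> Tissue:
    """Packaged seed tissue for the organizer-maintained growth model:
    a semicircular dome of 80 cells (radius 9), Lloyd-relaxed with short
    walls collapsed so the spring dynamics start well-conditioned.  The
    dome is several screening lengths of the tip signal U deep, which is
    what confines the organizer to the apex."""
    return voronoi_template("semicircle", 80, seed=13, radius=9.0,
                            n_arc=48, lloyd=4, min_edge=0.12)


def ablate(t: Tissue, cell_ids: Sequence[int]) -> Tissue:
    """Remove the given cells from the tissue (modelling laser ablation).

    The remaining cells are re-assembled; walls that faced an ablated
    cell become boundary walls.
    """
    keep = [ci for ci in range(t.n_cells) if ci not in set(cell_ids)]
    if not keep:
        raise ValueError("cannot ablate every cell")
    return tissue_from_polygons([t.cell_polygon(ci) for ci in keep])


def central_cells(t: Tissue, radius: float) -> list[int]:
    """Cells whose centroid is within ``radius`` of the tissue centroid."""
    cent = np.array([t.cell_polygon(ci).mean(axis=0) for ci in range(t.n_cells)])
    mid = 0.5 * (t.V.max(axis=0) + t.V.min(axis=0))
    dist = np.hypot(*(cent - mid).T)
    return [int(i) for i in np.where(dist <= radius)[0]]


def organizer_growth_model(
        k1: float = 2.0, k2: float = 0.2, k3: float = 1.0, k4: float = 0.25,
        k5: float = 1.0, k6: float = 0.05, k7: float = 7.0, k8: float = 1.5,
        k9: float = 0.1, D_U: float = 10.0, D_V: float = 0.5, D_X: float = 0.5,
        v_X: float = 1.0, v_W: float = 1.0, v_V: float = 1.0,
        h_X: float = 0.0, h_W: float = 0.0, h_V: float = 0.0,
        T_WX: float = 4.0, T_WV: float = 4.0, T_UW: float = 22.5,
        T_VW: float = -25.0, T_WW: float = 27.5,
        p0: float = 0.001, p1: float = 0.004,
        mu0: float = 5e-6, mu1: float = 0.004,
        *, spring_k: float = 1.0, threshold_mean: float | None = None,
        threshold_sd_frac: float = 0.05, tip_fraction: float = 0.2,
        division_model: str = "errera") -> ModelSpec:
    """Organizer-maintained growth model of the shoot apical meristem.

    U is produced in the TIP cells (a cytokinin-like signal), V in the
    epidermal L1 layer (a CLAVATA-like signal); both diffuse with an
    impermeable epidermis (no boundary permeability).  The organizer W is
    activated by U, repressed by V and self-activating; X mediates W's
    positive feedback onto V; the mediator Z (produced constitutively and
    removed in proportion to U) enhances W degradation away from the tip,
    with an extra L2 degradation term.  W feeds back mechanically:
    pressure P[i] = p0 + p1 W[i] and wall growth rate
    mu[r] = mu0 + mu1 (W[i] + W[j]).  Division is area-triggered with the
    Errera rule; ``threshold_mean`` defaults to twice the mean initial
    cell area at compile time (set explicitly for control).
    """
    rxns = []
    rxns += parse_arrow("0 -> U", rate=MassAction(
        lambda env, k1=k1: k1 * env.indicator("TIP")))
    rxns += parse_arrow("U -> 0", rate=MassAction(k2))
    rxns += parse_arrow("0 -> V", rate=MassAction(
        lambda env, k3=k3: k3 * env.indicator("L1")))
    rxns += parse_arrow("V -> 0", rate=MassAction(k4))
    rxns += parse_arrow("0 -> Z", rate=MassAction(k7))
    rxns += parse_arrow("Z -> 0", rate=MassAction(
        lambda env, k8=k8: k8 * env.conc("U")))
    rxns += parse_arrow("X |-> V", rate=GRN(v=v_V, T=T_WV, n=1.0, h=h_V))
    rxns += parse_arrow("U + V + W |-> W",
                        rate=GRN(v=v_W, T=(T_UW, T_VW, T_WW), n=1.0, h=h_W))
    rxns += parse_arrow("W -> 0", rate=MassAction(
        lambda env, k6=k6, k9=k9: k6 * env.conc("Z") + k9 * env.indicator("L2")))
    rxns += parse_arrow("W |-> X", rate=GRN(v=v_X, T=T_WX, n=1.0, h=h_X))
    rxns += parse_arrow("X -> 0", rate=MassAction(k5))
    inter = [DiffusionArrow("U", P_I=D_U),   # no P_O: epidermis impermeable
             DiffusionArrow("V", P_I=D_V),
             DiffusionArrow("X", P_I=D_X)]
    species = [SpeciesDef(n, initial=0.0) for n in ("U", "V", "W", "X", "Z")]
    growth = GrowthSpec(pressure=anti_collapse_pressure(p0, p1, "W"),
                        growth_rate=linear_feedback(mu0, mu1, "W", pair=True),
                        spring=spring_k)
    mean = threshold_mean if threshold_mean is not None else 1.0
    division = DivisionSpec(model=division_model, variable="area",
                            mean=mean, sd=threshold_sd_frac * mean)
    return ModelSpec(reactions=rxns, intercellular=inter, species=species,
                     growth=growth, division=division,
                     indicators=indicator_functions(tip_fraction, graded_tip=True),
                     parameters={"k1": k1, "k2": k2, "k3": k3, "k4": k4,
                                 "k5": k5, "k6": k6, "k7": k7, "k8": k8,
                                 "k9": k9, "p0": p0, "p1": p1,
                                 "mu0": mu0, "mu1": mu1})


def anti_collapse_pressure(p0: float, p1: float, species: str,
                           kappa: float = 0.05, area_floor: float = 0.5):
    """Pressure law ``p0 + p1 [S] + kappa (A_floor/A - 1)_+``.

    The first two terms are constituent feedback; the last is a
    compression back-pressure that switches on only when a cell is
    squeezed below ``area_floor`` (in absolute area units) and diverges
    as the area approaches zero.  Pure edge-spring tissues have no
    intrinsic resistance to a cell being flattened at constant perimeter;
    this term keeps crushed cells from degenerating (and the mesh from
    folding) while leaving normally-sized cells untouched.
    """

    def law(env):
        base = p0 + p1 * env.conc(species)
        A = env.geom.areas
        return base + kappa * np.maximum(area_floor / A - 1.0, 0.0)

    return law


def seed_organizer(model: ModelSpec, center: tuple[float, float] = (0.0, 7.2),
                   radius: float = 1.8, level: float = 8.0) -> None:
    """Initialize the organizer marker W in a small disk of cells.

    The organizer network is bistable per cell (W is self-activating), so
    the initial W distribution selects which cells start on the high
    branch; a localized seed under the apex reproduces the maintained
    multi-cell niche.  The seed is expressed as a callable of the tissue
    so it composes with any fixture geometry.
    """
    c = np.asarray(center, dtype=float)

    def init(t: Tissue, geom) -> np.ndarray:
        cent = np.asarray(geom.centroids)
        dist = np.hypot(*(cent - c).T)
        return np.where(dist < radius, level, 0.0)

    for sd in model.species:
        if sd.name == "W":
            sd.initial = init
            return
    model.species.append(SpeciesDef("W", initial=init))


def set_area_threshold(model: ModelSpec, tissue: Tissue,
                       factor: float = 2.0, sd_frac: float = 0.05) -> None:
    """Set the division threshold to ``factor`` times the mean cell area."""
    g = compute_geometry(tissue)
    mean = factor * float(g.areas.mean())
    model.division.mean = mean
    model.division.sd = sd_frac * mean


def run_organizer_demo(seed: int = 5, max_divisions: int = 100,
                       t_max: float = 20000.0, n_samples: int = 81,
                       threshold_factor: float = 1.8):
    """Run the organizer-maintained growth demonstration end to end.

    Builds the packaged dome fixture, configures the organizer model with
    its frozen demo conditions (apex W seed, area-division threshold at
    ``threshold_factor`` times the mean initial cell area with 5% spread)
    and integrates until ``max_divisions`` divisions have occurred.
    Deterministic given ``seed``.
    """
    from .engine import run_growing

    tissue = organizer_fixture_tissue()
    g = compute_geometry(tissue)
    model = organizer_growth_model(
        threshold_mean=threshold_factor * float(g.areas.mean()),
        threshold_sd_frac=0.05)
    seed_organizer(model)
    return run_growing(model, tissue, (0.0, t_max), seed=seed,
                       n_samples=n_samples, max_divisions=max_divisions)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render(t: Tissue, values: np.ndarray, path: str | Path,
           cmap: str = "Blues", vmin: float | None = None,
           vmax: float | None = None, title: str | None = None) -> Path:
    """Filled-polygon concentration map (SVG or PNG by file extension).

    The color scale is monotone in the field values (darker = higher by
    default); SVG output is byte-deterministic for identical inputs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    plt.rcParams["svg.hashsalt"] = "tissuesim"
    values = np.asarray(values, dtype=float)
    polys = [t.cell_polygon(ci) for ci in range(t.n_cells)]
    fig, ax = plt.subplots(figsize=(5, 5))
    pc = PolyCollection(polys, array=values, cmap=cmap, edgecolors="k",
                        linewidths=0.5)
    if vmin is not None or vmax is not None:
        pc.set_clim(vmin, vmax)
    ax.add_collection(pc)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(pc, ax=ax, shrink=0.8)
    path = Path(path)
    fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)
    return path
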