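"""Arrow-based reaction DSL: parsing, catalytic expansion, ODE term generation.

Reactions are written as compact arrow strings and compiled automatically
into ODE right-hand sides.  The canonical mass-action form
``e1 X1 + e2 X2 + ... -> f1 Y1 + ...`` with rate constant ``k`` contributes
``(f_j - e_j) * k * prod_i [X_i]^{e_i}`` to species ``U_j``.  On top of
this sit reversible (``<->``), enzymatic-expansion, and regulatory arrow
forms (Hill, GRN, S-System, NHCA, rational, user, Michaelis-Menten, MWC).

Arrow heads
-----------
``->``   irreversible mass action (one rate constant)
``<->``  reversible mass action (two rate constants; expands to two arrows)
``|->``  regulatory: inputs modulate the production of the target without
         being consumed (Hill, GRN, SSystem, NHCA, Rational, USER)
``=>``   converting: the substrate is consumed as the product is formed
         (MM, MWC, or an arbitrary flux function)

Rate-law parameters may be numbers, names resolved from a model-wide
parameter table, or (in tissue context) callables evaluated per cell.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit as logistic


def sigma_control(x):
    """Smooth saturating control function (1 + x/sqrt(1+x^2))/2.

    Monotone increasing, bounded in (0, 1), value 1/2 at 0 — an algebraic
    alternative to the logistic used by GRN-type rate laws.
    """
    x = np.asarray(x, dtype=float)
    out = 0.5 * (1.0 + x / np.sqrt(1.0 + x * x))
    return out if out.ndim else float(out)


CONTROL_FUNCTIONS: dict[str, Callable] = {
    "logistic": lambda x: logistic(np.asarray(x, dtype=float)),
    "sigma": sigma_control,
}


class ArrowError(ValueError):
    """Malformed arrow expression or rate specification."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """A chemical species, optionally bound to one cell of the tissue.

    ``cell_index=None`` means "every cell" once the model is expanded over
    a tissue.  A ``fixed`` species is held constant (no ODE state
    variable); this is how Dirichlet boundary conditions are expressed.
    """

    name: str
    cell_index: int | None = None
    fixed: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ArrowError("species name must be non-empty")

    def key(self):
        return self.name if self.cell_index is None else (self.name, self.cell_index)


class RateLaw:
    """Base class for rate laws attached to a reaction."""


Param = float | str | Callable


@dataclass(frozen=True)
class MassAction(RateLaw):
    k: Param


@dataclass(frozen=True)
class Hill(RateLaw):
    v: Param
    n: float
    K: Param
    a: float = 0.0
    T: float | Sequence[float] = 1.0


@dataclass(frozen=True)
class GRN(RateLaw):
    """Saturating-control production: v * ctrl(h + T . X^n)."""

    v: Param
    T: float | Sequence[float]
    n: float | Sequence[float] = 1.0
    h: float = 0.0
    control: str = "logistic"


@dataclass(frozen=True)
class SSystem(RateLaw):
    tau: Param
    C_plus: Param
    C_minus: Param
    n_plus: Sequence[float] | float = 1.0
    n_minus: Sequence[float] | float = 1.0


@dataclass(frozen=True)
class NHCA(RateLaw):
    v: Param
    T_plus: float | Sequence[float]
    T_minus: float | Sequence[float]
    n: float | Sequence[float] = 1.0
    m: float = 1.0
    k: Param = 1.0


@dataclass(frozen=True)
class Rational(RateLaw):
    """(a0 + a[1:] . X^n) / (d0 + d[1:] . X^m)."""

    a: Sequence[float]
    d: Sequence[float]
    m: Sequence[float] | float = 1.0
    n: Sequence[float] | float = 1.0


@dataclass(frozen=True)
class USER(RateLaw):
    """v * f(h - T . X^n) for a user-supplied saturation function f."""

    v: Param
    T: float | Sequence[float]
    n: float | Sequence[float]
    h: float
    f: Callable = field(default=lambda x: logistic(np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class MM(RateLaw):
    K: Param
    v: Param


@dataclass(frozen=True)
class MWC(RateLaw):
    k: Param
    n: float
    c: float
    L: float
    K: Param


@dataclass(frozen=True)
class FluxFunction(RateLaw):
    """User flux g(X) for the stoichiometric ``e.X => f.Y`` form."""

    g: Callable


REGULATORY_LAWS = (Hill, GRN, SSystem, NHCA, Rational, USER)
CONVERTING_LAWS = (MM, MWC, FluxFunction)


@dataclass(frozen=True)
class Reaction:
    """One elementary (or regulatory) reaction.

    ``reactants`` and ``products`` pair species with positive integer
    stoichiometries; an empty list encodes the empty set.  For regulatory
    laws the "reactants" are the regulatory inputs and are not consumed.
    ``modifier`` is the enzyme/modifier species [E] multiplying the rate.
    """

    reactants: tuple[tuple[Species, int], ...]
    products: tuple[tuple[Species, int], ...]
    rate_law: RateLaw
    modifier: Species | None = None

    def __post_init__(self) -> None:
        if not self.reactants and not self.products:
            raise ArrowError("reaction needs at least one reactant or product")
        for sp, st in (*self.reactants, *self.products):
            if st <= 0 or int(st) != st:
                raise ArrowError(f"stoichiometry of {sp.name} must be a positive integer")

    def species(self) -> list[Species]:
        out = [sp for sp, _ in (*self.reactants, *self.products)]
        if self.modifier is not None:
            out.append(self.modifier)
        return out


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(\d+)?\s*([A-Za-z_][A-Za-z0-9_]*)\s*(?:\[(\d+)\])?\s*$")


def _parse_side(side: str, arrow: str) -> list[tuple[Species, int]]:
    side = side.strip()
    if side in ("0", "", "∅"):
        return []
    out = []
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ArrowError(f"cannot parse term {term!r} in arrow {arrow!r}")
        stoich = int(m.group(1)) if m.group(1) else 1
        cell = int(m.group(3)) if m.group(3) else None
        out.append((Species(m.group(2), cell_index=cell), stoich))
    return out


def parse_arrow(spec: str,
                rate: RateLaw | tuple | None = None,
                enzyme: str | Species | None = None) -> list[Reaction]:
    """Parse one arrow expression into elementary one-directional reactions.

    ``spec`` uses the grammar ``<side> HEAD <side>`` with heads ``->``,
    ``<->``, ``|->``, ``=>`` and sides ``0`` or ``[int] name [+ ...]``;
    ``name[i]`` binds the species to cell ``i``.  A reversible arrow needs
    two rate constants, given as ``(k_forward, k_backward)`` or as a
    ``MassAction`` whose ``k`` is a 2-tuple.
    """
    if enzyme is not None and not isinstance(enzyme, Species):
        enzyme = Species(enzyme)
    for head in ("<->", "|->", "=>", "->"):
        if head in spec:
            lhs, rhs = spec.split(head, 1)
            break
    else:
        raise ArrowError(f"no arrow head found in {spec!r}")
    if any(h in rhs for h in ("<->", "|->", "=>", "->")):
        raise ArrowError(f"multiple arrow heads in {spec!r}")
    left, right = _parse_side(lhs, spec), _parse_side(rhs, spec)

    if head == "<->":
        if isinstance(rate, MassAction) and isinstance(rate.k, tuple):
            kf, kb = rate.k
        elif isinstance(rate, tuple) and len(rate) == 2:
            kf, kb = rate
            kf = kf.k if isinstance(kf, MassAction) else kf
            kb = kb.k if isinstance(kb, MassAction) else kb
        else:
            raise ArrowError(f"reversible arrow {spec!r} needs two rate constants")
        return [Reaction(tuple(left), tuple(right), MassAction(kf)),
                Reaction(tuple(right), tuple(left), MassAction(kb))]

    if isinstance(rate, tuple):
        raise ArrowError(f"one-directional arrow {spec!r} takes a single rate law")
    if rate is None:
        raise ArrowError(f"arrow {spec!r} is missing its rate law")

    if head == "->":
        if not isinstance(rate, MassAction):
            raise ArrowError(f"'->' arrows use mass action; got {type(rate).__name__}")
        return [Reaction(tuple(left), tuple(right), rate)]
    if head == "|->":
        if not isinstance(rate, REGULATORY_LAWS):
            raise ArrowError(f"'|->' arrows need a regulatory rate law, got "
                             f"{type(rate).__name__}")
        return [Reaction(tuple(left), tuple(right), rate, modifier=enzyme)]
    # head == "=>"
    if not isinstance(rate, CONVERTING_LAWS):
        raise ArrowError(f"'=>' arrows need MM, MWC or a flux function, got "
                         f"{type(rate).__name__}")
    return [Reaction(tuple(left), tuple(right), rate, modifier=enzyme)]


# ---------------------------------------------------------------------------
# Catalytic / cascade expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalyticArrow:
    """Enzymatic arrow X =(E)= Y expanded into elementary mass-action steps.

    ``mode="simple"`` is the 2-step mechanism X+E <-> X_E <-> Y+E
    (4 rate constants); ``mode="intermediate"`` adds the bound-product
    complex: X+E <-> X_E <-> Y_E <-> Y+E (6 rate constants).
    """

    substrate: str
    product: str
    enzyme: str
    rates: tuple[Param, ...]
    mode: str = "simple"


def _complex_name(a: str, b: str, taken: set[str]) -> str:
    base = f"{a}_{b}"
    name, i = base, 2
    while name in taken:
        name = f"{base}_{i}"
        i += 1
    taken.add(name)
    return name


def expand_catalytic(arrow: CatalyticArrow,
                     existing: set[str] | None = None) -> list[Reaction]:
    """Expand a catalytic arrow into irreversible elementary reactions.

    Bound complexes get deterministic underscore-joined names (``X_E``),
    with a numeric suffix if the name is already taken.
    """
    need = 4 if arrow.mode == "simple" else 6
    if arrow.mode not in ("simple", "intermediate"):
        raise ArrowError(f"unknown catalytic mode {arrow.mode!r}")
    if len(arrow.rates) != need:
        raise ArrowError(
            f"catalytic arrow {arrow.substrate}->{arrow.product} needs {need} "
            f"rate constants, got {len(arrow.rates)}")
    taken = set(existing) if existing is not None else set()
    taken |= {arrow.substrate, arrow.product, arrow.enzyme}
    X, Y, E = arrow.substrate, arrow.product, arrow.enzyme
    XE = _complex_name(X, E, taken)
    r = arrow.rates
    if arrow.mode == "simple":
        steps = [(f"{X} + {E} -> {XE}", r[0]), (f"{XE} -> {X} + {E}", r[1]),
                 (f"{XE} -> {Y} + {E}", r[2]), (f"{Y} + {E} -> {XE}", r[3])]
    else:
        YE = _complex_name(Y, E, taken)
        steps = [(f"{X} + {E} -> {XE}", r[0]), (f"{XE} -> {X} + {E}", r[1]),
                 (f"{XE} -> {YE}", r[2]), (f"{YE} -> {XE}", r[3]),
                 (f"{YE} -> {Y} + {E}", r[4]), (f"{Y} + {E} -> {YE}", r[5])]
    out = []
    for s, k in steps:
        out.extend(parse_arrow(s, MassAction(k)))
    return out


def expand_double_catalytic(substrate: str, product: str,
                            forward_enzyme: str, reverse_enzyme: str,
                            rates: tuple[Param, ...],
                            existing: set[str] | None = None) -> list[Reaction]:
    """X =(E,F)= Y: forward conversion by E, reverse conversion by F."""
    if len(rates) != 8:
        raise ArrowError("double-catalytic arrow needs 8 rate constants")
    taken = set(existing) if existing is not None else set()
    fwd = expand_catalytic(
        CatalyticArrow(substrate, product, forward_enzyme, tuple(rates[:4])), taken)
    taken |= {s.name for rx in fwd for s in rx.species()}
    rev = expand_catalytic(
        CatalyticArrow(product, substrate, reverse_enzyme, tuple(rates[4:])), taken)
    return fwd + rev


def expand_cascade(chain: Sequence[str], enzyme: str,
                   rates: Sequence[tuple[Param, ...]],
                   existing: set[str] | None = None) -> list[Reaction]:
    """Cascade X <-> Y <-> Z ... catalyzed by one enzyme, expanded pairwise."""
    if len(rates) != len(chain) - 1:
        raise ArrowError("cascade needs one rate tuple per consecutive pair")
    taken = set(existing) if existing is not None else set(chain) | {enzyme}
    out: list[Reaction] = []
    for (a, b), r in zip(zip(chain, chain[1:]), rates):
        step = expand_catalytic(CatalyticArrow(a, b, enzyme, tuple(r)), taken)
        taken |= {s.name for rx in step for s in rx.species()}
        out.extend(step)
    return out


# ---------------------------------------------------------------------------
# Rate evaluation (shared by the scalar term API and the tissue engine)
# ---------------------------------------------------------------------------

def resolve_param(p: Param, params: Mapping[str, float] | None):
    if isinstance(p, str):
        if params is None or p not in params:
            raise ArrowError(f"unresolved rate parameter {p!r}")
        return params[p]
    return p


def _vec(x, n: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1 and n > 1:
        arr = np.repeat(arr, n)
    if arr.size != n:
        raise ArrowError(f"weight/exponent vector of length {arr.size} does not "
                         f"match {n} input species")
    return arr


def rate_law_flux(law: RateLaw, X, E=1.0, params: Mapping[str, float] | None = None):
    """Evaluate the flux of a rate law.

    ``X`` is the sequence of input concentrations (each a scalar or a
    per-cell array, in reaction input order, already raised to nothing —
    stoichiometric powers are applied here), ``E`` the modifier
    concentration.  Works elementwise over arrays, so the same code serves
    single-compartment models and whole-tissue vectorized evaluation.
    """
    X = [np.asarray(x, dtype=float) for x in X]
    nin = len(X)
    R = lambda p: resolve_param(p, params)
    if isinstance(law, MassAction):
        raise ArrowError("mass-action flux needs stoichiometries; use reaction_flux")
    if isinstance(law, Hill):
        T = _vec(law.T, nin)
        u = law.a + sum(t * x for t, x in zip(T, X))
        un = np.power(u, law.n)
        return R(law.v) * np.asarray(E, dtype=float) * un / (R(law.K) ** law.n + un)
    if isinstance(law, GRN):
        T, n = _vec(law.T, nin), _vec(law.n, nin)
        u = law.h + sum(t * np.power(x, p) for t, x, p in zip(T, X, n))
        ctrl = CONTROL_FUNCTIONS[law.control]
        return R(law.v) * np.asarray(E, dtype=float) * ctrl(u)
    if isinstance(law, SSystem):
        npl, nmi = _vec(law.n_plus, nin), _vec(law.n_minus, nin)
        prod_p = np.prod([np.power(x, p) for x, p in zip(X, npl)], axis=0)
        prod_m = np.prod([np.power(x, p) for x, p in zip(X, nmi)], axis=0)
        return (np.asarray(E, dtype=float) / R(law.tau)) * (
            R(law.C_plus) * prod_p - R(law.C_minus) * prod_m)
    if isinstance(law, NHCA):
        Tp, Tm, n = _vec(law.T_plus, nin), _vec(law.T_minus, nin), _vec(law.n, nin)
        act = np.prod([np.power(1.0 + t * np.power(x, p), law.m)
                       for t, x, p in zip(Tp, X, n)], axis=0)
        rep = np.prod([np.power(1.0 + t * np.power(x, p), law.m)
                       for t, x, p in zip(Tm, X, n)], axis=0)
        return R(law.v) * np.asarray(E, dtype=float) * act / (R(law.k) * rep + act)
    if isinstance(law, Rational):
        a, d = np.asarray(law.a, float), np.asarray(law.d, float)
        n = _vec(law.n, nin) if nin else law.n
        m = _vec(law.m, nin) if nin else law.m
        num = a[0] + sum(ai * np.power(x, p) for ai, x, p in zip(a[1:], X, n))
        den = d[0] + sum(di * np.power(x, p) for di, x, p in zip(d[1:], X, m))
        return num / den
    if isinstance(law, USER):
        T, n = _vec(law.T, nin), _vec(law.n, nin)
        u = law.h - sum(t * np.power(x, p) for t, x, p in zip(T, X, n))
        return R(law.v) * law.f(u)
    if isinstance(law, MM):
        (x,) = X
        return R(law.v) * np.asarray(E, dtype=float) * x / (R(law.K) + x)
    if isinstance(law, MWC):
        (x,) = X
        al = x / R(law.K)
        c, L, n = law.c, law.L, law.n
        num = al * (1 + al) ** (n - 1) + L * c * al * (1 + c * al) ** (n - 1)
        den = (1 + al) ** n + L * (1 + c * al) ** n
        return R(law.k) * np.asarray(E, dtype=float) * num / den
    if isinstance(law, FluxFunction):
        return law.g(*X)
    raise ArrowError(f"unknown rate law {type(law).__name__}")


def reaction_flux(rxn: Reaction, conc: Callable[[Species], object],
                  params: Mapping[str, float] | None = None, t: float = 0.0,
                  rate_env=None):
    """Flux of a reaction given a concentration accessor ``conc(species)``.

    For mass action this is ``k * prod [X_i]^{e_i}``; for the other laws
    it is :func:`rate_law_flux` of the input concentrations.  A callable
    mass-action rate constant is called with ``rate_env`` (the engine's
    per-cell environment) or, if ``rate_env`` is None, with ``(conc, t)``.
    """
    law = rxn.rate_law
    E = 1.0 if rxn.modifier is None else conc(rxn.modifier)
    if isinstance(law, MassAction):
        k = law.k
        if callable(k):
            k = k(rate_env) if rate_env is not None else k(conc, t)
        else:
            k = resolve_param(k, params)
        if np.any(np.asarray(k) < 0):
            raise ArrowError("negative mass-action rate constant")
        flux = k
        for sp, st in rxn.reactants:
            flux = flux * np.power(conc(sp), st)
        return flux
    X = [conc(sp) for sp, _ in rxn.reactants]
    return rate_law_flux(law, X, E=E, params=params)


def stoichiometric_changes(rxn: Reaction) -> dict[Species, int]:
    """Net coefficient multiplying the reaction flux in each species' ODE."""
    law = rxn.rate_law
    out: dict[Species, int] = {}
    if isinstance(law, MassAction) or isinstance(law, FluxFunction):
        for sp, st in rxn.reactants:
            out[sp] = out.get(sp, 0) - st
        for sp, st in rxn.products:
            out[sp] = out.get(sp, 0) + st
        return {sp: c for sp, c in out.items() if c != 0}
    if isinstance(law, (MM, MWC)):
        for sp, _ in rxn.reactants:
            out[sp] = -1
        for sp, _ in rxn.products:
            out[sp] = +1
        return out
    # pure regulatory production: inputs are not consumed
    for sp, st in rxn.products:
        out[sp] = out.get(sp, 0) + st
    return out


# ---------------------------------------------------------------------------
# Scalar ODE term sets (single-compartment API)
# ---------------------------------------------------------------------------

class ODETermSet:
    """Additive ODE flux terms per species.

    ``terms[key]`` is a list of signed callables ``(state, t) -> float``
    where ``state`` maps species keys (name, or (name, cell)) to values.
    Fixed species map to an empty list.
    """

    def __init__(self) -> None:
        self.terms: dict[object, list[Callable]] = {}

    def add(self, key, fn: Callable) -> None:
        self.terms.setdefault(key, []).append(fn)

    def declare(self, key) -> None:
        self.terms.setdefault(key, [])

    def merge(self, other: "ODETermSet") -> "ODETermSet":
        for key, fns in other.terms.items():
            self.terms.setdefault(key, []).extend(fns)
        return self

    def rhs(self, state: Mapping, t: float = 0.0) -> dict:
        """Evaluate d/dt of every species at ``state``."""
        return {key: sum(fn(state, t) for fn in fns) if fns else 0.0
                for key, fns in self.terms.items()}


def _terms_for(rxn: Reaction, params: Mapping[str, float] | None) -> ODETermSet:
    ts = ODETermSet()

    def conc_from(state):
        return lambda sp: state[sp.key()]

    for sp in rxn.species():
        if not sp.fixed:
            ts.declare(sp.key())
    for sp, coeff in stoichiometric_changes(rxn).items():
        if sp.fixed:
            continue
        def fn(state, t, _r=rxn, _c=coeff):
            return _c * reaction_flux(_r, conc_from(state), params, t)
        ts.add(sp.key(), fn)
    return ts


def mass_action_terms(reactions: Sequence[Reaction],
                      params: Mapping[str, float] | None = None) -> ODETermSet:
    """ODE terms for a list of mass-action reactions.

    Each species U_j of each reaction receives ``(f_j - e_j) * k *
    prod_i [X_i]^{e_i}``; rate constants are validated non-negative at
    evaluation time.
    """
    ts = ODETermSet()
    for rxn in reactions:
        if not isinstance(rxn.rate_law, MassAction):
            raise ArrowError("mass_action_terms: all rate laws must be MassAction")
        ts.merge(_terms_for(rxn, params))
    return ts


def regulatory_terms(reaction: Reaction,
                     params: Mapping[str, float] | None = None) -> ODETermSet:
    """ODE terms for a single regulatory/enzymatic arrow (Hill, GRN, ...)."""
    if isinstance(reaction.rate_law, MassAction):
        raise ArrowError("regulatory_terms expects a non-mass-action rate law")
    return _terms_for(reaction, params)


def network_terms(reactions: Sequence[Reaction],
                  params: Mapping[str, float] | None = None) -> ODETermSet:
    """ODE terms for a mixed list of mass-action and regulatory reactions."""
    ts = ODETermSet()
    for rxn in reactions:
        ts.merge(_terms_for(rxn, params))
    return ts
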