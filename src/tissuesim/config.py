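"""TOML model configuration.

A model file holds the arrow list and parameter table::

    [parameters]
    a = 0.1
    beta = 0.1

    [species.A]
    initial = 1.0          # or "fixed = true" / "fixed = 'boundary'"

    [[reactions]]
    arrow = "0 <-> A"
    rate = ["a", "beta"]   # mass action: one constant, or two for <->

    [[reactions]]
    arrow = "Y + A |-> W"
    law = "GRN"
    v = "v"
    T = ["T_WY", "T_WA"]
    n = 1
    h = 0.0
    control = "sigma"

    [[intercellular]]
    kind = "diffusion"     # or "transport" / "igrn"
    species = "A"
    PI = 1.5
    PO = 1.5

    [growth]
    spring = 1.0
    pressure = { base = 0.001, coeff = 0.004, species = "W" }
    growth_rate = { base = 5e-6, coeff = 0.004, species = "W", pair = true }

    [division]
    model = "errera"
    variable = "area"
    mean = 2.0
    sd = 0.1

    [indicators]
    tip_fraction = 0.1

Numeric fields may name entries of ``[parameters]``; they are resolved
at load time.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .arrows import GRN, MM, MWC, NHCA, Hill, MassAction, Rational, SSystem, \
    USER, parse_arrow
from .division import DivisionSpec
from .engine import ModelSpec, SpeciesDef
from .intercellular import DiffusionArrow, IGRNArrow, TransportArrow
from .mechanics import GrowthSpec, linear_feedback
from .models import indicator_functions

_LAWS = {"Hill": Hill, "GRN": GRN, "SSystem": SSystem, "NHCA": NHCA,
         "Rational": Rational, "USER": USER, "MM": MM, "MWC": MWC}


class ConfigError(ValueError):
    pass


def _resolve(value, params):
    if isinstance(value, str):
        if value not in params:
            raise ConfigError(f"unknown parameter {value!r}")
        return params[value]
    if isinstance(value, list):
        return [_resolve(v, params) for v in value]
    return value


def _feedback_law(entry, params):
    if isinstance(entry, dict):
        base = _resolve(entry.get("base", 0.0), params)
        coeff = _resolve(entry.get("coeff", 0.0), params)
        if coeff == 0.0 or "species" not in entry:
            return base
        return linear_feedback(base, coeff, entry["species"],
                               pair=bool(entry.get("pair", False)))
    return _resolve(entry, params)


def load_model(path: str | Path) -> ModelSpec:
    """Load a :class:`~tissuesim.engine.ModelSpec` from a TOML file."""
    with open(path, "rb") as f:
        doc = tomllib.load(f)
    params = dict(doc.get("parameters", {}))
    model = ModelSpec(parameters=params)
    for name, tbl in doc.get("species", {}).items():
        model.species.append(SpeciesDef(
            name, initial=_resolve(tbl.get("initial", 0.0), params),
            fixed=tbl.get("fixed", False)))
    for tbl in doc.get("reactions", []):
        arrow = tbl["arrow"]
        if "law" in tbl:
            cls = _LAWS.get(tbl["law"])
            if cls is None:
                raise ConfigError(f"unknown rate law {tbl['law']!r}")
            kwargs = {k: _resolve(v, params) for k, v in tbl.items()
                      if k not in ("arrow", "law", "enzyme")}
            model.reactions += parse_arrow(arrow, rate=cls(**kwargs),
                                           enzyme=tbl.get("enzyme"))
        else:
            rate = _resolve(tbl["rate"], params)
            if isinstance(rate, list):
                rate = tuple(rate) if len(rate) == 2 else rate[0]
            if isinstance(rate, tuple):
                model.reactions += parse_arrow(arrow, rate=rate)
            else:
                model.reactions += parse_arrow(arrow, rate=MassAction(rate))
    for tbl in doc.get("intercellular", []):
        kind = tbl.get("kind", "diffusion")
        if kind == "diffusion":
            model.intercellular.append(DiffusionArrow(
                tbl["species"], P_I=_resolve(tbl["PI"], params),
                P_O=_resolve(tbl["PO"], params) if "PO" in tbl else None))
        elif kind == "transport":
            model.intercellular.append(TransportArrow(
                tbl["species"], f_out=_resolve(tbl.get("f_out", 0.0), params),
                f_in=_resolve(tbl.get("f_in", 0.0), params)))
        elif kind == "igrn":
            model.intercellular.append(IGRNArrow(
                tbl["source"], tbl["target"], v=_resolve(tbl["v"], params),
                T=_resolve(tbl.get("T", 1.0), params),
                n=_resolve(tbl.get("n", 1.0), params),
                h=_resolve(tbl.get("h", 0.0), params),
                control=tbl.get("control", "logistic")))
        else:
            raise ConfigError(f"unknown intercellular kind {kind!r}")
    if "growth" in doc:
        g = doc["growth"]
        model.growth = GrowthSpec(
            pressure=_feedback_law(g.get("pressure", 0.0), params),
            growth_rate=_feedback_law(g.get("growth_rate", 0.0), params),
            spring=_feedback_law(g.get("spring", 1.0), params))
    if "division" in doc:
        d = doc["division"]
        model.division = DivisionSpec(
            model=d.get("model", "errera"),
            variable=d.get("variable", "area"),
            mean=_resolve(d.get("mean", 1.0), params),
            sd=_resolve(d.get("sd", 0.0), params),
            weights=tuple(d.get("weights", (1.0, 1.0, 0.0, 0.0))),
            eps_L=d.get("eps_L", 0.1), eps_perp=d.get("eps_perp", 0.1))
    ind = doc.get("indicators")
    if ind is not None or model.growth is not None:
        tip = (ind or {}).get("tip_fraction", 0.1)
        model.indicators = indicator_functions(tip)
    return model
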