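"""Reaction DSL: parsing, catalytic expansion, mass-action and regulatory terms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tissuesim as ts
from tissuesim.arrows import (
    GRN, MM, NHCA, ArrowError, CatalyticArrow, Hill, MassAction, Species,
    expand_catalytic, mass_action_terms, network_terms, parse_arrow,
    regulatory_terms, sigma_control,
)


class TestParsing:
    def test_base_form(self):
        (rxn,) = parse_arrow("A -> B", rate=MassAction(2.0))
        assert rxn.reactants == ((Species("A"), 1),)
        assert rxn.products == ((Species("B"), 1),)
        assert rxn.rate_law == MassAction(2.0)

    def test_stoichiometries_and_cells(self):
        (rxn,) = parse_arrow("2A + B -> 3A", rate=MassAction("c"))
        assert rxn.reactants == ((Species("A"), 2), (Species("B"), 1))
        assert rxn.products == ((Species("A"), 3),)
        (rxn2,) = parse_arrow("X[17] -> Y[17]", rate=MassAction(1.0))
        assert rxn2.reactants[0][0].cell_index == 17

    def test_reversible_expands_to_two_opposed(self):
        fw, bw = parse_arrow("A + B <-> C", rate=(1.0, 2.0))
        assert fw.reactants == bw.products and fw.products == bw.reactants
        assert fw.rate_law == MassAction(1.0) and bw.rate_law == MassAction(2.0)

    def test_empty_side_zeroth_order(self):
        (rxn,) = parse_arrow("0 -> A", rate=MassAction(0.5))
        assert rxn.reactants == () and rxn.products == ((Species("A"), 1),)

    @pytest.mark.parametrize("bad, rate", [
        ("A >> B", MassAction(1.0)),          # unknown arrow head
        ("A -> B", None),                     # missing rate
        ("A <-> B", MassAction(1.0)),         # reversible needs two constants
        ("A -> B -> C", MassAction(1.0)),     # multiple heads
        ("A |-> B", MassAction(1.0)),         # regulatory head, mass-action law
        ("2.5A -> B", MassAction(1.0)),       # fractional stoichiometry
    ])
    def test_parse_errors(self, bad, rate):
        with pytest.raises(ArrowError):
            parse_arrow(bad, rate=rate)


class TestCatalyticExpansion:
    def test_simple_catalytic_four_steps(self):
        rxns = expand_catalytic(CatalyticArrow("X", "Y", "E", (1, 2, 3, 4)))
        assert len(rxns) == 4
        names = {sp.name for r in rxns for sp in r.species()}
        assert names == {"X", "Y", "E", "X_E"}

    def test_intermediate_catalytic_six_steps(self):
        rxns = expand_catalytic(
            CatalyticArrow("X", "Y", "E", (1, 2, 3, 4, 5, 6), mode="intermediate"))
        assert len(rxns) == 6
        names = {sp.name for r in rxns for sp in r.species()}
        assert names == {"X", "Y", "E", "X_E", "Y_E"}

    def test_double_catalytic_is_two_expansions(self):
        rxns = ts.expand_double_catalytic("X", "Y", "E", "F", tuple(range(1, 9)))
        assert len(rxns) == 8
        names = {sp.name for r in rxns for sp in r.species()}
        assert names == {"X", "Y", "E", "F", "X_E", "Y_F"}

    def test_cascade_concatenates_pairwise(self):
        rxns = ts.expand_cascade(["X", "Y", "Z"], "E",
                                 [(1, 2, 3, 4), (5, 6, 7, 8)])
        assert len(rxns) == 8
        names = {sp.name for r in rxns for sp in r.species()}
        assert names == {"X", "Y", "Z", "E", "X_E", "Y_E"}

    def test_complex_name_collision_gets_counter(self):
        rxns = expand_catalytic(CatalyticArrow("X", "Y", "E", (1, 2, 3, 4)),
                                existing={"X_E"})
        names = {sp.name for r in rxns for sp in r.species()}
        assert "X_E_2" in names

    def test_missing_rate_constants_rejected(self):
        with pytest.raises(ArrowError):
            expand_catalytic(CatalyticArrow("X", "Y", "E", (1, 2)))

    def test_enzyme_conserved_in_generated_odes(self):
        """Total enzyme [E] + [X_E] is exactly conserved by the expansion."""
        rxns = expand_catalytic(CatalyticArrow("X", "Y", "E", (1.0, 0.5, 2.0, 0.1)))
        terms = mass_action_terms(rxns)
        state = {"X": 0.7, "Y": 0.2, "E": 0.4, "X_E": 0.3}
        rhs = terms.rhs(state)
        assert rhs["E"] + rhs["X_E"] == pytest.approx(0.0, abs=1e-14)
        # and total X + Y + X_E likewise
        assert rhs["X"] + rhs["Y"] + rhs["X_E"] == pytest.approx(0.0, abs=1e-14)


class TestMassActionTerms:
    def test_hand_rule_simple(self):
        terms = mass_action_terms(parse_arrow("A -> B", rate=MassAction(2.0)))
        rhs = terms.rhs({"A": 3.0, "B": 0.0})
        assert rhs["A"] == pytest.approx(-6.0)
        assert rhs["B"] == pytest.approx(6.0)

    def test_hand_rule_autocatalytic(self):
        c = 1.7
        terms = mass_action_terms(parse_arrow("2A + B -> 3A", rate=MassAction(c)))
        A, B = 1.3, 0.9
        rhs = terms.rhs({"A": A, "B": B})
        assert rhs["A"] == pytest.approx(c * A**2 * B)     # f - e = 1
        assert rhs["B"] == pytest.approx(-c * A**2 * B)

    def test_zeroth_order_source_is_state_independent(self):
        terms = mass_action_terms(parse_arrow("0 -> A", rate=MassAction(0.25)))
        assert terms.rhs({"A": 0.0})["A"] == pytest.approx(0.25)
        assert terms.rhs({"A": 123.0})["A"] == pytest.approx(0.25)

    def test_negative_rate_constant_rejected(self):
        terms = mass_action_terms(parse_arrow("A -> B", rate=MassAction(-1.0)))
        with pytest.raises(ArrowError):
            terms.rhs({"A": 1.0, "B": 0.0})

    def test_symbolic_rate_resolved_from_table(self):
        terms = mass_action_terms(parse_arrow("A -> B", rate=MassAction("k")),
                                  params={"k": 3.0})
        assert terms.rhs({"A": 2.0, "B": 0.0})["B"] == pytest.approx(6.0)

    @settings(deadline=None, max_examples=30)
    @given(st.data())
    def test_matches_finite_differences_of_propensity_integral(self, data):
        """RHS terms equal analytic d/dX of k * prod X^e within 1e-8.

        The mass-action flux is checked against central finite differences
        of the closed-form propensity product on random small networks.
        """
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        names = ["A", "B", "C", "D"][: rng.integers(2, 5)]
        rxns = []
        for _ in range(rng.integers(1, 6)):
            nr = rng.integers(0, 3)
            npr = rng.integers(0 if nr else 1, 3)
            lhs = " + ".join(f"{rng.integers(1, 3)}{rng.choice(names)}"
                             for _ in range(nr)) or "0"
            rhs_s = " + ".join(f"{rng.integers(1, 3)}{rng.choice(names)}"
                               for _ in range(npr)) or "0"
            rxns += parse_arrow(f"{lhs} -> {rhs_s}",
                                rate=MassAction(float(rng.uniform(0.1, 2))))
        terms = mass_action_terms(rxns)
        state = {n: float(rng.uniform(0.2, 2.0)) for n in names}
        got = terms.rhs(state)
        # independent hand rule: sum (f - e) k prod X^e per reaction
        want = {n: 0.0 for n in names}
        for r in rxns:
            k = r.rate_law.k
            flux = k * np.prod([state[sp.name] ** e for sp, e in r.reactants])
            e_of = {}
            for sp, e in r.reactants:
                e_of[sp.name] = e_of.get(sp.name, 0) - e
            for sp, f in r.products:
                e_of[sp.name] = e_of.get(sp.name, 0) + f
            for n, coeff in e_of.items():
                want[n] += coeff * flux
        for n in names:
            assert got.get(n, 0.0) == pytest.approx(want[n], abs=1e-8)


class TestRegulatoryTerms:
    def test_hill_half_saturation(self):
        (rxn,) = parse_arrow("X |-> Y", rate=Hill(v=2.0, n=3, K=0.7), enzyme="E")
        rhs = regulatory_terms(rxn).rhs({"X": 0.7, "Y": 0.0, "E": 1.0})
        assert rhs["Y"] == pytest.approx(1.0)   # v [E] / 2 at [X] = K
        assert rhs["X"] == 0.0                  # inputs are not consumed

    def test_grn_logistic_at_zero_input(self):
        (rxn,) = parse_arrow("X |-> Y", rate=GRN(v=2.0, T=5.0, h=0.0), enzyme="E")
        rhs = regulatory_terms(rxn).rhs({"X": 0.0, "Y": 0.0, "E": 1.0})
        assert rhs["Y"] == pytest.approx(1.0)   # logistic(0) = 1/2

    def test_mm_half_max_and_conversion(self):
        (rxn,) = parse_arrow("X => Y", rate=MM(K=0.5, v=2.0), enzyme="E")
        rhs = regulatory_terms(rxn).rhs({"X": 0.5, "Y": 0.0, "E": 1.0})
        assert rhs["Y"] == pytest.approx(1.0)
        assert rhs["X"] == pytest.approx(-1.0)  # [Y]' = -[X]'

    def test_nhca_all_weights_zero(self):
        (rxn,) = parse_arrow("X1 + X2 |-> Y",
                             rate=NHCA(v=3.0, T_plus=0.0, T_minus=0.0, k=2.0),
                             enzyme="E")
        rhs = regulatory_terms(rxn).rhs({"X1": 1.0, "X2": 2.0, "Y": 0.0, "E": 1.0})
        assert rhs["Y"] == pytest.approx(3.0 / (2.0 + 1.0))   # v [E] / (k + 1)

    def test_weight_length_mismatch_raises(self):
        (rxn,) = parse_arrow("X1 + X2 |-> Y", rate=GRN(v=1.0, T=(1.0, 2.0, 3.0)))
        with pytest.raises(ArrowError):
            regulatory_terms(rxn).rhs({"X1": 1.0, "X2": 1.0, "Y": 0.0})

    @pytest.mark.parametrize("ctrl", [sigma_control,
                                      lambda x: 1 / (1 + np.exp(-np.asarray(x)))])
    def test_control_functions_monotone_bounded(self, ctrl):
        x = np.linspace(-50, 50, 1001)
        y = np.asarray(ctrl(x))
        assert np.all(np.diff(y) >= 0)
        core = np.abs(x) <= 10
        assert np.all(np.diff(y)[core[:-1]] > 0)
        assert np.all((y >= 0) & (y <= 1))
        assert np.all((y[core] > 0) & (y[core] < 1))
        assert ctrl(0.0) == pytest.approx(0.5)

    def test_grn_term_bounded_by_v_times_enzyme(self, rng):
        (rxn,) = parse_arrow("X |-> Y", rate=GRN(v=1.3, T=4.0, control="sigma"),
                             enzyme="E")
        terms = regulatory_terms(rxn)
        for _ in range(50):
            st_ = {"X": rng.uniform(0, 100), "Y": 0.0, "E": rng.uniform(0, 2)}
            val = terms.rhs(st_)["Y"]
            assert 0 <= val <= 1.3 * st_["E"] + 1e-12


class TestConservation:
    def test_closed_network_conserves_total(self):
        """A <-> B integrated trajectories keep [A] + [B] constant."""
        from scipy.integrate import solve_ivp
        terms = network_terms(parse_arrow("A <-> B", rate=(1.0, 0.5)))
        keys = ["A", "B"]

        def rhs(t, y):
            r = terms.rhs(dict(zip(keys, y)), t)
            return [r[k] for k in keys]

        sol = solve_ivp(rhs, (0, 10), [1.0, 0.0], rtol=1e-9, atol=1e-12,
                        dense_output=True)
        tot = sol.y.sum(axis=0)
        assert np.allclose(tot, 1.0, atol=1e-7)
        # equilibrium ratio k_f/k_b = [B]/[A]
        assert sol.y[1, -1] / sol.y[0, -1] == pytest.approx(2.0, rel=1e-5)
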