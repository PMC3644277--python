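from fractions import Fraction
from itertools import combinations

import pytest

from minnut.constraints import (
    LinearAtom,
    NutsetOracle,
    build_constraints,
    export_smtlib,
    is_satisfiable,
    nutset,
    verify_witness,
)
from minnut.exactlp import LinearConstraint, solve_feasibility


def _atom_set(system):
    """Unit-clause atoms as {(coeff-dict-items, rel)} for order-free compare."""
    return {
        (frozenset(atom.coeffs), atom.rel) for atom in system.unit_atoms()
    }


class TestExactLP:
    def test_simple_feasible_system(self):
        witness = solve_feasibility(
            {"x": "nonneg", "y": "nonneg"},
            [
                LinearConstraint((("x", Fraction(1)), ("y", Fraction(-1))), ">=",
                                 Fraction(0)),
                LinearConstraint((("y", Fraction(1)),), ">=", Fraction(1)),
            ],
        )
        assert witness is not None
        assert witness["y"] >= 1 and witness["x"] >= witness["y"]

    def test_infeasible_system(self):
        result = solve_feasibility(
            {"x": "nonneg"},
            [
                LinearConstraint((("x", Fraction(1)),), "=", Fraction(0)),
                LinearConstraint((("x", Fraction(1)),), ">=", Fraction(1)),
            ],
        )
        assert result is None

    def test_free_variable_can_go_negative(self):
        witness = solve_feasibility(
            {"x": "free"},
            [LinearConstraint((("x", Fraction(-1)),), ">=", Fraction(2))],
        )
        assert witness is not None and witness["x"] <= -2

    def test_exact_rationals_no_rounding(self):
        witness = solve_feasibility(
            {"x": "nonneg"},
            [LinearConstraint((("x", Fraction(3)),), "=", Fraction(1))],
        )
        assert witness == {"x": Fraction(1, 3)}


class TestBuildConstraints:
    def test_steady_atoms_for_example_network(self, example1_af):
        system = build_constraints(example1_af, {"A", "F"}, "steady")
        expected = {
            # B: -r1 + r2 >= 0 ; C: r1 - r2 >= 0 ; D: r1 >= 0 ; E: r2 > 0
            (frozenset({("R1", Fraction(-1)), ("R2", Fraction(1))}), ">="),
            (frozenset({("R1", Fraction(1)), ("R2", Fraction(-1))}), ">="),
            (frozenset({("R1", Fraction(1))}), ">="),
            (frozenset({("R2", Fraction(1))}), ">"),
        }
        assert _atom_set(system) == expected
        assert system.variables == {"R1": "nonneg", "R2": "nonneg"}

    def test_machinery_clauses_match_published_forms(self, example1_af):
        """Machinery clauses for B, C, D: production-positive or every
        mentioning rate zero."""
        system = build_constraints(example1_af, {"A", "F"}, "machinery")
        disjunctive = {
            prov: clause
            for clause, prov in zip(system.clauses, system.provenance)
            if len(clause.disjuncts) > 1
        }
        assert set(disjunctive) == {"B", "C", "D"}

        def clause_shape(clause):
            positive, zeros = clause.disjuncts
            (atom,) = positive
            return (
                frozenset(atom.coeffs),
                atom.rel,
                frozenset(frozenset(a.coeffs) for a in zeros),
            )

        r1 = frozenset({("R1", Fraction(1))})
        r2 = frozenset({("R2", Fraction(1))})
        assert clause_shape(disjunctive["B"]) == (
            frozenset({("R1", Fraction(-1)), ("R2", Fraction(1))}), ">", {r1, r2}
        )
        assert clause_shape(disjunctive["C"]) == (
            frozenset({("R1", Fraction(1)), ("R2", Fraction(-1))}), ">", {r1, r2}
        )
        assert clause_shape(disjunctive["D"]) == (r1, ">", {r1})

    def test_all_exempt_yields_no_clauses(self, example1):
        model = example1.copy()
        model.biomass = set()
        model.transportables = list(model.compounds)
        system = build_constraints(model, model.transportables, "steady")
        assert system.clauses == []

    def test_non_transportable_nutrient_rejected(self, example1):
        with pytest.raises(ValueError, match="non-transportables"):
            build_constraints(example1, {"E"}, "steady")

    def test_auxiliaries_are_exempt(self, example1_af):
        model = example1_af.copy()
        model.auxiliaries = {"B"}
        system = build_constraints(model, {"A", "F"}, "machinery")
        assert "B" not in system.provenance


class TestSatisfiability:
    def test_steady_feasible_with_unit_witness(self, example1_af):
        system = build_constraints(example1_af, {"A", "F"}, "steady")
        sat, witness = is_satisfiable(system)
        assert sat
        assert verify_witness(system, witness)
        # the canonical solution r1 = r2 = k also verifies directly
        assert verify_witness(system, {"R1": Fraction(1), "R2": Fraction(1)})

    def test_machinery_infeasible_on_recycling_network(self, example1_af):
        system = build_constraints(example1_af, {"A", "F"}, "machinery")
        sat, witness = is_satisfiable(system)
        assert not sat and witness is None

    def test_machinery_feasible_when_pool_compound_supplied(self, example1):
        system = build_constraints(example1, {"A", "B", "F"}, "machinery")
        sat, witness = is_satisfiable(system)
        assert sat and verify_witness(system, witness)
        assert verify_witness(system, {"R1": Fraction(2), "R2": Fraction(1)})

    def test_empty_system_all_zero(self):
        from minnut.constraints import ConstraintSystem

        sat, witness = is_satisfiable(ConstraintSystem({"r": "nonneg"}, []))
        assert sat and witness == {"r": Fraction(0)}

    def test_strict_atoms_scale_to_at_least_one(self, example1_af):
        """Homogeneity: feasible systems admit witnesses in which every strict
        expression reaches >= 1 (the solver's strict-handling strategy)."""
        system = build_constraints(example1_af, {"A", "F"}, "steady")
        _, witness = is_satisfiable(system)
        for clause in system.clauses:
            (atom,) = clause.disjuncts[0]
            if atom.rel == ">":
                value = sum(k * witness[v] for v, k in atom.coeffs)
                assert value >= 1


class TestNutset:
    @pytest.mark.parametrize(
        "nutrients,mode,expected",
        [
            ({"A", "F"}, "machinery", False),
            ({"A", "B", "F"}, "machinery", True),
            ({"A", "F"}, "steady", True),
        ],
    )
    def test_example_network_verdicts(self, example1, nutrients, mode, expected):
        assert nutset(example1, nutrients, mode) is expected

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("mode", ["steady", "machinery"])
    def test_monotone_in_nutrients(self, make_random_model, seed, mode):
        model = make_random_model(seed, n_transportables=4)
        oracle = NutsetOracle(model, mode)
        T = model.transportables
        verdicts = {
            frozenset(c): oracle(c)
            for r in range(len(T) + 1)
            for c in combinations(T, r)
        }
        for n, v in verdicts.items():
            for n2, v2 in verdicts.items():
                if n <= n2:
                    assert not (v and not v2), (sorted(n), sorted(n2))

    @pytest.mark.parametrize("seed", range(6))
    def test_machinery_implies_steady(self, make_random_model, seed):
        model = make_random_model(seed, n_transportables=4)
        mach = NutsetOracle(model, "machinery")
        steady = NutsetOracle(model, "steady")
        T = model.transportables
        for r in range(len(T) + 1):
            for combo in combinations(T, r):
                if mach(combo):
                    assert steady(combo)

    @pytest.mark.parametrize("seed", [2, 4, 7, 8])
    def test_bidirectional_encodings_agree(self, make_random_model, seed):
        """Sign-free variables with mention-clauses and split pairs with
        reactant-only clauses give the same growth verdicts."""
        model = make_random_model(seed, n_transportables=4,
                                  reversible_fraction=0.6)
        assert any(r.reversible for r in model.reactions)
        free = NutsetOracle(model, "machinery", "free-variable")
        split = NutsetOracle(model, "machinery", "split-unidirectional")
        T = model.transportables
        for r in range(len(T) + 1):
            for combo in combinations(T, r):
                assert free(combo) == split(combo), combo

    def test_oracle_memoizes(self, example1):
        oracle = NutsetOracle(example1, "machinery")
        oracle({"A", "B", "F"})
        oracle({"A", "B", "F"})
        assert oracle.n_calls == 2 and oracle.n_solver_calls == 1


def test_smtlib_export_structure(example1_af):
    text = export_smtlib(build_constraints(example1_af, {"A", "F"}, "machinery"))
    assert text.startswith("(set-logic QF_LRA)")
    assert "(declare-const |R1| Real)" in text
    assert "(or (> " in text and "(and (= " in text
    assert text.rstrip().endswith("(check-sat)")


def test_witness_verification_rejects_bad_assignment(example1_af):
    system = build_constraints(example1_af, {"A", "F"}, "steady")
    assert not verify_witness(system, {"R1": Fraction(1), "R2": Fraction(0)})
    assert not verify_witness(system, {"R1": Fraction(-1), "R2": Fraction(1)})
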