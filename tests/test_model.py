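from fractions import Fraction

import pytest

from minnut.model import (
    Compound,
    MetabolicModel,
    ParseError,
    Reaction,
    ValidationError,
    build_stoich_matrix,
    format_equation,
    load_model,
    merge_directions,
    parse_equation,
    parse_formula,
    save_model,
    split_directions,
)


@pytest.mark.parametrize(
    "text,expected",
    [
        ("CH4O", {"C": 1, "H": 4, "O": 1}),
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("Fe2S2", {"Fe": 2, "S": 2}),
        ("H", {"H": 1}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text) == expected


@pytest.mark.parametrize("bad", ["", "2H", "C6H12O6!", "ch4"])
def test_parse_formula_rejects_garbage(bad):
    with pytest.raises(ParseError):
        parse_formula(bad)


class TestEquationParsing:
    def test_coefficients_and_sides(self):
        rxn = parse_equation("R", "2 A + B -> C + 3/2 D")
        assert rxn.reactants == (("A", Fraction(2)), ("B", Fraction(1)))
        assert rxn.products == (("C", Fraction(1)), ("D", Fraction(3, 2)))
        assert not rxn.reversible

    def test_reversible_arrow(self):
        assert parse_equation("R", "A <-> B").reversible
        assert not parse_equation("R", "A -> B").reversible

    def test_duplicate_mentions_are_summed(self):
        rxn = parse_equation("R", "A + A -> B")
        assert rxn.reactants == (("A", Fraction(2)),)

    def test_round_trip_through_format(self):
        rxn = parse_equation("R", "2 A + B <-> C")
        assert parse_equation("R", format_equation(rxn)) == rxn

    @pytest.mark.parametrize("bad", ["A + B", "A -> 0.x B", "A -> -> B"])
    def test_parse_errors(self, bad):
        with pytest.raises(ParseError):
            parse_equation("R", bad)


class TestValidation:
    def test_dangling_compound_is_named(self, example1):
        example1.reactions.append(parse_equation("R3", "Q -> E"))
        with pytest.raises(ValidationError, match="Q"):
            example1.validate()

    def test_duplicate_reaction_id(self, example1):
        example1.reactions.append(example1.reactions[0])
        with pytest.raises(ValidationError, match="duplicate"):
            example1.validate()

    def test_unknown_transportable(self, example1):
        example1.transportables.append("ZZ")
        with pytest.raises(ValidationError, match="ZZ"):
            example1.validate()

    def test_nonpositive_formula_count(self):
        with pytest.raises(ValidationError):
            Compound("X", formula={"C": 0})

    def test_empty_side_requires_exchange_flag(self):
        with pytest.raises(ValidationError):
            Reaction("R", reactants=(("A", Fraction(1)),), products=())
        stub = Reaction(
            "R", reactants=(("A", Fraction(1)),), products=(), is_exchange=True
        )
        assert stub.products == ()


class TestRoundTrip:
    @pytest.mark.parametrize("fmt,suffix", [("canonical-json", ".json"),
                                            ("canonical-tsv", ".tsv")])
    def test_save_load_identity(self, tmp_path, example1, fmt, suffix):
        path = tmp_path / f"model{suffix}"
        save_model(example1, path, fmt)
        assert load_model(path, fmt) == example1

    def test_transportable_order_preserved(self, tmp_path):
        from minnut.fixtures import example1_model

        model = example1_model(transportables=("F", "B", "A"))
        path = tmp_path / "m.json"
        save_model(model, path)
        assert load_model(path).transportables == ["F", "B", "A"]

    def test_load_example_network_from_file(self, tmp_path, example1):
        path = tmp_path / "m.json"
        save_model(example1, path)
        loaded = load_model(path)
        assert len(loaded.compounds) == 6
        assert len(loaded.reactions) == 2
        assert loaded.biomass == {"E"}

    def test_equation_strings_accepted_in_json(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(
            """
            {"compounds": [{"id": "A"}, {"id": "B"}],
             "reactions": [{"id": "R1", "equation": "2 A -> B"}],
             "transportables": ["A"], "biomass": ["B"]}
            """
        )
        model = load_model(path)
        assert model.reactions[0].reactants == (("A", Fraction(2)),)

    def test_sbml_import(self, tmp_path, example1):
        import libsbml
        doc = libsbml.SBMLDocument(3, 2)
        sm = doc.createModel()
        comp = sm.createCompartment()
        comp.setId("cytosol")
        comp.setConstant(True)
        for cid in example1.compounds:
            sp = sm.createSpecies()
            sp.setId(cid)
            sp.setCompartment("cytosol")
            sp.setHasOnlySubstanceUnits(False)
            sp.setBoundaryCondition(False)
            sp.setConstant(False)
        for rxn in example1.reactions:
            sr = sm.createReaction()
            sr.setId(rxn.id)
            sr.setReversible(rxn.reversible)
            for cid, k in rxn.reactants:
                ref = sr.createReactant()
                ref.setSpecies(cid)
                ref.setStoichiometry(float(k))
                ref.setConstant(True)
            for cid, k in rxn.products:
                ref = sr.createProduct()
                ref.setSpecies(cid)
                ref.setStoichiometry(float(k))
                ref.setConstant(True)
        path = tmp_path / "m.xml"
        path.write_text(libsbml.writeSBMLToString(doc))
        model = load_model(
            path, transportables=["A", "B", "F"], biomass={"E"}
        )
        assert set(model.compounds) == set(example1.compounds)
        assert [r.id for r in model.reactions] == ["R1", "R2"]
        assert model.reactions[0].reactants == (("A", Fraction(1)), ("B", Fraction(1)))


class TestStoichMatrix:
    def test_example_network_columns(self, example1):
        m = build_stoich_matrix(example1)
        assert m.column("R1") == {
            "A": Fraction(-1), "B": Fraction(-1), "C": Fraction(1), "D": Fraction(1)
        }
        assert m.column("R2") == {
            "C": Fraction(-1), "F": Fraction(-1), "B": Fraction(1), "E": Fraction(1)
        }
        assert m.shape == (6, 2)

    def test_zero_reactions(self):
        model = MetabolicModel(
            compounds={"A": Compound("A")}, reactions=[],
            transportables=["A"], biomass=set(),
        )
        assert build_stoich_matrix(model).shape == (1, 0)

    def test_reversible_split_gives_negated_columns(self):
        model = MetabolicModel(
            compounds={"A": Compound("A"), "B": Compound("B")},
            reactions=[parse_equation("R", "A <-> B")],
            transportables=["A"], biomass={"B"},
        )
        m = build_stoich_matrix(model, "split-unidirectional")
        fwd, rev = m.column("R"), m.column("R__rev")
        assert rev == {cid: -v for cid, v in fwd.items()}

    def test_mass_balanced_columns_conserve_elements(self):
        model = MetabolicModel(
            compounds={
                "X": Compound("X", {"C": 1, "H": 2, "O": 1}),
                "Y": Compound("Y", {"C": 2, "H": 4, "O": 2}),
            },
            reactions=[parse_equation("R", "2 X -> Y")],
            transportables=["X"], biomass={"Y"},
        )
        col = build_stoich_matrix(model).column("R")
        for element in ("C", "H", "O"):
            total = sum(
                v * model.compounds[cid].formula[element] for cid, v in col.items()
            )
            assert total == 0


class TestDirectionSplitting:
    def test_all_unidirectional_unchanged(self, example1):
        assert split_directions(example1).reactions == example1.reactions

    def test_split_merge_round_trip(self):
        model = MetabolicModel(
            compounds={"A": Compound("A"), "B": Compound("B")},
            reactions=[parse_equation("R", "A <-> B")],
            transportables=["A"], biomass={"B"},
        )
        split = split_directions(model)
        assert [r.id for r in split.reactions] == ["R", "R__rev"]
        assert all(not r.reversible for r in split.reactions)
        assert merge_directions(split) == model

    def test_merge_after_deleting_one_direction(self):
        model = MetabolicModel(
            compounds={"A": Compound("A"), "B": Compound("B")},
            reactions=[parse_equation("R", "A <-> B")],
            transportables=["A"], biomass={"B"},
        )
        split = split_directions(model)
        split.reactions = [r for r in split.reactions if r.id == "R"]
        merged = merge_directions(split)
        assert len(merged.reactions) == 1
        rxn = merged.reactions[0]
        assert not rxn.reversible
        assert rxn.reactants == (("A", Fraction(1)),)
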