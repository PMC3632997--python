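"""Model readers, dependency graph, and finite-difference dependence signs."""

import pytest
import sympy

import physiomap as pm
from physiomap import expr as ex
from physiomap import fixtures as fx
from physiomap.ingest import (
    Equation,
    IngestedModel,
    ModelFormatError,
    ModelVariable,
    build_dependency_graph,
    partial_dependence_sign,
    read_equation_model,
    read_sbml,
    write_sbml,
)

SBML_L2_NO_REACTIONS = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="m">
    <listOfParameters>
      <parameter id="alpha" value="2.5"/>
      <parameter id="beta" value="0.1"/>
    </listOfParameters>
  </model>
</sbml>
"""

SBML_INHIBITED_REACTION = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="m">
    <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="S" compartment="c" initialAmount="1" boundaryCondition="false"
               hasOnlySubstanceUnits="true" constant="false"/>
      <species id="P" compartment="c" initialAmount="0" boundaryCondition="false"
               hasOnlySubstanceUnits="true" constant="false"/>
      <species id="E" compartment="c" initialAmount="1" boundaryCondition="true"
               hasOnlySubstanceUnits="true" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="r1" reversible="false">
        <listOfReactants><speciesReference species="S" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="P" stoichiometry="1" constant="true"/></listOfProducts>
        <listOfModifiers><modifierSpeciesReference species="E" sboTerm="SBO:0000020"/></listOfModifiers>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


class TestReadSbml:
    def test_no_reactions_two_parameters(self, tmp_path):
        path = tmp_path / "m.sbml"
        path.write_text(SBML_L2_NO_REACTIONS)
        model = read_sbml(path)
        assert len(model.reactions) == 0
        assert set(model.variables) == {"alpha", "beta"}
        assert model.nominal_values["alpha"] == 2.5

    def test_glycolysis_round_trip_counts(self, tmp_path, glycolysis):
        model, spec = glycolysis
        path = tmp_path / "gly.sbml"
        path.write_text(write_sbml(model))
        reread = read_sbml(path)
        assert len(reread.reactions) == spec.expected["reactions"]
        n_species = sum(
            1 for v in reread.variables.values()
            if v.annotation is not None and v.annotation.bearer
        )
        assert n_species == spec.expected["species"]
        assert sum(len(r.modifiers) for r in reread.reactions) == spec.expected["modifiers"]

    def test_round_trip_preserves_variables_annotations_reactions(
        self, tmp_path, glycolysis
    ):
        model, _spec = glycolysis
        path = tmp_path / "gly.sbml"
        path.write_text(write_sbml(model))
        reread = read_sbml(path)
        assert set(reread.variables) == set(model.variables)
        for name, var in model.variables.items():
            other = reread.variables[name]
            assert other.annotation == var.annotation, name
            assert other.is_state == var.is_state
            assert other.boundary == var.boundary
        def rxn_set(m):
            return {
                (r.id, tuple(sorted(r.reactants)), tuple(sorted(r.products)),
                 tuple(sorted(r.modifiers)), r.reversible)
                for r in m.reactions
            }
        assert rxn_set(reread) == rxn_set(model)

    def test_inhibitor_sbo_term_maps_to_negative_polarity(self, tmp_path):
        path = tmp_path / "inh.sbml"
        path.write_text(SBML_INHIBITED_REACTION)
        model = read_sbml(path)
        assert model.reactions[0].modifiers == [("E", -1)]
        assert model.variables["E"].boundary

    def test_unparseable_file_is_format_error(self, tmp_path):
        path = tmp_path / "junk.sbml"
        path.write_text("this is not xml")
        with pytest.raises(ModelFormatError):
            read_sbml(path)


class TestReadEquationModel:
    def test_pressure_driven_flow(self, tmp_path):
        path = tmp_path / "flow.eqn"
        path.write_text(
            "var F {property: opbx:FluidFlowRate}\n"
            "var P1 {property: opbx:FluidPressure, entity: fmax:PortionOfBlood}\n"
            "var P2 {property: opbx:FluidPressure, entity: fmax:Aorta}\n"
            "eq F = (P1 - P2) / R\n"
        )
        model = read_equation_model(path)
        assert len(model.variables) >= 4  # F, P1, P2 and auto-declared R
        assert len(model.equations) == 1
        ann = model.variables["F"].annotation
        assert ann is not None and ann.property_term == "opbx:FluidFlowRate"
        assert model.variables["R"].annotation is None
        assert any("R" in w for w in model.warnings)

    def test_empty_file_gives_empty_model(self, tmp_path):
        path = tmp_path / "empty.eqn"
        path.write_text("")
        model = read_equation_model(path)
        assert model.variables == {} and model.equations == []

    def test_derivative_marks_state(self, tmp_path):
        path = tmp_path / "v.eqn"
        path.write_text("eq V' = F_in - F_out\n")
        model = read_equation_model(path)
        assert model.variables["V"].is_state
        eq = model.equation_defining("V")
        assert eq.is_derivative
        assert set(eq.rhs_dependencies) == {"F_in", "F_out"}

    def test_syntax_error_names_line(self, tmp_path):
        path = tmp_path / "bad.eqn"
        path.write_text("var A\neq A = (1 +\n")
        with pytest.raises(ModelFormatError, match="line 2"):
            read_equation_model(path)

    def test_duplicate_variable_rejected(self, tmp_path):
        path = tmp_path / "dup.eqn"
        path.write_text("var A\nvar A\n")
        with pytest.raises(ModelFormatError, match="duplicate"):
            read_equation_model(path)


class TestSidecar:
    def _base_model(self, tmp_path):
        path = tmp_path / "m.eqn"
        path.write_text("var F_LV_aorta\nvar R\neq F_LV_aorta = 1 / R\n")
        return read_equation_model(path)

    def test_annotates_named_variable(self, tmp_path):
        model = self._base_model(tmp_path)
        sc = tmp_path / "sc.json"
        sc.write_text('{"variables": {"F_LV_aorta": {"property": "opbx:FluidFlowRate"}}}')
        model, unknown = pm.apply_sidecar_annotations(model, sc)
        assert unknown == []
        assert model.variables["F_LV_aorta"].annotation.property_term == "opbx:FluidFlowRate"

    def test_empty_sidecar_is_identity(self, tmp_path):
        model = self._base_model(tmp_path)
        sc = tmp_path / "sc.json"
        sc.write_text("{}")
        before = {n: v.annotation for n, v in model.variables.items()}
        model, unknown = pm.apply_sidecar_annotations(model, sc)
        assert unknown == []
        assert {n: v.annotation for n, v in model.variables.items()} == before

    def test_unknown_variable_reported_others_untouched(self, tmp_path):
        model = self._base_model(tmp_path)
        sc = tmp_path / "sc.json"
        sc.write_text('{"variables": {"Qx": {"property": "opbx:FluidFlowRate"}}}')
        model, unknown = pm.apply_sidecar_annotations(model, sc)
        assert unknown == ["Qx"]
        assert model.variables["F_LV_aorta"].annotation is None

    def test_unknown_term_is_error(self, tmp_path):
        model = self._base_model(tmp_path)
        sc = tmp_path / "sc.json"
        sc.write_text('{"variables": {"R": {"property": "opbx:NotATerm"}}}')
        with pytest.raises(ModelFormatError, match="opbx:NotATerm"):
            pm.apply_sidecar_annotations(model, sc)


def _walk_vars(node):
    """Independent expression-tree walk (oracle for dependency edges)."""
    if isinstance(node, ex.Var):
        return {node.name}
    if isinstance(node, ex.Neg):
        return _walk_vars(node.arg)
    if isinstance(node, ex.BinOp):
        return _walk_vars(node.left) | _walk_vars(node.right)
    return set()


class TestDependencyGraph:
    def test_single_equation_edges(self, tmp_path):
        path = tmp_path / "m.eqn"
        path.write_text("eq F = (P1 - P2) / R\n")
        model = read_equation_model(path)
        dg = build_dependency_graph(model)
        assert set(dg.edges) == {("P1", "F"), ("P2", "F"), ("R", "F")}

    def test_equationless_variables_have_no_edges(self, tmp_path):
        path = tmp_path / "m.eqn"
        path.write_text("var A\nvar B\n")
        model = read_equation_model(path)
        dg = build_dependency_graph(model)
        assert set(dg.nodes) == {"A", "B"} and dg.edges == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_edges_match_expression_walk_oracle(self, seed):
        model, _ = fx.make_random_network(6, 6, p_modifier=0.4, seed=seed)
        dg = build_dependency_graph(model)
        expected = set()
        for eq in model.equations:
            for dep in _walk_vars(eq.rhs):
                expected.add((dep, eq.target))
        assert set(dg.edges) == expected

    def test_deterministic_across_calls(self):
        model, _ = fx.make_random_network(6, 6, seed=7)
        a = build_dependency_graph(model)
        b = build_dependency_graph(model)
        assert a.nodes == b.nodes and a.edges == b.edges


# 20 hand-picked expressions: linear, ratio, mass-action and Hill-type forms.
SIGN_LIBRARY = [
    ("3 * u + w", {"u": 1.0, "w": 2.0}),
    ("w - 2 * u", {"u": 1.0, "w": 2.0}),
    ("-u", {"u": 5.0}),
    ("u - u", {"u": 1.0}),
    ("(u - w) / r", {"u": 2.0, "w": 1.0, "r": 1.0}),
    ("(w - u) / r", {"u": 2.0, "w": 1.0, "r": 1.0}),
    ("k * u * w", {"k": 0.7, "u": 1.0, "w": 2.0}),
    ("k * u * u", {"k": 0.7, "u": 1.5}),
    ("k * w / u", {"k": 1.0, "u": 2.0, "w": 3.0}),
    ("k / (1 + u)", {"k": 1.0, "u": 0.5}),
    ("k * u / (1 + u)", {"k": 2.0, "u": 0.5}),
    ("k * u^2 / (1 + u^2)", {"k": 2.0, "u": 0.5}),
    ("k / (1 + u^2)", {"k": 2.0, "u": 0.5}),
    ("u^3", {"u": 2.0}),
    ("u^3", {"u": -2.0}),
    ("w * u^2", {"u": -1.0, "w": 1.0}),
    ("(u + w) * (u - w)", {"u": 3.0, "w": 1.0}),
    ("u / (u + w)", {"u": 1.0, "w": 4.0}),
    ("w / (u + w)", {"u": 1.0, "w": 4.0}),
    ("k * u * w / ((1 + u) * (1 + w))", {"k": 1.0, "u": 0.3, "w": 0.8}),
]


class TestPartialDependenceSign:
    @staticmethod
    def _model_for(expr_text, nominals):
        model = IngestedModel()
        eq = Equation(id="eq_y", target="y", is_derivative=False,
                      rhs=ex.parse_infix(expr_text))
        model.equations.append(eq)
        model.variables["y"] = ModelVariable(name="y", equation_id="eq_y")
        for name in eq.rhs_dependencies:
            model.variables[name] = ModelVariable(name=name)
        model.nominal_values.update(nominals)
        return model

    def test_pressure_difference_flow(self):
        model = self._model_for("(P1 - P2) / R", {"P1": 2.0, "P2": 1.0, "R": 1.0})
        assert partial_dependence_sign(model, "P1", "y") == 1
        assert partial_dependence_sign(model, "P2", "y") == -1

    def test_cancelling_expression_is_zero(self):
        model = self._model_for("u - u", {"u": 1.0})
        assert partial_dependence_sign(model, "u", "y") == 0

    def test_mass_action_positive(self):
        model = self._model_for("k * S1 * S2", {"k": 2.0, "S1": 1.0, "S2": 3.0})
        assert partial_dependence_sign(model, "S1", "y") == 1

    @pytest.mark.parametrize("expr_text, nominals", SIGN_LIBRARY)
    def test_agrees_with_analytic_derivative(self, expr_text, nominals):
        """Finite-difference sign equals the symbolic derivative's sign."""
        model = self._model_for(expr_text, nominals)
        symbolic = sympy.sympify(expr_text.replace("^", "**"))
        for name in sorted(ex.variables(model.equations[0].rhs)):
            deriv = symbolic.diff(sympy.Symbol(name))
            value = float(deriv.subs({sympy.Symbol(k): v for k, v in nominals.items()}))
            expected = 0 if abs(value) < 1e-12 else (1 if value > 0 else -1)
            assert partial_dependence_sign(model, name, "y") == expected, name

    def test_division_by_zero_at_nominal_point_is_indeterminate(self):
        model = self._model_for("w / u", {"u": 0.0, "w": 1.0})
        assert partial_dependence_sign(model, "w", "y") == "indeterminate"
        assert any("evaluation failed" in w for w in model.warnings)
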