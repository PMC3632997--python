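"""Participant location, role assignment, and the two generation paths."""

import pytest

import physiomap as pm
from physiomap import fixtures as fx
from physiomap.ingest import build_dependency_graph, read_equation_model
from physiomap.inference import (
    classify_variable_role,
    infer_from_dependencies,
    infer_from_reactions,
    locate_participants,
)
from physiomap.pmap import physiomap_to_xml
from helpers import flow_signatures, maps_isomorphic


def eqn_model(tmp_path, text):
    path = tmp_path / "m.eqn"
    path.write_text(text)
    return read_equation_model(path)


class TestClassifyVariableRole:
    def test_cv_roles(self, cv4, registry):
        model, _ = cv4
        roles = classify_variable_role(model, registry)
        assert roles["F_LV_aorta"].role == "flow"
        assert roles["F_LV_aorta"].domain_id == "domx:fluid"
        assert roles["P_LV"].role == "force"
        assert roles["V_aorta"].role == "amount"
        assert roles["R_LV"].role == "unannotated"

    def test_concentration_species_is_chemical_amount(self, glycolysis, registry):
        model, _ = glycolysis
        roles = classify_variable_role(model, registry)
        assert roles["glucose"].role == "amount"
        assert roles["glucose"].domain_id == "domx:chemical"


class TestLocateParticipants:
    def test_pressure_driven_flow_upstream_signs(self, tmp_path, registry):
        model = eqn_model(
            tmp_path,
            "var F {property: opbx:FluidFlowRate}\n"
            "var P1 {property: opbx:FluidPressure, entity: fmax:LeftVentricle}\n"
            "var P2 {property: opbx:FluidPressure, entity: fmax:Aorta}\n"
            "eq F = (P1 - P2) / R\n"
            "init P1 = 2.0\ninit P2 = 1.0\ninit R = 1.0\n",
        )
        roles = classify_variable_role(model, registry)
        ev = locate_participants(model, build_dependency_graph(model), roles, "F")
        up = {(e.neighbor, e.dependence_sign) for e in ev if e.direction == "upstream"}
        assert up == {("P1", 1), ("P2", -1)}
        assert [e for e in ev if e.direction == "downstream"] == []

    def test_downstream_volume(self, tmp_path, registry):
        model = eqn_model(
            tmp_path,
            "var F {property: opbx:FluidFlowRate}\n"
            "var V2 {property: opbx:FluidVolume, entity: fmax:Aorta}\n"
            "eq V2' = F\n"
            "eq F = 1 + Z\n",
        )
        roles = classify_variable_role(model, registry)
        ev = locate_participants(model, build_dependency_graph(model), roles, "F")
        down = [(e.neighbor, e.dependence_sign) for e in ev if e.direction == "downstream"]
        assert down == [("V2", 1)]

    def test_multi_hop_chain_counts_hops(self, tmp_path, registry):
        """F feeds x feeds the amount C: evidence composes the signs over 2 hops."""
        model = eqn_model(
            tmp_path,
            "var F {property: opbx:ChemicalFlowRate}\n"
            "var C {property: opbx:ChemicalAmount, entity: chebix:Glucose}\n"
            "var x\n"
            "eq F = 2 - Z\n"
            "eq x = F\n"
            "eq C' = x\n",
        )
        roles = classify_variable_role(model, registry)
        ev = locate_participants(model, build_dependency_graph(model), roles, "F")
        down = [(e.neighbor, e.dependence_sign, e.hop_count)
                for e in ev if e.direction == "downstream"]
        assert down == [("C", 1, 2)]

    def test_non_flow_variable_rejected(self, cv4, registry):
        model, _ = cv4
        roles = classify_variable_role(model, registry)
        with pytest.raises(ValueError):
            locate_participants(model, build_dependency_graph(model), roles, "P_LV")


class TestInferFlowProcess:
    def test_cv_flow_source_and_sink(self, cv4, registry):
        model, spec = cv4
        pmap = infer_from_dependencies(model, registry)
        proc = pmap.processes["flow_F_LV_aorta"]
        assert proc.kind == "flow" and proc.domain_id == "domx:fluid"
        by_role = {p.role: pmap.entities[p.entity_id] for p in proc.participants}
        assert by_role["source"].annotation.bearer[1].term_id == "fmax:LeftVentricle"
        assert by_role["sink"].annotation.bearer[1].term_id == "fmax:Aorta"

    def test_no_evidence_yields_unresolved_boundary_flow(self, tmp_path, registry):
        model = eqn_model(
            tmp_path,
            "var F {property: opbx:FluidFlowRate}\neq F = 1 + k\n",
        )
        pmap = infer_from_dependencies(model, registry)
        proc = pmap.processes["flow_F"]
        assert proc.unresolved
        roles_present = {p.role for p in proc.participants}
        assert roles_present == {"source", "sink"}
        assert all(
            pmap.entities[p.entity_id].display_label == "environment"
            for p in proc.participants
        )

    def test_symmetric_conflict_demotes_to_mediator(self, tmp_path, registry):
        """A and B carry the same entity annotation, so the same entity gets
        opposite roles and must fall back to mediator with a warning."""
        model = eqn_model(
            tmp_path,
            "var F {property: opbx:FluidFlowRate}\n"
            "var A {property: opbx:FluidPressure, entity: fmax:Aorta}\n"
            "var B {property: opbx:FluidPressure, entity: fmax:Aorta}\n"
            "eq F = (A - B) / R\n"
            "init A = 2.0\ninit B = 1.0\n",
        )
        pmap = infer_from_dependencies(model, registry)
        proc = pmap.processes["flow_F"]
        mediators = [p for p in proc.participants if p.role == "mediator"]
        assert len(mediators) == 1
        assert any("mediator" in w for w in pmap.warnings)


class TestInferFromReactions:
    def test_glycolysis_counts(self, glycolysis):
        model, spec = glycolysis
        pmap = infer_from_reactions(model)
        flows = [p for p in pmap.processes.values() if p.kind == "flow"]
        mods = [p for p in pmap.processes.values() if p.kind == "modulation"]
        assert len(flows) == spec.expected["flow_processes"]
        assert len(mods) == spec.expected["modulation_processes"]
        assert pm.validate(pmap) == []

    def test_stoichiometry_carried_to_participants(self, glycolysis):
        model, _ = glycolysis
        model.reactions[0].reactants = [("glucose", 2.0)]
        pmap = infer_from_reactions(model)
        proc = pmap.processes["flow_r_hk"]
        source = next(p for p in proc.participants if p.role == "source")
        sink = next(p for p in proc.participants if p.role == "sink")
        assert source.stoichiometry == 2.0 and sink.stoichiometry == 1.0

    def test_products_only_reaction_gets_environment_source(self, glycolysis):
        model, _ = glycolysis
        model.reactions[0].reactants = []
        pmap = infer_from_reactions(model)
        proc = pmap.processes["flow_r_hk"]
        src = next(p for p in proc.participants if p.role == "source")
        assert pmap.entities[src.entity_id].display_label == "environment"


class TestInferFromDependencies:
    def test_cv_circuit_matches_construction(self, cv4):
        model, spec = cv4
        pmap = infer_from_dependencies(model)
        flows = {p.rate_variable: p for p in pmap.processes.values() if p.kind == "flow"}
        assert len(flows) == spec.expected["flows"]
        for fname, roles in spec.expected["flow_roles"].items():
            proc = flows[fname]
            by_role = {p.role: pmap.entities[p.entity_id] for p in proc.participants}
            for role in ("source", "sink"):
                bearer = by_role[role].annotation.bearer
                assert (bearer[0].term_id, bearer[1].term_id) == roles[role], (fname, role)

    def test_annotations_without_equations_gives_empty_map(self, tmp_path, registry):
        model = eqn_model(
            tmp_path,
            "var C {property: opbx:ChemicalAmount, entity: chebix:Glucose}\n",
        )
        pmap = infer_from_dependencies(model, registry)
        assert pmap.processes == {}
        assert pmap.warnings

    def test_glycolysis_both_paths_isomorphic(self, glycolysis):
        model, _ = glycolysis
        assert maps_isomorphic(infer_from_reactions(model), infer_from_dependencies(model))

    def test_dependency_modulations_carry_sign_derived_polarity(self, glycolysis):
        model, _ = glycolysis
        pmap = infer_from_dependencies(model)
        mods = {p.regulator_entity_id: p.polarity
                for p in pmap.processes.values() if p.kind == "modulation"}
        by_term = {
            pmap.entities[eid].annotation.bearer[0].term_id: pol
            for eid, pol in mods.items()
        }
        assert by_term == {"chebix:AMP": 1, "chebix:ATP": -1}

    def test_deterministic_output_bytes(self, cv4):
        model, _ = cv4
        a = physiomap_to_xml(infer_from_dependencies(model))
        b = physiomap_to_xml(infer_from_dependencies(model))
        assert a == b

    def test_provenance_names_method_and_flow_variable(self, cv4):
        model, _ = cv4
        pmap = infer_from_dependencies(model)
        for proc in pmap.processes.values():
            assert proc.provenance.method == "dependency-inference"
            assert proc.provenance.flow_variable
            assert proc.provenance.source_uri == model.source_uri
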