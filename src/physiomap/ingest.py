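"""Read simulation models into a uniform in-memory form.

Two source formats are supported:

* SBML Level 2/3 reaction networks (species, compartments, parameters,
  reactions with kinetic laws, rate/assignment rules, MIRIAM-style ontology
  annotations, SBO modifier terms).  A minimal writing dialect is provided
  for the bundled model generators.
* A line-oriented declarative equation-model format carrying inline
  composite annotations — the ingestion path for lumped-parameter models
  that are equations-only (no tagged reactions).

Both produce an :class:`IngestedModel`; downstream inference works only on
that form.  The module also derives the variable dependency digraph from
the model equations and estimates the sign of each dependence by central
finite differences at the model's nominal operating point.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from lxml import etree

from . import expr as ex
from .ontology import (
    BearerLink,
    Category,
    CompositeAnnotation,
    TermRegistry,
    load_registry,
)

__all__ = [
    "ModelVariable",
    "Equation",
    "ReactionRecord",
    "IngestedModel",
    "DependencyGraph",
    "ModelFormatError",
    "read_sbml",
    "write_sbml",
    "synthesize_mass_balance_odes",
    "read_equation_model",
    "write_equation_model",
    "apply_sidecar_annotations",
    "build_dependency_graph",
    "partial_dependence_sign",
]

INDETERMINATE = "indeterminate"

SBML_L3_NS = "http://www.sbml.org/sbml/level3/version2/core"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
TERM_URN_PREFIX = "urn:physiomap:term:"

# SBO modifier families mapped to modulation polarity; everything else is
# polarity 0 (unknown).
_SBO_INHIBITOR = {20, 206, 207, 536, 537, 597}
_SBO_STIMULATOR = {13, 21, 459, 460, 461, 462}


class ModelFormatError(ValueError):
    """Unparseable or structurally invalid model file."""


@dataclass
class ModelVariable:
    name: str
    annotation: CompositeAnnotation | None = None
    is_state: bool = False
    equation_id: str | None = None
    boundary: bool = False  # clamped boundary-condition species


@dataclass
class Equation:
    id: str
    target: str
    is_derivative: bool
    rhs: ex.Expr
    rhs_dependencies: tuple[str, ...] = ()
    synthesized: bool = False  # mass-balance ODE implied by reactions

    def __post_init__(self) -> None:
        if not self.rhs_dependencies:
            self.rhs_dependencies = tuple(sorted(ex.variables(self.rhs)))


@dataclass
class ReactionRecord:
    id: str
    reactants: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    modifiers: list[tuple[str, int]] = field(default_factory=list)
    rate_variable: str | None = None
    reversible: bool = False


@dataclass
class IngestedModel:
    variables: dict[str, ModelVariable] = field(default_factory=dict)
    equations: list[Equation] = field(default_factory=list)
    reactions: list[ReactionRecord] = field(default_factory=list)
    source_format: str = "eqn"
    source_uri: str = ""
    nominal_values: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def equation_defining(self, name: str) -> Equation | None:
        """The equation that determines `name` (its derivative when a state)."""
        var = self.variables.get(name)
        if var is None or var.equation_id is None:
            return None
        return self._equation_index().get(var.equation_id)

    def _equation_index(self) -> dict[str, Equation]:
        return {eq.id: eq for eq in self.equations}

    def check_integrity(self) -> None:
        index = self._equation_index()
        for var in self.variables.values():
            if var.equation_id is not None and var.equation_id not in index:
                raise ModelFormatError(
                    f"variable {var.name} references missing equation {var.equation_id}"
                )
            if var.is_state:
                eq = index.get(var.equation_id or "")
                if eq is None or not eq.is_derivative:
                    raise ModelFormatError(
                        f"state variable {var.name} has no derivative equation"
                    )
        for eq in self.equations:
            if eq.target not in self.variables:
                raise ModelFormatError(f"equation {eq.id} targets unknown {eq.target}")
            for dep in eq.rhs_dependencies:
                if dep not in self.variables:
                    raise ModelFormatError(
                        f"equation {eq.id} references undeclared variable {dep}"
                    )
        for rxn in self.reactions:
            if not rxn.reactants and not rxn.products:
                raise ModelFormatError(f"reaction {rxn.id} has neither side")
            for name, stoich in rxn.reactants + rxn.products:
                if name not in self.variables:
                    raise ModelFormatError(f"reaction {rxn.id} names unknown {name}")
                if stoich <= 0:
                    raise ModelFormatError(f"reaction {rxn.id}: stoichiometry <= 0")
            for name, _pol in rxn.modifiers:
                if name not in self.variables:
                    raise ModelFormatError(f"reaction {rxn.id} names unknown {name}")


@dataclass
class DependencyGraph:
    """Directed graph with an edge u→v iff u appears in the equation defining v."""

    graph: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)


# ---------------------------------------------------------------------------
# SBML reading


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _find_all(parent, name: str):
    return [el for el in parent.iter() if _local(el.tag) == name]


def _children(parent, name: str):
    return [el for el in parent if _local(el.tag) == name]


def _miriam_terms(element, registry: TermRegistry) -> tuple[list[str], list[str]]:
    """Mapped registry term ids and unmapped URIs from an element's annotation."""
    mapped: list[str] = []
    unmapped: list[str] = []
    for ann in _children(element, "annotation"):
        for qualifier in ann.iter():
            if _local(qualifier.tag) not in ("is", "isVersionOf"):
                continue
            for li in qualifier.iter():
                if _local(li.tag) != "li":
                    continue
                uri = li.get(f"{{{RDF_NS}}}resource")
                if not uri:
                    continue
                term = registry.term_for_iri(uri)
                if term is None and uri.startswith(TERM_URN_PREFIX):
                    # local CURIEs are accepted as opaque entity identifiers
                    # even off-registry (full FMA/ChEBI import is out of scope)
                    term = uri[len(TERM_URN_PREFIX):]
                if term is not None:
                    mapped.append(term)
                else:
                    unmapped.append(uri)
    return mapped, unmapped


def _sbo_polarity(sbo: str | None) -> int:
    if not sbo:
        return 0
    m = re.fullmatch(r"SBO:(\d{7})", sbo.strip())
    if not m:
        return 0
    code = int(m.group(1))
    if code in _SBO_INHIBITOR:
        return -1
    if code in _SBO_STIMULATOR:
        return +1
    return 0


def read_sbml(path: str | Path, registry: TermRegistry | None = None) -> IngestedModel:
    """Read an SBML Level 2/3 file into an :class:`IngestedModel`.

    Species, compartments and parameters become model variables; each
    reaction yields a :class:`ReactionRecord` plus a rate variable (named
    after the reaction) whose equation is the kinetic-law math, annotated as
    a chemical molar flow rate.  Mass-balance ODEs for non-boundary species
    are synthesized from the stoichiometry so the dependency graph reflects
    the full equation system the SBML encodes.  MIRIAM biology-qualifier
    URIs that map into the registry become composite annotations; unknown
    URIs are warned about and left unannotated.
    """
    registry = registry or load_registry()
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ModelFormatError(f"cannot parse SBML file {path}: {exc}") from None
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise ModelFormatError(f"{path}: root element is not <sbml>")
    models = _children(root, "model")
    if not models:
        raise ModelFormatError(f"{path}: no <model> element")
    mel = models[0]

    model = IngestedModel(source_format="sbml", source_uri=str(path))

    # compartments: variable + entity-term map for species bearers
    compartment_term: dict[str, str | None] = {}
    for comp in _find_all(mel, "compartment"):
        cid = comp.get("id")
        if not cid:
            continue
        mapped, unmapped = _miriam_terms(comp, registry)
        compartment_term[cid] = mapped[0] if mapped else None
        if unmapped:
            model.warnings.append(
                f"compartment {cid}: unknown ontology URI(s) {unmapped}"
            )
        model.variables[cid] = ModelVariable(name=cid)
        size = comp.get("size") or comp.get("volume")
        if size is not None:
            model.nominal_values[cid] = float(size)

    # species
    species_ids: list[str] = []
    species_compartment: dict[str, str] = {}
    for sp in _find_all(mel, "species"):
        sid = sp.get("id")
        if not sid:
            continue
        species_ids.append(sid)
        boundary = sp.get("boundaryCondition") == "true" or sp.get("constant") == "true"
        mapped, unmapped = _miriam_terms(sp, registry)
        annotation = None
        if mapped:
            prop = (
                "opbx:ChemicalConcentration"
                if sp.get("initialConcentration") is not None
                else "opbx:ChemicalAmount"
            )
            bearer = [BearerLink(mapped[0], "none")]
            comp_id = sp.get("compartment")
            if comp_id:
                species_compartment[sid] = comp_id
                cterm = compartment_term.get(comp_id)
                if cterm:
                    bearer.append(BearerLink(cterm, "contained-in"))
            annotation = CompositeAnnotation(prop, tuple(bearer))
        else:
            if unmapped:
                model.warnings.append(
                    f"species {sid}: unknown ontology URI(s) {unmapped}"
                )
            comp_id = sp.get("compartment")
            if comp_id:
                species_compartment[sid] = comp_id
        model.variables[sid] = ModelVariable(
            name=sid, annotation=annotation, boundary=boundary
        )
        init = sp.get("initialAmount") or sp.get("initialConcentration")
        if init is not None:
            model.nominal_values[sid] = float(init)

    # global parameters
    for par in _find_all(mel, "parameter"):
        if _local(par.getparent().tag) != "listOfParameters":
            continue
        if _local(par.getparent().getparent().tag) != "model":
            continue  # local kinetic-law parameters handled per reaction
        pid = par.get("id")
        if not pid:
            continue
        model.variables[pid] = ModelVariable(name=pid)
        value = par.get("value")
        if value is not None:
            model.nominal_values[pid] = float(value)

    # reactions
    reaction_lists = _children(mel, "listOfReactions")
    reaction_els = _children(reaction_lists[0], "reaction") if reaction_lists else []
    for rxn in reaction_els:
        rid = rxn.get("id")
        if not rid:
            raise ModelFormatError(f"{path}: reaction without id")
        record = ReactionRecord(
            id=rid, reversible=(rxn.get("reversible", "true") == "true")
        )
        for side, bucket in (("listOfReactants", record.reactants),
                             ("listOfProducts", record.products)):
            for lst in _children(rxn, side):
                for ref in _children(lst, "speciesReference"):
                    name = ref.get("species")
                    stoich = float(ref.get("stoichiometry", "1"))
                    bucket.append((name, stoich))
        for lst in _children(rxn, "listOfModifiers"):
            for ref in _children(lst, "modifierSpeciesReference"):
                record.modifiers.append(
                    (ref.get("species"), _sbo_polarity(ref.get("sboTerm")))
                )
        # kinetic law -> rate variable equation
        rate_expr: ex.Expr | None = None
        for kl in _children(rxn, "kineticLaw"):
            rename_map: dict[str, str] = {}
            for lst in _children(kl, "listOfLocalParameters") + _children(
                kl, "listOfParameters"
            ):
                for par in lst:
                    pid = par.get("id")
                    if not pid:
                        continue
                    hoisted = f"{rid}_{pid}" if pid in model.variables else pid
                    rename_map[pid] = hoisted
                    model.variables[hoisted] = ModelVariable(name=hoisted)
                    if par.get("value") is not None:
                        model.nominal_values[hoisted] = float(par.get("value"))
            maths = _children(kl, "math")
            if maths:
                try:
                    rate_expr = ex.parse_mathml(maths[0])
                except ex.ExprError as exc:
                    model.warnings.append(
                        f"reaction {rid}: unsupported kinetic-law math ({exc})"
                    )
                if rate_expr is not None and rename_map:
                    rate_expr = ex.rename(rate_expr, rename_map)
        if rate_expr is not None:
            eq = Equation(id=f"eq_{rid}", target=rid, is_derivative=False, rhs=rate_expr)
            model.equations.append(eq)
            model.variables[rid] = ModelVariable(
                name=rid,
                annotation=CompositeAnnotation(
                    "opbx:ChemicalFlowRate", (), free_label=rid
                ),
                equation_id=eq.id,
            )
            record.rate_variable = rid
        model.reactions.append(record)

    synthesize_mass_balance_odes(model)

    # rules
    for rule in _find_all(mel, "rateRule") + _find_all(mel, "assignmentRule"):
        target = rule.get("variable")
        maths = _children(rule, "math")
        if target is None or not maths:
            continue
        is_deriv = _local(rule.tag) == "rateRule"
        rhs = ex.parse_mathml(maths[0])
        eq = Equation(
            id=f"{'ode' if is_deriv else 'eq'}_{target}",
            target=target,
            is_derivative=is_deriv,
            rhs=rhs,
        )
        model.equations.append(eq)
        if target not in model.variables:
            model.variables[target] = ModelVariable(name=target)
        model.variables[target].equation_id = eq.id
        model.variables[target].is_state = is_deriv

    for unsupported in ("piecewise", "listOfEvents", "algebraicRule"):
        if _find_all(mel, unsupported):
            model.warnings.append(f"unsupported SBML construct ignored: {unsupported}")

    model.check_integrity()
    return model


def synthesize_mass_balance_odes(model: IngestedModel) -> None:
    """Add the stoichiometric ODE for each non-boundary species with a rate.

    For every species touched by reactions with known rate variables, the
    implied mass balance ``species' = Σ ±stoich·rate`` becomes a synthesized
    derivative equation; boundary (clamped) species and species that already
    have an equation are left alone.
    """
    net: dict[str, list[tuple[float, str]]] = {}
    for record in model.reactions:
        if not record.rate_variable:
            continue
        for name, stoich in record.reactants:
            net.setdefault(name, []).append((-stoich, record.rate_variable))
        for name, stoich in record.products:
            net.setdefault(name, []).append((+stoich, record.rate_variable))
    for sid in sorted(net):
        var = model.variables[sid]
        if var.boundary or var.equation_id is not None:
            continue
        rhs: ex.Expr | None = None
        for coeff, rate in sorted(net[sid], key=lambda t: (t[1], t[0])):
            term: ex.Expr = ex.Var(rate)
            if abs(coeff) != 1.0:
                term = ex.BinOp("*", ex.Num(abs(coeff)), term)
            if rhs is None:
                rhs = ex.Neg(term) if coeff < 0 else term
            else:
                rhs = ex.BinOp("-" if coeff < 0 else "+", rhs, term)
        eq = Equation(
            id=f"ode_{sid}", target=sid, is_derivative=True, rhs=rhs, synthesized=True
        )
        model.equations.append(eq)
        var.is_state = True
        var.equation_id = eq.id


def write_sbml(model: IngestedModel, registry: TermRegistry | None = None) -> str:
    """Serialize a reaction-network model to the minimal SBML L3 dialect.

    Covers what :func:`read_sbml` reads back: species with MIRIAM entity
    annotations, compartments, global parameters, reactions with kinetic
    laws and SBO-tagged modifiers.  Synthesized mass-balance equations are
    omitted (they are implied by the stoichiometry).
    """
    registry = registry or load_registry()
    nsmap = {None: SBML_L3_NS}
    root = etree.Element(f"{{{SBML_L3_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    mel = etree.SubElement(root, f"{{{SBML_L3_NS}}}model")
    mel.set("id", "model")

    species_names = sorted(
        {n for r in model.reactions for n, _ in r.reactants + r.products}
        | {n for r in model.reactions for n, _ in r.modifiers}
    )
    rate_names = {r.rate_variable for r in model.reactions if r.rate_variable}

    def entity_uri(term_id: str) -> str:
        iri = registry.get(term_id).external_iri if term_id in registry else None
        return iri or f"{TERM_URN_PREFIX}{term_id}"

    def attach_miriam(el, term_id: str) -> None:
        meta = f"meta_{el.get('id')}"
        el.set("metaid", meta)
        ann = etree.SubElement(el, f"{{{SBML_L3_NS}}}annotation")
        rdf = etree.SubElement(
            ann, f"{{{RDF_NS}}}RDF", nsmap={"rdf": RDF_NS, "bqbiol": BQBIOL_NS}
        )
        desc = etree.SubElement(rdf, f"{{{RDF_NS}}}Description")
        desc.set(f"{{{RDF_NS}}}about", f"#{meta}")
        qual = etree.SubElement(desc, f"{{{BQBIOL_NS}}}is")
        bag = etree.SubElement(qual, f"{{{RDF_NS}}}Bag")
        li = etree.SubElement(bag, f"{{{RDF_NS}}}li")
        li.set(f"{{{RDF_NS}}}resource", entity_uri(term_id))

    # compartments derived from species bearer chains
    comp_ids: dict[str, str] = {}  # term -> compartment id
    for name in species_names:
        ann = model.variables[name].annotation
        if ann and len(ann.bearer) > 1 and ann.bearer[1].relation == "contained-in":
            term = ann.bearer[1].term_id
            comp_ids.setdefault(term, term.split(":", 1)[-1].lower())
    if not comp_ids:
        comp_ids["__default__"] = "compartment"
    loc = etree.SubElement(mel, f"{{{SBML_L3_NS}}}listOfCompartments")
    for term, cid in sorted(comp_ids.items(), key=lambda kv: kv[1]):
        comp = etree.SubElement(loc, f"{{{SBML_L3_NS}}}compartment")
        comp.set("id", cid)
        comp.set("size", "1")
        comp.set("constant", "true")
        if term != "__default__":
            attach_miriam(comp, term)
    default_comp = sorted(comp_ids.values())[0]

    los = etree.SubElement(mel, f"{{{SBML_L3_NS}}}listOfSpecies")
    for name in species_names:
        var = model.variables[name]
        sp = etree.SubElement(los, f"{{{SBML_L3_NS}}}species")
        sp.set("id", name)
        comp = default_comp
        if var.annotation and len(var.annotation.bearer) > 1:
            comp = comp_ids.get(var.annotation.bearer[1].term_id, default_comp)
        sp.set("compartment", comp)
        sp.set("initialAmount", repr(model.nominal_values.get(name, 1.0)))
        sp.set("boundaryCondition", "true" if var.boundary else "false")
        sp.set("hasOnlySubstanceUnits", "true")
        sp.set("constant", "false")
        if var.annotation and var.annotation.bearer:
            attach_miriam(sp, var.annotation.bearer[0].term_id)

    params = sorted(
        n
        for n, v in model.variables.items()
        if n not in species_names
        and n not in rate_names
        and v.equation_id is None
        and n not in comp_ids.values()
    )
    if params:
        lop = etree.SubElement(mel, f"{{{SBML_L3_NS}}}listOfParameters")
        for name in params:
            par = etree.SubElement(lop, f"{{{SBML_L3_NS}}}parameter")
            par.set("id", name)
            par.set("value", repr(model.nominal_values.get(name, 1.0)))
            par.set("constant", "true")

    eq_index = {eq.target: eq for eq in model.equations if not eq.synthesized}
    if model.reactions:
        lor = etree.SubElement(mel, f"{{{SBML_L3_NS}}}listOfReactions")
        for record in model.reactions:
            rxn = etree.SubElement(lor, f"{{{SBML_L3_NS}}}reaction")
            rxn.set("id", record.id)
            rxn.set("reversible", "true" if record.reversible else "false")
            if record.reactants:
                lst = etree.SubElement(rxn, f"{{{SBML_L3_NS}}}listOfReactants")
                for name, stoich in record.reactants:
                    ref = etree.SubElement(lst, f"{{{SBML_L3_NS}}}speciesReference")
                    ref.set("species", name)
                    ref.set("stoichiometry", repr(stoich))
                    ref.set("constant", "true")
            if record.products:
                lst = etree.SubElement(rxn, f"{{{SBML_L3_NS}}}listOfProducts")
                for name, stoich in record.products:
                    ref = etree.SubElement(lst, f"{{{SBML_L3_NS}}}speciesReference")
                    ref.set("species", name)
                    ref.set("stoichiometry", repr(stoich))
                    ref.set("constant", "true")
            if record.modifiers:
                lst = etree.SubElement(rxn, f"{{{SBML_L3_NS}}}listOfModifiers")
                for name, polarity in record.modifiers:
                    ref = etree.SubElement(
                        lst, f"{{{SBML_L3_NS}}}modifierSpeciesReference"
                    )
                    ref.set("species", name)
                    if polarity == -1:
                        ref.set("sboTerm", "SBO:0000020")
                    elif polarity == +1:
                        ref.set("sboTerm", "SBO:0000459")
            if record.rate_variable and record.rate_variable in eq_index:
                kl = etree.SubElement(rxn, f"{{{SBML_L3_NS}}}kineticLaw")
                kl.append(ex.to_mathml(eq_index[record.rate_variable].rhs))

    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# equation-model format

_VAR_RE = re.compile(r"var\s+([A-Za-z_]\w*)\s*(?:\{(.*)\})?\s*$")
_EQ_RE = re.compile(r"eq\s+([A-Za-z_]\w*)(')?\s*=\s*(.+)$")
_INIT_RE = re.compile(r"init\s+([A-Za-z_]\w*)\s*=\s*([-+0-9.eE]+)\s*$")


def _parse_annotation_body(
    body: str, registry: TermRegistry, lineno: int, var_name: str
) -> CompositeAnnotation | None:
    prop: str | None = None
    bearer: list[BearerLink] = []
    for part in body.split(","):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise ModelFormatError(f"line {lineno}: bad annotation field {part!r}")
        key, value = part.split(":", 1)
        key = key.strip()
        value = value.strip()
        if key == "property":
            prop = value
        elif key == "entity":
            tokens = value.split()
            if not tokens:
                raise ModelFormatError(f"line {lineno}: empty entity chain")
            bearer.append(BearerLink(tokens[0], "none"))
            rest = tokens[1:]
            if len(rest) % 2:
                raise ModelFormatError(
                    f"line {lineno}: entity chain must alternate relation/term"
                )
            for rel, term in zip(rest[::2], rest[1::2]):
                bearer.append(BearerLink(term, rel))
        elif key == "domain":
            pass  # informative; the domain comes from the property term
        else:
            raise ModelFormatError(f"line {lineno}: unknown annotation key {key!r}")
    if prop is None:
        return None
    if prop not in registry:
        raise ModelFormatError(f"line {lineno}: unknown property term {prop!r}")
    if registry.get(prop).category is not Category.PROPERTY:
        raise ModelFormatError(f"line {lineno}: {prop} is not a property term")
    if bearer:
        return CompositeAnnotation(prop, tuple(bearer))
    return CompositeAnnotation(prop, (), free_label=var_name)


def read_equation_model(
    path: str | Path, registry: TermRegistry | None = None
) -> IngestedModel:
    """Read the declarative annotated equation-model format.

    One statement per line::

        var NAME {property: CURIE, entity: CURIE [rel CURIE ...], domain: ID}
        eq NAME = expression        # algebraic assignment
        eq NAME' = expression       # time derivative (NAME becomes a state)
        init NAME = number
        # comment

    Symbols referenced but never declared become unannotated parameters
    (with a warning), so resistances and capacitances need no ceremony.
    """
    registry = registry or load_registry()
    path = Path(path)
    model = IngestedModel(source_format="eqn", source_uri=str(path))
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("var"):
            m = _VAR_RE.match(line)
            if not m:
                raise ModelFormatError(f"line {lineno}: bad var statement")
            name, body = m.group(1), m.group(2)
            if name in model.variables:
                raise ModelFormatError(f"line {lineno}: duplicate variable {name}")
            annotation = (
                _parse_annotation_body(body, registry, lineno, name) if body else None
            )
            model.variables[name] = ModelVariable(name=name, annotation=annotation)
        elif line.startswith("eq"):
            m = _EQ_RE.match(line)
            if not m:
                raise ModelFormatError(f"line {lineno}: bad eq statement")
            target, prime, rhs_text = m.group(1), m.group(2), m.group(3)
            try:
                rhs = ex.parse_infix(rhs_text)
            except ex.ExprError as exc:
                raise ModelFormatError(f"line {lineno}: {exc}") from None
            is_deriv = prime == "'"
            eq = Equation(
                id=f"{'ode' if is_deriv else 'eq'}_{target}",
                target=target,
                is_derivative=is_deriv,
                rhs=rhs,
            )
            if any(e.id == eq.id for e in model.equations):
                raise ModelFormatError(
                    f"line {lineno}: {target} already has an equation"
                )
            model.equations.append(eq)
            for symbol in (target, *eq.rhs_dependencies):
                if symbol not in model.variables:
                    model.variables[symbol] = ModelVariable(name=symbol)
                    model.warnings.append(
                        f"line {lineno}: undeclared symbol {symbol} "
                        "auto-declared as unannotated parameter"
                    )
            model.variables[target].equation_id = eq.id
            model.variables[target].is_state = is_deriv
        elif line.startswith("init"):
            m = _INIT_RE.match(line)
            if not m:
                raise ModelFormatError(f"line {lineno}: bad init statement")
            name, value = m.group(1), float(m.group(2))
            if name not in model.variables:
                model.variables[name] = ModelVariable(name=name)
            model.nominal_values[name] = value
        else:
            raise ModelFormatError(f"line {lineno}: unknown statement {line!r}")
    model.check_integrity()
    return model


def write_equation_model(model: IngestedModel) -> str:
    """Serialize a model to the equation-model text format."""
    lines: list[str] = ["# annotated equation model"]
    for name in sorted(model.variables):
        var = model.variables[name]
        ann = var.annotation
        if ann is None:
            lines.append(f"var {name}")
            continue
        parts = [f"property: {ann.property_term}"]
        if ann.bearer:
            chain = ann.bearer[0].term_id
            for link in ann.bearer[1:]:
                chain += f" {link.relation} {link.term_id}"
            parts.append(f"entity: {chain}")
        lines.append(f"var {name} {{{', '.join(parts)}}}")
    for eq in model.equations:
        if eq.synthesized:
            continue
        prime = "'" if eq.is_derivative else ""
        lines.append(f"eq {eq.target}{prime} = {ex.to_infix(eq.rhs)}")
    for name in sorted(model.nominal_values):
        lines.append(f"init {name} = {model.nominal_values[name]!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sidecar annotations


def apply_sidecar_annotations(
    model: IngestedModel,
    sidecar_path: str | Path,
    registry: TermRegistry | None = None,
) -> tuple[IngestedModel, list[str]]:
    """Overlay composite annotations from a sidecar JSON file.

    Returns the model and the list of sidecar variable names absent from the
    model (reported, not fatal).  Property terms must resolve in the
    registry; bearer entity CURIEs are accepted as opaque identifiers.
    """
    registry = registry or load_registry()
    data = json.loads(Path(sidecar_path).read_text(encoding="utf-8"))
    entries = data.get("variables", {})
    unknown: list[str] = []
    for name, spec in entries.items():
        prop = spec.get("property")
        if prop is None or prop not in registry:
            raise ModelFormatError(f"sidecar: unknown registry term {prop!r}")
        if registry.get(prop).category is not Category.PROPERTY:
            raise ModelFormatError(f"sidecar: {prop} is not a property term")
        if name not in model.variables:
            unknown.append(name)
            continue
        bearer = tuple(
            BearerLink(term, rel) for term, rel in spec.get("bearer", [])
        )
        free_label = spec.get("free_label")
        if not bearer and free_label is None:
            free_label = name
        model.variables[name].annotation = CompositeAnnotation(
            prop, bearer, free_label=free_label
        )
    return model, unknown


# ---------------------------------------------------------------------------
# dependency graph and signs


def build_dependency_graph(model: IngestedModel) -> DependencyGraph:
    """Edge u→v for every u on the right-hand side of v's defining equation.

    Derivative equations contribute edges into their state variable.  Node
    insertion is lexicographic so the graph (and everything derived from
    it) is deterministic across runs and platforms.
    """
    g = nx.DiGraph()
    for name in sorted(model.variables):
        g.add_node(name)
    edges: set[tuple[str, str]] = set()
    for eq in model.equations:
        for dep in eq.rhs_dependencies:
            edges.add((dep, eq.target))
    for u, v in sorted(edges):
        g.add_edge(u, v)
    return DependencyGraph(g)


def _nominal_env(model: IngestedModel, names) -> dict[str, float]:
    return {n: model.nominal_values.get(n, 1.0) for n in names}


def partial_dependence_sign(model: IngestedModel, u: str, v: str):
    """Sign of the partial dependence of v's equation on u at the nominal point.

    Central finite difference at relative step 1e-6, cross-checked at 1e-4;
    a sign that flips between step sizes, or an evaluation failure (e.g.
    division by zero at the nominal point), yields ``"indeterminate"``.
    Differences below 1e-12 in magnitude count as zero.
    """
    eq = model.equation_defining(v)
    if eq is None or u not in eq.rhs_dependencies:
        raise KeyError(f"no dependence {u} -> {v} in the model equations")
    env = _nominal_env(model, eq.rhs_dependencies)
    x0 = env[u]

    def diff_sign(rel_step: float) -> int | str:
        h = rel_step * abs(x0) if x0 != 0.0 else rel_step
        try:
            env[u] = x0 + h
            hi = ex.evaluate(eq.rhs, env)
            env[u] = x0 - h
            lo = ex.evaluate(eq.rhs, env)
        except (ex.ExprError, OverflowError, ZeroDivisionError):
            return INDETERMINATE
        finally:
            env[u] = x0
        d = hi - lo
        if not math.isfinite(d):
            return INDETERMINATE
        if abs(d) < 1e-12:
            return 0
        return 1 if d > 0 else -1

    s1 = diff_sign(1e-6)
    s2 = diff_sign(1e-4)
    if s1 == INDETERMINATE or s2 == INDETERMINATE:
        model.warnings.append(f"dependence sign {u}->{v}: evaluation failed")
        return INDETERMINATE
    if s1 != s2:
        return INDETERMINATE
    return s1
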