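"""Derive process-participant maps from ingested models.

Two generation procedures:

* **explicit-tags** — reaction networks tag reactants, products and
  modifiers directly, so each reaction becomes a chemical flow process and
  each modifier a modulation process with its annotated polarity.

* **dependency-inference** — equation-based models carry no reaction tags;
  participants are recovered from the variable dependency network.  For
  each variable annotated as a flow rate, an upstream traversal finds the
  force/amount variables (of the flow's biophysical domain) that drive it,
  and a downstream traversal finds those that respond to it.  The sign of
  each dependence orients the participant: a positive upstream driver or a
  negatively-responding downstream pool marks a source, the mirror cases a
  sink.  Same-domain amount variables that only feed the rate law — with no
  mass-balance response — are modulators, not participants, and are
  emitted as modulation processes with sign-derived polarity.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .ingest import (
    INDETERMINATE,
    DependencyGraph,
    IngestedModel,
    build_dependency_graph,
    partial_dependence_sign,
)
from .ontology import (
    CompositeAnnotation,
    PropertyClass,
    TermRegistry,
    classify_property,
    load_registry,
)
from .pmap import Participant, PhysioMap, ProcessNode, Provenance

__all__ = [
    "VariableRole",
    "ParticipantEvidence",
    "HOP_LIMIT",
    "classify_variable_role",
    "locate_participants",
    "infer_flow_process",
    "infer_from_reactions",
    "infer_from_dependencies",
    "infer_auto",
]

HOP_LIMIT = 10  # guards pathological dependency chains


@dataclass(frozen=True)
class VariableRole:
    name: str
    role: str  # flow | force | amount | other | unannotated
    domain_id: str | None = None


@dataclass(frozen=True)
class ParticipantEvidence:
    flow_variable: str
    neighbor: str
    direction: str  # upstream | downstream
    dependence_sign: object  # +1 | -1 | 0 | "indeterminate"
    hop_count: int
    same_domain: bool = True


def classify_variable_role(
    model: IngestedModel, registry: TermRegistry | None = None
) -> dict[str, VariableRole]:
    """Assign each model variable the role its annotation implies."""
    registry = registry or load_registry()
    roles: dict[str, VariableRole] = {}
    for name, var in model.variables.items():
        if var.annotation is None:
            roles[name] = VariableRole(name, "unannotated")
            continue
        pclass, domain = classify_property(registry, var.annotation.property_term)
        role = {
            PropertyClass.FLOW_RATE: "flow",
            PropertyClass.FORCE: "force",
            PropertyClass.AMOUNT: "amount",
            PropertyClass.OTHER: "other",
        }[pclass]
        roles[name] = VariableRole(name, role, domain)
    return roles


def _compose(a, b):
    if a == INDETERMINATE or b == INDETERMINATE:
        return INDETERMINATE
    return a * b


def locate_participants(
    model: IngestedModel,
    depgraph: DependencyGraph,
    roles: dict[str, VariableRole],
    flow_var: str,
) -> list[ParticipantEvidence]:
    """Collect force/amount evidence around one flow variable.

    Breadth-first in both directions; each branch stops at the first
    force/amount variable of the flow's domain (deeper ones are assumed
    mediated by the nearer).  Unannotated, other-role and wrong-domain
    variables are passed through, the wrong-domain ones being recorded as
    evidence too.  The composed sign along a path is the product of edge
    signs; any indeterminate hop makes the whole path indeterminate, and
    conflicting signs meeting at one variable do the same.
    """
    if roles[flow_var].role != "flow":
        raise ValueError(f"{flow_var} is not a flow-rate variable")
    flow_domain = roles[flow_var].domain_id
    g = depgraph.graph
    out: list[ParticipantEvidence] = []

    for direction in ("upstream", "downstream"):
        neighbors = g.predecessors if direction == "upstream" else g.successors
        # edge sign between the frontier variable and its neighbor
        def edge_sign(cur: str, nxt: str):
            if direction == "upstream":
                return partial_dependence_sign(model, nxt, cur)
            return partial_dependence_sign(model, cur, nxt)

        signs: dict[str, object] = {flow_var: +1}
        depth: dict[str, int] = {flow_var: 0}
        frontier = deque([flow_var])
        while frontier:
            cur = frontier.popleft()
            if depth[cur] >= HOP_LIMIT:
                continue
            for nxt in sorted(neighbors(cur)):
                composed = _compose(signs[cur], edge_sign(cur, nxt))
                if nxt in signs:
                    if depth[nxt] == depth[cur] + 1 and signs[nxt] != composed:
                        signs[nxt] = INDETERMINATE  # conflicting same-depth paths
                    continue
                signs[nxt] = composed
                depth[nxt] = depth[cur] + 1
                role = roles.get(nxt)
                stops_branch = (
                    role is not None
                    and role.role in ("force", "amount")
                    and role.domain_id == flow_domain
                )
                if not stops_branch:
                    # unannotated, other-role and wrong-domain variables are
                    # passed through (wrong-domain ones still recorded below)
                    frontier.append(nxt)

        for name in sorted(signs):
            if name == flow_var:
                continue
            role = roles.get(name)
            if role is None or role.role not in ("force", "amount"):
                continue
            out.append(
                ParticipantEvidence(
                    flow_variable=flow_var,
                    neighbor=name,
                    direction=direction,
                    dependence_sign=signs[name],
                    hop_count=depth[name],
                    same_domain=(role.domain_id == flow_domain),
                )
            )
    return out


def _variable_annotation(model: IngestedModel, name: str) -> CompositeAnnotation:
    ann = model.variables[name].annotation
    if ann is not None:
        return ann
    return CompositeAnnotation("opbx:AmountProperty", (), free_label=name)


def _entity_for(pmap: PhysioMap, model: IngestedModel, roles, name: str):
    ann = _variable_annotation(model, name)
    amount_property = None
    role = roles.get(name)
    if role is not None and role.role == "amount":
        amount_property = ann.property_term
    label = ann.free_label or (ann.bearer[0].term_id.split(":")[-1] if ann.bearer else name)
    if len(ann.bearer) > 1:
        label = " in ".join(b.term_id.split(":")[-1] for b in ann.bearer[:2])
    return pmap.add_entity(ann, display_label=label, amount_property=amount_property)


def infer_flow_process(
    flow_var: str,
    evidence: list[ParticipantEvidence],
    model: IngestedModel,
    roles: dict[str, VariableRole],
    pmap: PhysioMap,
    method: str = "dependency-inference",
) -> list[ProcessNode]:
    """Turn the evidence around one flow variable into map nodes.

    Role assignment: upstream drivers with positive dependence and
    downstream pools with negative response are sources; the mirror cases
    sinks.  An entity assigned both (with definite signs) is demoted to
    mediator with a recorded conflict.  Wrong-domain, indeterminate-sign or
    upstream-only-amount evidence becomes a polarity-carrying modulation
    instead of a participant.  With no definite evidence at all, the
    process is still created, flagged unresolved, with an implicit
    environment entity on the empty side.

    Returns the created processes (the flow first, then any modulations);
    entities are minted into ``pmap`` as a side effect.
    """
    provenance = Provenance(
        source_uri=model.source_uri, method=method, flow_variable=flow_var
    )
    flow_domain = roles[flow_var].domain_id
    proc = ProcessNode(
        id=f"flow_{flow_var}",
        kind="flow",
        domain_id=flow_domain,
        rate_variable=flow_var,
        provenance=provenance,
    )

    # group definite same-domain evidence per variable
    participant_ev: list[ParticipantEvidence] = []
    modulator_ev: list[ParticipantEvidence] = []
    downstream_entities: set[tuple] = set()
    for ev in evidence:
        if ev.direction == "downstream" and ev.same_domain:
            if ev.dependence_sign in (+1, -1):
                downstream_entities.add(
                    _variable_annotation(model, ev.neighbor).bearer_key()
                )
    for ev in evidence:
        definite = ev.dependence_sign in (+1, -1)
        if not ev.same_domain or not definite:
            modulator_ev.append(ev)
            continue
        var_role = roles[ev.neighbor].role
        if (
            ev.direction == "upstream"
            and var_role == "amount"
            and _variable_annotation(model, ev.neighbor).bearer_key()
            not in downstream_entities
        ):
            # feeds the rate law but is not moved by the flow: a modulator
            modulator_ev.append(ev)
            continue
        participant_ev.append(ev)

    role_by_entity: dict[str, set[str]] = {}
    for ev in participant_ev:
        ent = _entity_for(pmap, model, roles, ev.neighbor)
        if ev.direction == "upstream":
            role = "source" if ev.dependence_sign == +1 else "sink"
        else:
            role = "sink" if ev.dependence_sign == +1 else "source"
        role_by_entity.setdefault(ent.id, set()).add(role)

    participants: list[Participant] = []
    for eid in sorted(role_by_entity):
        assigned = role_by_entity[eid]
        if assigned == {"source", "sink"}:
            pmap.warnings.append(
                f"{flow_var}: entity {eid} is both source and sink; demoted to mediator"
            )
            participants.append(Participant(eid, "mediator"))
        else:
            for role in sorted(assigned):
                participants.append(Participant(eid, role))
    proc.participants = participants

    had_evidence = bool(participants)
    has_source = any(p.role == "source" for p in participants)
    has_sink = any(p.role == "sink" for p in participants)
    if not has_source or not has_sink:
        env = pmap.environment_entity()
        if not has_source:
            proc.participants.append(Participant(env.id, "source"))
        if not has_sink:
            proc.participants.append(Participant(env.id, "sink"))
        if not had_evidence:
            proc.unresolved = True
            pmap.warnings.append(
                f"{flow_var}: no definite participant evidence; boundary flow"
            )

    created = [proc]
    seen_regulators: set[str] = set()
    for ev in modulator_ev:
        if ev.direction != "upstream":
            continue  # a modulator acts on the rate, not the other way round
        ent = _entity_for(pmap, model, roles, ev.neighbor)
        if ent.id in seen_regulators or ent.id in role_by_entity:
            continue
        seen_regulators.add(ent.id)
        polarity = ev.dependence_sign if ev.dependence_sign in (-1, +1) else 0
        created.append(
            ProcessNode(
                id=f"mod_{ev.neighbor}_{proc.id}",
                kind="modulation",
                regulator_entity_id=ent.id,
                target_ref=proc.id,
                polarity=polarity,
                provenance=provenance,
            )
        )
    return created


def infer_from_reactions(
    model: IngestedModel, registry: TermRegistry | None = None
) -> PhysioMap:
    """Explicit-tag path: one chemical flow process per tagged reaction.

    Reactants become sources and products sinks (with stoichiometry); each
    modifier becomes a modulation process targeting the reaction with its
    annotated polarity.  Species without ontology annotations fall back to
    free-label entities named after the species.
    """
    registry = registry or load_registry()
    roles = classify_variable_role(model, registry)
    pmap = PhysioMap(
        metadata={
            "source": model.source_uri,
            "creation-method": "explicit-tags",
        }
    )
    for record in model.reactions:
        provenance = Provenance(
            source_uri=model.source_uri,
            method="explicit-tags",
            flow_variable=record.rate_variable,
        )
        proc = ProcessNode(
            id=f"flow_{record.id}",
            kind="flow",
            domain_id="domx:chemical",
            rate_variable=record.rate_variable,
            provenance=provenance,
        )
        for name, stoich in record.reactants:
            ent = _entity_for(pmap, model, roles, name)
            proc.participants.append(Participant(ent.id, "source", stoich))
        for name, stoich in record.products:
            ent = _entity_for(pmap, model, roles, name)
            proc.participants.append(Participant(ent.id, "sink", stoich))
        if not record.reactants or not record.products:
            env = pmap.environment_entity()
            if not record.reactants:
                proc.participants.append(Participant(env.id, "source"))
            if not record.products:
                proc.participants.append(Participant(env.id, "sink"))
        pmap.processes[proc.id] = proc
        for name, polarity in record.modifiers:
            ent = _entity_for(pmap, model, roles, name)
            mod = ProcessNode(
                id=f"mod_{name}_{proc.id}",
                kind="modulation",
                regulator_entity_id=ent.id,
                target_ref=proc.id,
                polarity=polarity,
                provenance=provenance,
            )
            pmap.processes[mod.id] = mod
    return pmap


def infer_from_dependencies(
    model: IngestedModel, registry: TermRegistry | None = None
) -> PhysioMap:
    """Dependency path: infer a flow process for every flow-rate variable."""
    registry = registry or load_registry()
    roles = classify_variable_role(model, registry)
    depgraph = build_dependency_graph(model)
    pmap = PhysioMap(
        metadata={
            "source": model.source_uri,
            "creation-method": "dependency-inference",
        }
    )
    flow_vars = sorted(n for n, r in roles.items() if r.role == "flow")
    if not flow_vars:
        pmap.warnings.append("model has no flow-rate-annotated variables")
        return pmap
    for flow_var in flow_vars:
        evidence = locate_participants(model, depgraph, roles, flow_var)
        for proc in infer_flow_process(
            flow_var, evidence, model, roles, pmap, method="dependency-inference"
        ):
            pmap.processes[proc.id] = proc
    return pmap


def infer_auto(model: IngestedModel, registry: TermRegistry | None = None) -> PhysioMap:
    """Explicit tags when the model has reactions, dependency inference otherwise."""
    if model.reactions:
        return infer_from_reactions(model, registry)
    return infer_from_dependencies(model, registry)
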