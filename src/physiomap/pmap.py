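"""The process-participant graph ("PhysioMap") and its serializations.

A PhysioMap holds *entity* nodes (portions of stuff bearing physical
properties) and *process* nodes of two kinds: **flow** processes that move
stuff (and its energy) from source entities to sink entities, possibly
enabled by mediators; and **modulation** processes in which a regulator
property changes another property without significant energy flow,
carrying a polarity (+1 stimulatory, -1 inhibitory, 0 unknown).

The module defines the XML file format (schema version 1.0), GraphML/DOT
exports for display tools, and the bipartite signed influence graph that
the qualitative tracing operations run on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from lxml import etree

from .ontology import BearerLink, CompositeAnnotation

__all__ = [
    "SCHEMA_VERSION",
    "EntityNode",
    "Participant",
    "ProcessNode",
    "Provenance",
    "PhysioMap",
    "Violation",
    "SignedGraph",
    "PhysioMapSchemaError",
    "validate",
    "write_physiomap_xml",
    "read_physiomap_xml",
    "export_graph",
    "to_signed_graph",
]

SCHEMA_VERSION = "1.0"

ROLES = ("source", "sink", "mediator")
KINDS = ("flow", "modulation")
METHODS = ("explicit-tags", "dependency-inference", "manual")

ENVIRONMENT_ENTITY_ID = "environment"


class PhysioMapSchemaError(ValueError):
    """PhysioMap XML that does not conform to the schema."""


@dataclass
class EntityNode:
    id: str
    annotation: CompositeAnnotation
    display_label: str = ""
    amount_property: str | None = None

    def key(self) -> tuple:
        return self.annotation.bearer_key()


@dataclass
class Participant:
    entity_id: str
    role: str
    stoichiometry: float = 1.0


@dataclass
class Provenance:
    source_uri: str = ""
    method: str = "manual"
    flow_variable: str | None = None


@dataclass
class ProcessNode:
    id: str
    kind: str
    domain_id: str | None = None
    participants: list[Participant] = field(default_factory=list)
    regulator_entity_id: str | None = None
    target_ref: str | None = None  # process id or entity id
    polarity: int | None = None
    rate_variable: str | None = None
    provenance: Provenance = field(default_factory=Provenance)
    unresolved: bool = False  # boundary flow with no definite evidence


@dataclass
class Violation:
    node_id: str
    rule: str
    message: str


@dataclass
class PhysioMap:
    entities: dict[str, EntityNode] = field(default_factory=dict)
    processes: dict[str, ProcessNode] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------

    def add_entity(
        self,
        annotation: CompositeAnnotation,
        display_label: str = "",
        amount_property: str | None = None,
    ) -> EntityNode:
        """Add an entity, reusing an existing node with the same borne entity.

        Entity identity is the bearer chain (or normalised free label); the
        pressure and the volume of the same portion of blood are one
        entity.  The amount property is recorded the first time an
        amount-classified property is seen.
        """
        key = annotation.bearer_key()
        for node in self.entities.values():
            if node.key() == key:
                if node.amount_property is None and amount_property is not None:
                    node.amount_property = amount_property
                if not node.display_label and display_label:
                    node.display_label = display_label
                return node
        eid = f"e{len(self.entities) + 1}"
        node = EntityNode(
            id=eid,
            annotation=annotation,
            display_label=display_label,
            amount_property=amount_property,
        )
        self.entities[eid] = node
        return node

    def environment_entity(self) -> EntityNode:
        """The implicit entity standing for the unmodeled exterior."""
        for node in self.entities.values():
            if node.id == ENVIRONMENT_ENTITY_ID:
                return node
        node = EntityNode(
            id=ENVIRONMENT_ENTITY_ID,
            annotation=CompositeAnnotation(
                "opbx:AmountProperty", (), free_label="environment"
            ),
            display_label="environment",
        )
        self.entities[node.id] = node
        return node

    def entity_by_key(self, key: tuple) -> EntityNode | None:
        for node in self.entities.values():
            if node.key() == key:
                return node
        return None


# ---------------------------------------------------------------------------
# validation


def validate(pmap: PhysioMap) -> list[Violation]:
    """Check structural invariants; violations are data, not exceptions."""
    out: list[Violation] = []
    seen_keys: dict[tuple, str] = {}
    for ent in pmap.entities.values():
        key = ent.key()
        if key in seen_keys:
            out.append(
                Violation(
                    ent.id,
                    "duplicate-entity",
                    f"entities {seen_keys[key]} and {ent.id} have equivalent annotations",
                )
            )
        else:
            seen_keys[key] = ent.id
    for proc in pmap.processes.values():
        if proc.kind not in KINDS:
            out.append(Violation(proc.id, "bad-kind", f"unknown kind {proc.kind!r}"))
            continue
        if proc.kind == "flow":
            if proc.domain_id is None:
                out.append(
                    Violation(proc.id, "flow-no-domain", "flow process lacks a domain")
                )
            ends = [p for p in proc.participants if p.role in ("source", "sink")]
            if not ends:
                out.append(
                    Violation(
                        proc.id,
                        "flow-no-participants",
                        "flow process has no source or sink participant",
                    )
                )
            for part in proc.participants:
                if part.role not in ROLES:
                    out.append(
                        Violation(proc.id, "bad-role", f"unknown role {part.role!r}")
                    )
                if part.stoichiometry <= 0:
                    out.append(
                        Violation(
                            proc.id, "bad-stoichiometry", "stoichiometry must be > 0"
                        )
                    )
                if part.entity_id not in pmap.entities:
                    out.append(
                        Violation(
                            proc.id,
                            "dangling-entity",
                            f"participant references missing entity {part.entity_id}",
                        )
                    )
        else:  # modulation
            if proc.regulator_entity_id is None or proc.target_ref is None:
                out.append(
                    Violation(
                        proc.id,
                        "modulation-incomplete",
                        "modulation needs regulator and target",
                    )
                )
                continue
            if proc.polarity not in (-1, 0, 1):
                out.append(
                    Violation(
                        proc.id, "bad-polarity", f"polarity {proc.polarity!r} not in -1/0/+1"
                    )
                )
            if proc.regulator_entity_id not in pmap.entities:
                out.append(
                    Violation(
                        proc.id,
                        "dangling-entity",
                        f"regulator references missing entity {proc.regulator_entity_id}",
                    )
                )
            if (
                proc.target_ref not in pmap.processes
                and proc.target_ref not in pmap.entities
            ):
                out.append(
                    Violation(
                        proc.id,
                        "dangling-target",
                        f"modulation target {proc.target_ref} not in map",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# XML serialization

_REL_ATTR = {"none": None}


def _annotation_element(ann: CompositeAnnotation) -> etree._Element:
    el = etree.Element("annotation")
    el.set("property", ann.property_term)
    if ann.free_label is not None and not ann.bearer:
        el.set("free-label", ann.free_label)
    for link in ann.bearer:
        b = etree.SubElement(el, "bearer")
        b.set("term", link.term_id)
        b.set("relation", link.relation)
    return el


def _parse_annotation(el: etree._Element, where: str) -> CompositeAnnotation:
    prop = el.get("property")
    if not prop:
        raise PhysioMapSchemaError(f"{where}/annotation: missing property")
    bearer = []
    for i, b in enumerate(el.findall("bearer"), 1):
        term = b.get("term")
        rel = b.get("relation", "none")
        if not term:
            raise PhysioMapSchemaError(f"{where}/annotation/bearer[{i}]: missing term")
        try:
            bearer.append(BearerLink(term, rel))
        except ValueError as exc:
            raise PhysioMapSchemaError(
                f"{where}/annotation/bearer[{i}]: {exc}"
            ) from None
    free_label = el.get("free-label")
    try:
        return CompositeAnnotation(prop, tuple(bearer), free_label=free_label)
    except ValueError as exc:
        raise PhysioMapSchemaError(f"{where}/annotation: {exc}") from None


def _num_attr(value: float) -> str:
    return repr(int(value)) if float(value).is_integer() else repr(float(value))


def physiomap_to_xml(pmap: PhysioMap) -> bytes:
    """Canonical XML bytes: sorted ids, fixed attribute order, LF, UTF-8."""
    root = etree.Element("physiomap")
    root.set("version", SCHEMA_VERSION)
    for key in sorted(pmap.metadata):
        root.set(key, pmap.metadata[key])
    for eid in sorted(pmap.entities):
        ent = pmap.entities[eid]
        el = etree.SubElement(root, "entity")
        el.set("id", ent.id)
        if ent.display_label:
            el.set("label", ent.display_label)
        if ent.amount_property:
            el.set("amount-property", ent.amount_property)
        el.append(_annotation_element(ent.annotation))
    for pid in sorted(pmap.processes):
        proc = pmap.processes[pid]
        el = etree.SubElement(root, "process")
        el.set("id", proc.id)
        el.set("kind", proc.kind)
        if proc.domain_id:
            el.set("domain", proc.domain_id)
        if proc.rate_variable:
            el.set("rate-var", proc.rate_variable)
        el.set("method", proc.provenance.method)
        if proc.provenance.source_uri:
            el.set("source", proc.provenance.source_uri)
        if proc.provenance.flow_variable:
            el.set("flow-var", proc.provenance.flow_variable)
        if proc.unresolved:
            el.set("unresolved", "true")
        if proc.kind == "flow":
            for part in sorted(
                proc.participants, key=lambda p: (p.role, p.entity_id)
            ):
                pel = etree.SubElement(el, "participant")
                pel.set("entity", part.entity_id)
                pel.set("role", part.role)
                pel.set("stoich", _num_attr(part.stoichiometry))
        else:
            mel = etree.SubElement(el, "modulation")
            mel.set("regulator", proc.regulator_entity_id or "")
            mel.set("target", proc.target_ref or "")
            mel.set("polarity", repr(proc.polarity if proc.polarity is not None else 0))
    text = etree.tostring(root, pretty_print=True, encoding="unicode")
    return ('<?xml version="1.0" encoding="UTF-8"?>\n' + text).encode("utf-8")


def write_physiomap_xml(pmap: PhysioMap, path: str | Path) -> None:
    violations = validate(pmap)
    if violations:
        raise PhysioMapSchemaError(
            "refusing to write invalid map: "
            + "; ".join(f"{v.node_id}:{v.rule}" for v in violations)
        )
    Path(path).write_bytes(physiomap_to_xml(pmap))


def read_physiomap_xml(path: str | Path) -> PhysioMap:
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise PhysioMapSchemaError(f"cannot parse {path}: {exc}") from None
    root = tree.getroot()
    if root.tag != "physiomap":
        raise PhysioMapSchemaError(f"/: root element is {root.tag!r}, not physiomap")
    pmap = PhysioMap()
    for key, value in root.attrib.items():
        if key != "version":
            pmap.metadata[key] = value
    for i, el in enumerate(root.findall("entity"), 1):
        where = f"/physiomap/entity[{i}]"
        eid = el.get("id")
        if not eid:
            raise PhysioMapSchemaError(f"{where}: missing id")
        if eid in pmap.entities:
            raise PhysioMapSchemaError(f"{where}: duplicate entity id {eid}")
        anns = el.findall("annotation")
        if len(anns) != 1:
            raise PhysioMapSchemaError(f"{where}: exactly one annotation required")
        pmap.entities[eid] = EntityNode(
            id=eid,
            annotation=_parse_annotation(anns[0], where),
            display_label=el.get("label", ""),
            amount_property=el.get("amount-property"),
        )
    for i, el in enumerate(root.findall("process"), 1):
        where = f"/physiomap/process[{i}]"
        pid = el.get("id")
        kind = el.get("kind")
        if not pid:
            raise PhysioMapSchemaError(f"{where}: missing id")
        if pid in pmap.processes:
            raise PhysioMapSchemaError(f"{where}: duplicate process id {pid}")
        if kind not in KINDS:
            raise PhysioMapSchemaError(f"{where}: kind {kind!r} not in {KINDS}")
        method = el.get("method", "manual")
        if method not in METHODS:
            raise PhysioMapSchemaError(f"{where}: method {method!r} not in {METHODS}")
        proc = ProcessNode(
            id=pid,
            kind=kind,
            domain_id=el.get("domain"),
            rate_variable=el.get("rate-var"),
            provenance=Provenance(
                source_uri=el.get("source", ""),
                method=method,
                flow_variable=el.get("flow-var"),
            ),
            unresolved=el.get("unresolved") == "true",
        )
        if kind == "flow":
            for j, pel in enumerate(el.findall("participant"), 1):
                role = pel.get("role")
                if role not in ROLES:
                    raise PhysioMapSchemaError(
                        f"{where}/participant[{j}]: role {role!r} not in {ROLES}"
                    )
                entity = pel.get("entity")
                if not entity:
                    raise PhysioMapSchemaError(
                        f"{where}/participant[{j}]: missing entity"
                    )
                stoich = float(pel.get("stoich", "1"))
                if stoich <= 0:
                    raise PhysioMapSchemaError(
                        f"{where}/participant[{j}]: stoich must be > 0"
                    )
                proc.participants.append(Participant(entity, role, stoich))
        else:
            mels = el.findall("modulation")
            if len(mels) != 1:
                raise PhysioMapSchemaError(
                    f"{where}: modulation process needs one modulation element"
                )
            mel = mels[0]
            proc.regulator_entity_id = mel.get("regulator")
            proc.target_ref = mel.get("target")
            try:
                proc.polarity = int(mel.get("polarity", "0"))
            except ValueError:
                raise PhysioMapSchemaError(
                    f"{where}/modulation: bad polarity"
                ) from None
            if proc.polarity not in (-1, 0, 1):
                raise PhysioMapSchemaError(
                    f"{where}/modulation: polarity must be -1, 0 or +1"
                )
        pmap.processes[pid] = proc
    violations = validate(pmap)
    if violations:
        v = violations[0]
        raise PhysioMapSchemaError(f"/physiomap: invalid map ({v.node_id}: {v.rule})")
    return pmap


# ---------------------------------------------------------------------------
# display exports


def export_graph(pmap: PhysioMap, fmt: str = "dot") -> str:
    """Render the map for graph tools: processes as boxes, entities as circles.

    ``fmt`` is ``"dot"`` (Graphviz) or ``"graphml"``.
    """
    if fmt not in ("dot", "graphml"):
        raise ValueError(f"unknown export format {fmt!r} (use 'dot' or 'graphml')")
    g = nx.DiGraph()
    for eid in sorted(pmap.entities):
        ent = pmap.entities[eid]
        g.add_node(
            f"entity:{eid}",
            label=ent.display_label or eid,
            shape="circle",
            kind="entity",
        )
    for pid in sorted(pmap.processes):
        proc = pmap.processes[pid]
        g.add_node(
            f"process:{pid}",
            label=proc.rate_variable or pid,
            shape="rectangle",
            kind=proc.kind,
        )
        if proc.kind == "flow":
            for part in proc.participants:
                if part.role == "sink":
                    g.add_edge(
                        f"process:{pid}",
                        f"entity:{part.entity_id}",
                        role="sink",
                        stoich=part.stoichiometry,
                    )
                else:
                    g.add_edge(
                        f"entity:{part.entity_id}",
                        f"process:{pid}",
                        role=part.role,
                        stoich=part.stoichiometry,
                    )
        else:
            g.add_edge(
                f"entity:{proc.regulator_entity_id}",
                f"process:{pid}",
                role="regulator",
            )
            target = proc.target_ref or ""
            tnode = (
                f"process:{target}" if target in pmap.processes else f"entity:{target}"
            )
            g.add_edge(f"process:{pid}", tnode, role="modulation",
                       polarity=proc.polarity if proc.polarity is not None else 0)
    if fmt == "graphml":
        return "\n".join(nx.generate_graphml(g, named_key_ids=True))
    lines = ["digraph physiomap {"]
    for node, attrs in g.nodes(data=True):
        shape = "box" if attrs["shape"] == "rectangle" else "ellipse"
        lines.append(f'  "{node}" [label="{attrs["label"]}", shape={shape}];')
    for u, v, attrs in g.edges(data=True):
        extra = f', taillabel="{attrs["role"]}"'
        if "polarity" in attrs:
            sign = {1: "+", -1: "-", 0: "?"}[attrs["polarity"]]
            extra += f', label="{sign}"'
        lines.append(f'  "{u}" -> "{v}" [{extra[2:]}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# signed influence graph


@dataclass
class SignedGraph:
    """Bipartite signed digraph over ("entity", id) and ("process", id) nodes."""

    graph: nx.DiGraph

    @property
    def nodes(self) -> list[tuple[str, str]]:
        return list(self.graph.nodes)

    def sign(self, u, v) -> int:
        return self.graph.edges[u, v]["sign"]

    def is_bipartite(self) -> bool:
        """No edge connects two entity nodes; participant edges alternate kinds.

        Modulation processes targeting a flow process contribute the one
        process-to-process edge kind, so the bipartition is asserted over
        entity adjacency rather than over all edges.
        """
        for u, v, attrs in self.graph.edges(data=True):
            if u[0] == "entity" and v[0] == "entity":
                return False
            if attrs["provenance"] != "modulation" and u[0] == v[0]:
                return False
        return True


def to_signed_graph(pmap: PhysioMap, include_depletion: bool = False) -> SignedGraph:
    """Build the signed influence graph the qualitative tracing runs on.

    Sources, mediators and regulators influence their process positively;
    a flow influences its sinks positively, and (only when
    ``include_depletion`` is set) its sources negatively; a modulation
    passes its polarity to its target.  Polarity-0 edges are kept as
    0-sign edges — an unlabeled modulator may act either way.
    """
    g = nx.DiGraph()
    for eid in sorted(pmap.entities):
        g.add_node(("entity", eid))
    for pid in sorted(pmap.processes):
        g.add_node(("process", pid))
    for pid in sorted(pmap.processes):
        proc = pmap.processes[pid]
        pnode = ("process", pid)
        if proc.kind == "flow":
            for part in proc.participants:
                enode = ("entity", part.entity_id)
                if part.role == "sink":
                    g.add_edge(pnode, enode, sign=+1, provenance="sink-role")
                elif part.role == "source":
                    g.add_edge(enode, pnode, sign=+1, provenance="source-role")
                    if include_depletion:
                        g.add_edge(pnode, enode, sign=-1, provenance="depletion")
                else:  # mediator
                    g.add_edge(enode, pnode, sign=+1, provenance="mediator-role")
        else:
            g.add_edge(
                ("entity", proc.regulator_entity_id), pnode, sign=+1,
                provenance="modulation",
            )
            target = proc.target_ref or ""
            tnode = (
                ("process", target) if target in pmap.processes else ("entity", target)
            )
            g.add_edge(
                pnode, tnode,
                sign=proc.polarity if proc.polarity is not None else 0,
                provenance="modulation",
            )
    return SignedGraph(g)
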