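"""Semantic merging of process-participant maps.

Two maps extracted from different models often describe overlapping
physiology.  Merging unifies entities that denote the same borne physical
entity and processes that are semantically identical — same kind, domain
and full participant signature (entity identity, role and stoichiometry;
for modulations also regulator, target and polarity) — so that a shared
process is represented once in the merged system.  Near-matches that
differ only in polarity or stoichiometry are conflicts: both variants are
retained under disambiguated ids and reported, never silently collapsed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .pmap import PhysioMap, PhysioMapSchemaError, ProcessNode, validate

__all__ = ["MergeReport", "merge_physiomaps"]


@dataclass
class MergeReport:
    entity_matches: list[tuple[str, str]] = field(default_factory=list)
    process_matches: list[tuple[str, str]] = field(default_factory=list)
    conflicts: list[dict] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)  # retained id -> origin

    def as_dict(self) -> dict:
        return {
            "entity_matches": [list(p) for p in self.entity_matches],
            "process_matches": [list(p) for p in self.process_matches],
            "conflicts": self.conflicts,
            "provenance": self.provenance,
        }


def _flow_signature(proc: ProcessNode, ekey, with_stoich: bool):
    parts = frozenset(
        (ekey(p.entity_id), p.role, p.stoichiometry if with_stoich else None)
        for p in proc.participants
    )
    return ("flow", proc.domain_id, parts)


def _require_valid(pmap: PhysioMap, label: str) -> None:
    violations = validate(pmap)
    if violations:
        v = violations[0]
        raise PhysioMapSchemaError(f"{label} does not validate ({v.node_id}: {v.rule})")


def merge_physiomaps(m1: PhysioMap, m2: PhysioMap) -> tuple[PhysioMap, MergeReport]:
    """Merge two validated maps; semantically identical nodes appear once.

    Entity identity is the borne-entity key (bearer chain, or normalised
    free label for unannotated species — exact label equality only, to
    avoid false unification).  Process identity requires the full
    participant signature; a pair equal up to polarity or stoichiometry is
    reported as a conflict and both variants are kept.  The merged map
    always validates.
    """
    _require_valid(m1, "first map")
    _require_valid(m2, "second map")
    report = MergeReport()
    merged = PhysioMap(metadata=dict(m1.metadata))
    if m2.metadata.get("source") and m2.metadata.get("source") != m1.metadata.get(
        "source"
    ):
        merged.metadata["merged-source"] = m2.metadata["source"]
    merged.metadata["creation-method"] = "merge"

    # --- entities ---------------------------------------------------------
    entity_map_1: dict[str, str] = {}
    entity_map_2: dict[str, str] = {}
    for eid in sorted(m1.entities):
        node = copy.deepcopy(m1.entities[eid])
        merged.entities[node.id] = node
        entity_map_1[eid] = node.id
        report.provenance[node.id] = "m1"
    for eid in sorted(m2.entities):
        node = m2.entities[eid]
        existing = merged.entity_by_key(node.key())
        if existing is not None:
            entity_map_2[eid] = existing.id
            report.entity_matches.append((existing.id, eid))
            if existing.amount_property is None and node.amount_property:
                existing.amount_property = node.amount_property
            report.provenance[existing.id] = "m1+m2"
            continue
        new = copy.deepcopy(node)
        if new.id in merged.entities:
            new.id = f"{new.id}_b"
        merged.entities[new.id] = new
        entity_map_2[eid] = new.id
        report.provenance[new.id] = "m2"

    def key1(eid: str):
        return m1.entities[eid].key()

    def key2(eid: str):
        return m2.entities[eid].key()

    # --- flow processes ---------------------------------------------------
    flows1 = {
        pid: p for pid, p in m1.processes.items() if p.kind == "flow"
    }
    flows2 = {
        pid: p for pid, p in m2.processes.items() if p.kind == "flow"
    }
    sig_exact: dict[tuple, list[str]] = {}
    sig_loose: dict[tuple, str] = {}
    process_map_1: dict[str, str] = {}
    process_map_2: dict[str, str] = {}
    for pid in sorted(flows1):
        proc = copy.deepcopy(flows1[pid])
        for part in proc.participants:
            part.entity_id = entity_map_1[part.entity_id]
        merged.processes[proc.id] = proc
        process_map_1[pid] = proc.id
        report.provenance[proc.id] = "m1"
        sig_exact.setdefault(_flow_signature(flows1[pid], key1, True), []).append(proc.id)
        sig_loose.setdefault(_flow_signature(flows1[pid], key1, False), proc.id)
    for pid in sorted(flows2):
        proc2 = flows2[pid]
        exact = _flow_signature(proc2, key2, True)
        loose = _flow_signature(proc2, key2, False)
        if sig_exact.get(exact):
            target = sig_exact[exact].pop(0)  # each node matches at most once
            process_map_2[pid] = target
            report.process_matches.append((target, pid))
            report.provenance[target] = "m1+m2"
            continue
        new = copy.deepcopy(proc2)
        for part in new.participants:
            part.entity_id = entity_map_2[part.entity_id]
        if loose in sig_loose:
            report.conflicts.append(
                {
                    "kind": "flow-stoichiometry",
                    "retained": [sig_loose[loose], f"{pid}_b"],
                    "detail": "same participants and roles, different stoichiometry",
                }
            )
            new.id = f"{pid}_b"
        elif new.id in merged.processes:
            new.id = f"{new.id}_b"
        merged.processes[new.id] = new
        process_map_2[pid] = new.id
        report.provenance[new.id] = "m2"

    # --- modulation processes --------------------------------------------
    def mod_signature(proc: ProcessNode, ekey, pmap: PhysioMap, pmap_procs, with_pol):
        target = proc.target_ref or ""
        if target in pmap.processes:
            tsig = ("process", _flow_signature(pmap.processes[target], ekey, True))
        else:
            tsig = ("entity", ekey(target) if target in pmap.entities else target)
        return (
            "modulation",
            ekey(proc.regulator_entity_id),
            tsig,
            proc.polarity if with_pol else None,
        )

    mods1 = {pid: p for pid, p in m1.processes.items() if p.kind == "modulation"}
    mods2 = {pid: p for pid, p in m2.processes.items() if p.kind == "modulation"}
    msig_exact: dict[tuple, list[str]] = {}
    msig_loose: dict[tuple, str] = {}
    for pid in sorted(mods1):
        proc = copy.deepcopy(mods1[pid])
        proc.regulator_entity_id = entity_map_1[proc.regulator_entity_id]
        if proc.target_ref in m1.processes:
            proc.target_ref = process_map_1.get(proc.target_ref, proc.target_ref)
        elif proc.target_ref in m1.entities:
            proc.target_ref = entity_map_1[proc.target_ref]
        merged.processes[proc.id] = proc
        process_map_1[pid] = proc.id
        report.provenance[proc.id] = "m1"
        msig_exact.setdefault(
            mod_signature(mods1[pid], key1, m1, mods1, True), []
        ).append(proc.id)
        msig_loose.setdefault(mod_signature(mods1[pid], key1, m1, mods1, False), proc.id)
    for pid in sorted(mods2):
        proc2 = mods2[pid]
        exact = mod_signature(proc2, key2, m2, mods2, True)
        loose = mod_signature(proc2, key2, m2, mods2, False)
        if msig_exact.get(exact):
            target = msig_exact[exact].pop(0)
            process_map_2[pid] = target
            report.process_matches.append((target, pid))
            report.provenance[target] = "m1+m2"
            continue
        new = copy.deepcopy(proc2)
        new.regulator_entity_id = entity_map_2[new.regulator_entity_id]
        if new.target_ref in m2.processes:
            new.target_ref = process_map_2.get(new.target_ref, new.target_ref)
        elif new.target_ref in m2.entities:
            new.target_ref = entity_map_2[new.target_ref]
        if loose in msig_loose:
            report.conflicts.append(
                {
                    "kind": "modulation-polarity",
                    "retained": [msig_loose[loose], f"{pid}_b"],
                    "detail": "same regulator and target, different polarity",
                }
            )
            new.id = f"{pid}_b"
        elif new.id in merged.processes:
            new.id = f"{new.id}_b"
        merged.processes[new.id] = new
        process_map_2[pid] = new.id
        report.provenance[new.id] = "m2"

    _require_valid(merged, "merged map")
    return merged, report
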