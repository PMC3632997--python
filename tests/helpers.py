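"""Shared comparison utilities for the test suite.

Everything here is deliberately independent of the implementation paths it
checks: signatures are computed from public map structure only, and the
qualitative-propagation oracle enumerates simple paths by brute force.
"""

from __future__ import annotations

import copy
import itertools

import networkx as nx

import physiomap as pm
from physiomap import fixtures as fx
from physiomap.trace import SignState


def flow_signatures(pmap: pm.PhysioMap):
    """Comparable summary of a map: flows, modulations, entities by key."""

    def ekey(eid):
        return pmap.entities[eid].key()

    flows = sorted(
        (
            proc.rate_variable,
            proc.domain_id,
            tuple(sorted((ekey(p.entity_id), p.role) for p in proc.participants)),
        )
        for proc in pmap.processes.values()
        if proc.kind == "flow"
    )
    mods = sorted(
        (proc.rate_variable, ekey(proc.regulator_entity_id), proc.polarity)
        for proc in pmap.processes.values()
        if proc.kind == "modulation"
    )
    entities = sorted(e.key() for e in pmap.entities.values())
    return flows, mods, entities


def maps_isomorphic(a: pm.PhysioMap, b: pm.PhysioMap) -> bool:
    return flow_signatures(a) == flow_signatures(b)


def random_reaction_map(seed: int, **kwargs) -> pm.PhysioMap:
    """A map inferred from a seeded random reaction network (tag path)."""
    defaults = dict(n_species=6, n_reactions=5, p_modifier=0.3, acyclic=False)
    defaults.update(kwargs)
    model, _spec = fx.make_random_network(seed=seed, **defaults)
    return pm.infer_from_reactions(model)


def overlapping_map_pair(seed: int, total: int = 8, overlap: int = 3):
    """Two maps from reaction subsets of one network, sharing `overlap` reactions."""
    model, _spec = fx.make_random_network(
        n_species=8, n_reactions=total, p_modifier=0.2, seed=seed, acyclic=False
    )
    half = (total + overlap) // 2
    m1 = copy.deepcopy(model)
    m1.reactions = model.reactions[:half]
    m2 = copy.deepcopy(model)
    m2.reactions = model.reactions[half - overlap:]
    return pm.infer_from_reactions(m1), pm.infer_from_reactions(m2)


def shared_process_count(a: pm.PhysioMap, b: pm.PhysioMap) -> int:
    """Multiset intersection of full process signatures, computed directly."""

    def sigs(pmap):
        def ekey(eid):
            return pmap.entities[eid].key()

        out = []
        for proc in pmap.processes.values():
            if proc.kind == "flow":
                out.append(
                    (
                        "flow",
                        proc.domain_id,
                        frozenset(
                            (ekey(p.entity_id), p.role, p.stoichiometry)
                            for p in proc.participants
                        ),
                    )
                )
            else:
                target = proc.target_ref
                if target in pmap.processes:
                    tgt = pmap.processes[target]
                    tsig = (
                        "process",
                        tgt.domain_id,
                        frozenset(
                            (ekey(p.entity_id), p.role, p.stoichiometry)
                            for p in tgt.participants
                        ),
                    )
                else:
                    tsig = ("entity", ekey(target))
                out.append(
                    ("modulation", ekey(proc.regulator_entity_id), tsig, proc.polarity)
                )
        return out

    sa, sb = sigs(a), list(sigs(b))
    shared = 0
    for sig in sa:
        if sig in sb:
            sb.remove(sig)
            shared += 1
    return shared


def entity_for_species(pmap: pm.PhysioMap, term_id: str) -> str:
    """Entity node id whose base bearer term is `term_id`."""
    for ent in pmap.entities.values():
        if ent.annotation.bearer and ent.annotation.bearer[0].term_id == term_id:
            return ent.id
    raise KeyError(term_id)


def path_join_oracle(graph: pm.SignedGraph, start) -> dict:
    """Brute-force expectation for propagation on an acyclic signed graph.

    For every node, enumerate all simple paths from the perturbed node and
    join the per-path outcomes: a path with any 0-sign edge contributes
    ambiguous, otherwise up/down by the product of its edge signs.
    """
    g = graph.graph
    expected = {n: SignState.UNSET for n in g.nodes}
    expected[start] = SignState.UP
    for node in g.nodes:
        if node == start:
            continue
        outcomes = set()
        for path in nx.all_simple_paths(g, start, node):
            sign = 1
            for u, v in zip(path, path[1:]):
                s = g.edges[u, v]["sign"]
                sign = None if (s == 0 or sign is None) else sign * s
            outcomes.add(
                SignState.AMBIGUOUS
                if sign is None
                else (SignState.UP if sign > 0 else SignState.DOWN)
            )
        if not outcomes:
            continue
        if len(outcomes) == 1:
            expected[node] = outcomes.pop()
        else:
            expected[node] = SignState.AMBIGUOUS
    return expected
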