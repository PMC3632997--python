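"""Qualitative interrogation of a signed influence graph.

A hypothetical perturbation (an increment or decrement of an entity amount
or a process rate, or an experimental clamp) is propagated through the
network as qualitative up/down states over a five-value join-semilattice::

    unset  <  up, down  <  ambiguous          (clamped blocks propagation)

A positive edge preserves the incoming state, a negative edge flips
up/down, and an unknown-polarity (0) edge transmits *ambiguous* from any
active source — an unlabeled modulator may act either way, and silence
would understate the uncertainty.  The fixed point over this finite
lattice exists and is reached in at most 2·|nodes| sweeps.

The module also enumerates signed A-to-B paths and classifies elementary
feedback loops: a loop is positive when it has an even number of negative
edges (and no unknown-sign edges), negative when odd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx

from .pmap import SignedGraph

__all__ = [
    "SignState",
    "Perturbation",
    "TraceResult",
    "LoopRecord",
    "combine_signs",
    "propagate",
    "find_paths",
    "detect_feedback_loops",
]


class SignState(str, Enum):
    UNSET = "unset"
    UP = "up"
    DOWN = "down"
    CLAMPED = "clamped"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Perturbation:
    node: tuple[str, str]  # ("entity"|"process", id)
    direction: str  # up | down | clamp


@dataclass
class TraceResult:
    states: dict[tuple[str, str], SignState]
    edges_used: list[tuple] = field(default_factory=list)
    iterations: int = 0

    def affected(self) -> dict[tuple[str, str], SignState]:
        return {
            n: s
            for n, s in self.states.items()
            if s not in (SignState.UNSET, SignState.CLAMPED)
        }


def combine_signs(a: SignState, b: SignState) -> SignState:
    """Join on the sign lattice; clamped states do not combine."""
    if a is SignState.CLAMPED or b is SignState.CLAMPED:
        raise ValueError("clamped states block propagation and cannot be joined")
    if a is SignState.UNSET:
        return b
    if b is SignState.UNSET:
        return a
    if a is b:
        return a
    return SignState.AMBIGUOUS


def _transmit(state: SignState, sign: int) -> SignState:
    """State carried across one signed edge."""
    if state in (SignState.UNSET, SignState.CLAMPED):
        return SignState.UNSET  # clamped nodes absorb influence, transmit none
    if sign == 0:
        return SignState.AMBIGUOUS
    if state is SignState.AMBIGUOUS or sign == +1:
        return state
    return SignState.DOWN if state is SignState.UP else SignState.UP


def propagate(
    graph: SignedGraph, perturbations: list[Perturbation]
) -> TraceResult:
    """Propagate perturbations to the least fixed point of the sign lattice.

    Every node is reported; ``unset`` means unaffected.  Termination is
    guaranteed by monotonicity (each node's state can only climb the
    finite lattice) and asserted at 2·|nodes| sweeps.
    """
    g = graph.graph
    for p in perturbations:
        if p.node not in g:
            raise KeyError(f"unknown node {p.node!r}")
        if p.direction not in ("up", "down", "clamp"):
            raise ValueError(f"unknown perturbation direction {p.direction!r}")
    if not any(p.direction != "clamp" for p in perturbations):
        raise ValueError("need at least one non-clamp perturbation")

    initial: dict[tuple[str, str], SignState] = {}
    for p in perturbations:
        state = {
            "up": SignState.UP,
            "down": SignState.DOWN,
            "clamp": SignState.CLAMPED,
        }[p.direction]
        prev = initial.get(p.node)
        if prev is SignState.CLAMPED or state is SignState.CLAMPED:
            initial[p.node] = SignState.CLAMPED
        else:
            initial[p.node] = combine_signs(prev or SignState.UNSET, state)

    states: dict[tuple[str, str], SignState] = {
        n: initial.get(n, SignState.UNSET) for n in g.nodes
    }
    edges_used: set[tuple] = set()
    # every productive sweep climbs at least one node, and a node can climb
    # at most twice (unset -> up/down -> ambiguous), so productive sweeps
    # never exceed 2*|nodes|
    max_sweeps = 2 * max(1, g.number_of_nodes())
    sweeps = 0
    changed = True
    order = sorted(g.nodes)
    while changed:
        if sweeps > max_sweeps:
            raise RuntimeError("propagation failed to reach a fixed point")
        changed = False
        for node in order:
            if states[node] is SignState.CLAMPED:
                continue
            acc = initial.get(node, SignState.UNSET)
            for pred in g.predecessors(node):
                incoming = _transmit(states[pred], g.edges[pred, node]["sign"])
                if incoming is not SignState.UNSET:
                    edges_used.add((pred, node))
                acc = combine_signs(acc, incoming)
            if acc is not states[node]:
                states[node] = acc
                changed = True
        if changed:
            sweeps += 1
    return TraceResult(states=states, edges_used=sorted(edges_used), iterations=sweeps)


def find_paths(
    graph: SignedGraph,
    from_node: tuple[str, str],
    to_node: tuple[str, str],
    max_len: int = 12,
) -> list[tuple[list[tuple[str, str]], object]]:
    """All simple directed paths from A to B up to ``max_len`` edges.

    Depth-first with lexicographic neighbor order; each result carries the
    product of its edge signs, or ``"indeterminate"`` when a 0-sign edge
    lies on the path.
    """
    g = graph.graph
    for node in (from_node, to_node):
        if node not in g:
            raise KeyError(f"unknown node {node!r}")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    results: list[tuple[list[tuple[str, str]], object]] = []
    path = [from_node]
    on_path = {from_node}

    def dfs(cur, sign) -> None:
        if len(path) - 1 >= max_len:
            return
        for nxt in sorted(g.successors(cur)):
            if nxt in on_path:
                continue
            edge_sign = g.edges[cur, nxt]["sign"]
            nxt_sign = (
                "indeterminate"
                if (sign == "indeterminate" or edge_sign == 0)
                else sign * edge_sign
            )
            path.append(nxt)
            if nxt == to_node:
                results.append((list(path), nxt_sign))
            else:
                on_path.add(nxt)
                dfs(nxt, nxt_sign)
                on_path.discard(nxt)
            path.pop()

    if from_node == to_node:
        return []
    dfs(from_node, +1)
    return results


@dataclass(frozen=True)
class LoopRecord:
    nodes: tuple[tuple[str, str], ...]  # canonical rotation, smallest node first
    polarity: str  # positive | negative | indeterminate


def detect_feedback_loops(graph: SignedGraph, max_len: int = 20) -> list[LoopRecord]:
    """Classify every elementary directed cycle up to ``max_len`` edges.

    Positive feedback: even number of negative edges and no unknown-sign
    edges; negative feedback: odd number; any 0-sign edge on the loop makes
    its polarity indeterminate.
    """
    g = graph.graph
    records: list[LoopRecord] = []
    for cycle in nx.simple_cycles(g, length_bound=max_len):
        pivot = min(range(len(cycle)), key=lambda i: cycle[i])
        ordered = tuple(cycle[pivot:] + cycle[:pivot])
        negatives = 0
        indeterminate = False
        for i, node in enumerate(ordered):
            nxt = ordered[(i + 1) % len(ordered)]
            sign = g.edges[node, nxt]["sign"]
            if sign == 0:
                indeterminate = True
            elif sign < 0:
                negatives += 1
        if indeterminate:
            polarity = "indeterminate"
        else:
            polarity = "negative" if negatives % 2 else "positive"
        records.append(LoopRecord(nodes=ordered, polarity=polarity))
    records.sort(key=lambda r: (len(r.nodes), r.nodes))
    return records
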