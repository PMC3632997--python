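"""Sign algebra, perturbation propagation, path tracing, loop polarity."""

import itertools
import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import physiomap as pm
from physiomap.pmap import SignedGraph
from physiomap.trace import (
    LoopRecord,
    Perturbation,
    SignState,
    combine_signs,
    detect_feedback_loops,
    find_paths,
    propagate,
)
from helpers import entity_for_species, path_join_oracle, random_reaction_map

JOINABLE = [SignState.UNSET, SignState.UP, SignState.DOWN, SignState.AMBIGUOUS]


def signed(edges) -> SignedGraph:
    """Build a signed graph directly from (u, v, sign) triples."""
    g = nx.DiGraph()
    for u, v, s in edges:
        g.add_edge(u, v, sign=s, provenance="test")
    return SignedGraph(g)


class TestCombineSigns:
    def test_unset_is_identity(self):
        assert combine_signs(SignState.UP, SignState.UNSET) is SignState.UP

    def test_conflict_is_ambiguous(self):
        assert combine_signs(SignState.UP, SignState.DOWN) is SignState.AMBIGUOUS

    def test_exhaustive_semilattice_laws(self):
        """Associative, commutative, idempotent over every joinable pair/triple."""
        for a in JOINABLE:
            assert combine_signs(a, a) is a
        for a, b in itertools.product(JOINABLE, repeat=2):
            assert combine_signs(a, b) is combine_signs(b, a)
        for a, b, c in itertools.product(JOINABLE, repeat=3):
            assert combine_signs(a, combine_signs(b, c)) is combine_signs(
                combine_signs(a, b), c
            )

    def test_clamped_refuses_to_join(self):
        with pytest.raises(ValueError):
            combine_signs(SignState.CLAMPED, SignState.UP)


class TestPropagate:
    def test_negative_edge_flips(self):
        g = signed([(("entity", "A"), ("process", "F"), -1)])
        res = propagate(g, [Perturbation(("entity", "A"), "up")])
        assert res.states[("process", "F")] is SignState.DOWN

    def test_unknown_sign_edge_transmits_ambiguous(self):
        g = signed([(("entity", "A"), ("process", "F"), 0)])
        res = propagate(g, [Perturbation(("entity", "A"), "up")])
        assert res.states[("process", "F")] is SignState.AMBIGUOUS

    def test_clamped_node_blocks_propagation(self):
        g = signed(
            [
                (("entity", "A"), ("process", "F"), 1),
                (("process", "F"), ("entity", "B"), 1),
            ]
        )
        res = propagate(
            g,
            [
                Perturbation(("entity", "A"), "up"),
                Perturbation(("process", "F"), "clamp"),
            ],
        )
        assert res.states[("process", "F")] is SignState.CLAMPED
        assert res.states[("entity", "B")] is SignState.UNSET

    def test_glucose_increment_raises_whole_chain(self, glycolysis):
        model, spec = glycolysis
        pmap = pm.infer_from_reactions(model)
        g = pm.to_signed_graph(pmap)
        glc = entity_for_species(pmap, "chebix:Glucose")
        res = propagate(g, [Perturbation(("entity", glc), "up")])
        term_of = {
            eid: e.annotation.bearer[0].term_id for eid, e in pmap.entities.items()
        }
        ups = {n for n, s in res.states.items() if s is SignState.UP}
        chain_terms = {
            "chebix:Glucose", "chebix:Glucose6Phosphate", "chebix:Fructose6Phosphate",
            "chebix:Fructose16Bisphosphate", "chebix:Phosphoenolpyruvate",
            "chebix:Pyruvate",
        }
        up_terms = {term_of[nid] for kind, nid in ups if kind == "entity"}
        assert up_terms == chain_terms
        up_procs = {nid for kind, nid in ups if kind == "process"}
        assert up_procs == {f"flow_{r}" for r in spec.expected["reaction_ids"]}
        # the modifier pools and modulation processes are off-path
        for n, s in res.states.items():
            if n not in ups:
                assert s is SignState.UNSET

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_path_join_on_acyclic_maps(self, seed):
        pmap = random_reaction_map(seed, n_species=7, n_reactions=6, acyclic=True)
        g = pm.to_signed_graph(pmap)
        start = sorted(n for n in g.nodes if n[0] == "entity")[seed % 3]
        res = propagate(g, [Perturbation(start, "up")])
        assert res.states == path_join_oracle(g, start)

    def test_iteration_bound_on_cyclic_fixtures(self, cv4):
        model, _ = cv4
        pmap = pm.infer_from_dependencies(model)
        g = pm.to_signed_graph(pmap, include_depletion=True)
        start = sorted(g.nodes)[0]
        res = propagate(g, [Perturbation(start, "up")])
        assert res.iterations <= 2 * g.graph.number_of_nodes()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), extra=st.integers(0, 2))
    def test_adding_perturbations_is_monotone(self, seed, extra):
        """A second perturbation can only move states up the lattice."""
        order = {
            SignState.UNSET: 0, SignState.UP: 1, SignState.DOWN: 1,
            SignState.AMBIGUOUS: 2, SignState.CLAMPED: 2,
        }
        pmap = random_reaction_map(seed % 30, n_species=6, n_reactions=5)
        g = pm.to_signed_graph(pmap)
        nodes = sorted(g.nodes)
        base_node = nodes[seed % len(nodes)]
        extra_node = nodes[(seed + 1 + extra) % len(nodes)]
        base = propagate(g, [Perturbation(base_node, "up")])
        more = propagate(
            g,
            [Perturbation(base_node, "up"), Perturbation(extra_node, "up")],
        )
        for node in nodes:
            a, b = base.states[node], more.states[node]
            if a is b:
                continue
            assert order[b] >= order[a], node

    def test_unknown_node_raises(self):
        g = signed([(("entity", "A"), ("process", "F"), 1)])
        with pytest.raises(KeyError):
            propagate(g, [Perturbation(("entity", "nope"), "up")])

    def test_requires_a_non_clamp_perturbation(self):
        g = signed([(("entity", "A"), ("process", "F"), 1)])
        with pytest.raises(ValueError):
            propagate(g, [Perturbation(("entity", "A"), "clamp")])


class TestFindPaths:
    def test_disconnected_nodes_give_empty_list(self):
        g = signed([(("entity", "A"), ("process", "F"), 1)])
        g.graph.add_node(("entity", "Z"))
        assert find_paths(g, ("entity", "Z"), ("process", "F")) == []

    def test_two_edge_path_sign_is_product(self):
        g = signed(
            [
                (("entity", "A"), ("process", "F"), 1),
                (("process", "F"), ("entity", "B"), -1),
            ]
        )
        results = find_paths(g, ("entity", "A"), ("entity", "B"))
        assert len(results) == 1
        path, sign = results[0]
        assert sign == -1 and len(path) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        """Path sets and signs equal an independent all-simple-paths sweep."""
        rng = random.Random(seed)
        g = nx.DiGraph()
        nodes = [("entity", f"n{i}") if i % 2 == 0 else ("process", f"n{i}")
                 for i in range(8)]
        for u in nodes:
            for v in nodes:
                if u != v and rng.random() < 0.25:
                    g.add_edge(u, v, sign=rng.choice([-1, 0, 1]), provenance="test")
        for n in nodes:
            g.add_node(n)
        sg = SignedGraph(g)
        src, dst = nodes[0], nodes[-1]
        got = {(tuple(p), s) for p, s in find_paths(sg, src, dst, max_len=8)}
        expected = set()
        for path in nx.all_simple_paths(g, src, dst, cutoff=8):
            sign = 1
            for u, v in zip(path, path[1:]):
                es = g.edges[u, v]["sign"]
                sign = "indeterminate" if (es == 0 or sign == "indeterminate") else sign * es
            expected.add((tuple(path), sign))
        assert got == expected

    def test_max_len_caps_path_length(self):
        chain = [(("entity", f"n{i}"), ("process", f"n{i+1}"), 1) for i in range(0, 6, 2)]
        chain += [(("process", f"n{i}"), ("entity", f"n{i+1}"), 1) for i in range(1, 6, 2)]
        g = signed(chain)
        assert find_paths(g, ("entity", "n0"), ("entity", "n6"), max_len=3) == []
        assert len(find_paths(g, ("entity", "n0"), ("entity", "n6"), max_len=6)) == 1


class TestDetectFeedbackLoops:
    def test_acyclic_graph_has_no_loops(self, glycolysis):
        model, _ = glycolysis
        g = pm.to_signed_graph(pm.infer_from_reactions(model))
        assert detect_feedback_loops(g) == []

    def test_single_negative_edge_makes_negative_loop(self):
        cycle = [
            (("entity", "a"), ("process", "b"), 1),
            (("process", "b"), ("entity", "c"), 1),
            (("entity", "c"), ("process", "d"), 1),
            (("process", "d"), ("entity", "a"), -1),
        ]
        records = detect_feedback_loops(signed(cycle))
        assert len(records) == 1
        assert records[0].polarity == "negative"
        assert records[0].nodes[0] == ("entity", "a")  # canonical rotation

    @pytest.mark.parametrize("length", [2, 3, 4])
    def test_polarity_equals_negative_edge_parity_exhaustively(self, length):
        for signs in itertools.product([1, -1], repeat=length):
            edges = []
            for i in range(length):
                u = ("entity", f"n{i}") if i % 2 == 0 else ("process", f"n{i}")
                j = (i + 1) % length
                v = ("entity", f"n{j}") if j % 2 == 0 else ("process", f"n{j}")
                edges.append((u, v, signs[i]))
            records = detect_feedback_loops(signed(edges))
            assert len(records) == 1
            expected = "negative" if signs.count(-1) % 2 else "positive"
            assert records[0].polarity == expected, signs

    def test_zero_sign_edge_makes_loop_indeterminate(self):
        cycle = [
            (("entity", "a"), ("process", "b"), 1),
            (("process", "b"), ("entity", "a"), 0),
        ]
        records = detect_feedback_loops(signed(cycle))
        assert records[0].polarity == "indeterminate"

    def test_cv_ring_is_one_positive_loop(self, cv4):
        model, _ = cv4
        g = pm.to_signed_graph(pm.infer_from_dependencies(model))
        records = detect_feedback_loops(g)
        assert [(len(r.nodes), r.polarity) for r in records] == [(8, "positive")]
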