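"""Entailment index vs an independent brute-force transitive closure."""

import itertools
import random

import numpy as np
import pytest

from ontoeval import Mapping, Relation, build_index, split_equivalence
from .conftest import make_ontology, random_mapping


def brute_closure(n_nodes, edges):
    """Reflexive-transitive closure by repeated boolean matrix squaring."""
    reach = np.eye(n_nodes, dtype=bool)
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    for a, b in edges:
        adj[a, b] = True
    reach |= adj
    for _ in range(int(np.ceil(np.log2(max(n_nodes, 2)))) + 1):
        reach = reach | (reach @ reach)
    return reach


def random_instance(rng, n=30):
    """Two small hierarchies plus a random mapping set over them."""
    o1 = make_ontology("O1", classes=[f"A{i}" for i in range(n // 2)])
    o2 = make_ontology("O2", classes=[f"B{i}" for i in range(n - n // 2)])
    names = sorted(o1.classes) + sorted(o2.classes)
    index_of = {name: i for i, name in enumerate(names)}
    edges = []
    for onto, prefix in ((o1, "A"), (o2, "B")):
        nodes = sorted(onto.classes)
        for i, node in enumerate(nodes[1:], start=1):
            if rng.random() < 0.7:
                parent = nodes[rng.randrange(i)]
                onto.add_subsumption(node, parent)
                edges.append((index_of[node], index_of[parent]))
    mappings = []
    for _ in range(rng.randrange(1, 8)):
        a = f"A{rng.randrange(n // 2)}"
        b = f"B{rng.randrange(n - n // 2)}"
        rel = rng.choice(list(Relation))
        mappings.append(Mapping(a, b, rel))
        if rel is Relation.SUBSUMED_BY:
            edges.append((index_of[a], index_of[b]))
        elif rel is Relation.SUBSUMES:
            edges.append((index_of[b], index_of[a]))
        else:
            edges.append((index_of[a], index_of[b]))
            edges.append((index_of[b], index_of[a]))
    return o1, o2, mappings, names, index_of, edges


class TestSplitEquivalence:
    def test_equivalence_splits_into_both_directions(self):
        split = split_equivalence([Mapping("A", "B", Relation.EQUIVALENT)])
        assert {m.key for m in split} == {("A", "B", "<"), ("A", "B", ">")}

    def test_subsumption_passes_through(self):
        m = Mapping("A", "B", Relation.SUBSUMED_BY)
        assert split_equivalence([m]) == {m}

    def test_size_matches_enumeration_on_random_sets(self):
        rng = random.Random(2)
        for _ in range(50):
            ms = [random_mapping(rng) for _ in range(rng.randrange(0, 12))]
            expected = set()
            for m in ms:
                if m.relation is Relation.EQUIVALENT:
                    expected.add((m.source, m.target, "<"))
                    expected.add((m.source, m.target, ">"))
                else:
                    expected.add(m.key)
            assert {m.key for m in split_equivalence(ms)} == expected


class TestEntails:
    def test_within_ontology_ancestry_with_empty_mapping_set(self):
        o1 = make_ontology("O1", subsumptions=[("a", "b"), ("b", "c")])
        o2 = make_ontology("O2", classes=["x"])
        idx = build_index(o1, o2, [])
        assert idx.entails(Mapping("a", "c", Relation.SUBSUMED_BY))
        assert not idx.entails(Mapping("c", "a", Relation.SUBSUMED_BY))

    def test_cross_ontology_chain(self, chain):
        o1, o2, mapping = chain
        idx = build_index(o1, o2, [mapping])
        assert idx.entails(Mapping("a", "d", Relation.SUBSUMED_BY))
        assert idx.entails(Mapping("b", "c", Relation.EQUIVALENT))
        assert not idx.entails(Mapping("d", "a", Relation.SUBSUMED_BY))

    def test_asserted_mappings_are_entailed(self):
        rng = random.Random(3)
        for _ in range(20):
            o1, o2, mappings, *_ = random_instance(rng)
            idx = build_index(o1, o2, mappings)
            assert all(idx.entails(m) for m in mappings)

    def test_unknown_identifier_is_not_entailed(self, chain):
        o1, o2, mapping = chain
        idx = build_index(o1, o2, [mapping])
        assert not idx.entails(Mapping("nope", "d", Relation.SUBSUMED_BY))

    def test_agrees_with_brute_force_closure(self):
        """All pairs, all three relations, on 200 random 30-node instances."""
        rng = random.Random(42)
        for _ in range(200):
            o1, o2, mappings, names, index_of, edges = random_instance(rng)
            idx = build_index(o1, o2, mappings)
            reach = brute_closure(len(names), edges)
            a_names = sorted(o1.classes)
            b_names = sorted(o2.classes)
            for a, b in itertools.product(a_names, b_names):
                ia, ib = index_of[a], index_of[b]
                assert idx.entails(Mapping(a, b, Relation.SUBSUMED_BY)) == reach[ia, ib]
                assert idx.entails(Mapping(a, b, Relation.SUBSUMES)) == reach[ib, ia]
                assert idx.entails(Mapping(a, b, Relation.EQUIVALENT)) == (reach[ia, ib] and reach[ib, ia])

    def test_monotonicity_adding_mappings_preserves_entailments(self):
        rng = random.Random(9)
        for _ in range(20):
            o1, o2, mappings, names, index_of, edges = random_instance(rng)
            base = mappings[: len(mappings) // 2]
            idx_small = build_index(o1, o2, base)
            idx_big = build_index(o1, o2, mappings)
            probes = [random_mapping(rng, 10) for _ in range(30)]
            for a in sorted(o1.classes)[:10]:
                for b in sorted(o2.classes)[:10]:
                    probes.append(Mapping(a, b, rng.choice(list(Relation))))
            for m in probes:
                if idx_small.entails(m):
                    assert idx_big.entails(m)

    def test_order_independence_of_contraction(self):
        rng = random.Random(4)
        o1, o2, mappings, names, index_of, edges = random_instance(rng)
        idx1 = build_index(o1, o2, mappings)
        idx2 = build_index(o1, o2, list(reversed(mappings)))
        for a in sorted(o1.classes):
            for b in sorted(o2.classes):
                for rel in Relation:
                    m = Mapping(a, b, rel)
                    assert idx1.entails(m) == idx2.entails(m)


class TestCoherence:
    def test_no_disjointness_means_coherent(self, chain):
        o1, o2, mapping = chain
        assert build_index(o1, o2, [mapping]).check_coherence().coherent

    def test_textbook_clash(self):
        o1 = make_ontology("O1", subsumptions=[("A", "B"), ("A", "C")], disjoint=[("B", "C")])
        o2 = make_ontology("O2", classes=["x"])
        rep = build_index(o1, o2, []).check_coherence()
        assert not rep.coherent
        assert rep.unsatisfiable == {"A"}
        assert rep.witnesses["A"] == ("B", "C")

    def test_clash_via_mapping_chain(self):
        o1 = make_ontology("O1", subsumptions=[("A", "B")], disjoint=[("B", "C")], classes=["C"])
        o2 = make_ontology("O2", classes=["X"])
        # A ⊑ B, A ≡ X, X ⊑ C would force A under both B and C
        rep = build_index(
            o1, o2, [Mapping("A", "X", Relation.EQUIVALENT), Mapping("C", "X", Relation.SUBSUMES)]
        ).check_coherence()
        assert "A" in rep.unsatisfiable

    def test_agrees_with_brute_force_on_random_graphs(self):
        rng = random.Random(17)
        for _ in range(50):
            o1, o2, mappings, names, index_of, edges = random_instance(rng, n=20)
            pairs = []
            for _ in range(rng.randrange(0, 4)):
                x, y = rng.sample(names, 2)
                host = o1 if x.startswith("A") else o2
                host.classes.update((x, y))
                host.disjointness.add(frozenset((x, y)))
                pairs.append((x, y))
            idx = build_index(o1, o2, mappings)
            rep = idx.check_coherence()
            reach = brute_closure(len(names), edges)
            # a class is unsatisfiable iff it reaches both members of some
            # disjoint pair (reaching any member of an equivalence component
            # is reaching the component, so plain reachability suffices)
            expected = {
                node
                for i, node in enumerate(names)
                if any(reach[i, index_of[x]] and reach[i, index_of[y]] for x, y in pairs)
            }
            assert rep.unsatisfiable == expected
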