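"""Entailment over the aligned ontology by structural subsumption closure.

The aligned ontology is the merge of the two input hierarchies with an
alignment's mappings asserted as axioms.  Over taxonomies (atomic
subsumption, equivalence, disjointness) the atomic entailments of an OWL 2
reasoner coincide with graph reachability over the merged subsumption
graph after contracting equivalence cycles, which is what this module
computes.  The index is immutable once built; queries are answered from a
per-source memoized reachability cache rather than a full transitive
closure, since evaluations only touch a sparse subset of class pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .mappings import Alignment, Mapping, Relation
from .ontology import Ontology

__all__ = [
    "split_equivalence",
    "EntailmentIndex",
    "build_index",
    "CoherenceReport",
]

log = logging.getLogger(__name__)


def split_equivalence(mappings: Iterable[Mapping]) -> set[Mapping]:
    """Replace each equivalence mapping by its two directed subsumptions.

    ``A ≡ B`` becomes ``A ⊑ B`` and ``A ⊒ B`` (orientation preserved on the
    ontology pair); subsumption mappings pass through unchanged.  The result
    is deduplicated on (source, target, relation).
    """
    out: dict[tuple[str, str, str], Mapping] = {}
    for m in mappings:
        if m.relation is Relation.EQUIVALENT:
            parts = (
                Mapping(m.source, m.target, Relation.SUBSUMED_BY, m.confidence),
                Mapping(m.source, m.target, Relation.SUBSUMES, m.confidence),
            )
        else:
            parts = (m,)
        for p in parts:
            out.setdefault(p.key, p)
    return set(out.values())


@dataclass(frozen=True)
class CoherenceReport:
    """Outcome of the disjointness check over an aligned ontology."""

    coherent: bool
    unsatisfiable: frozenset[str]
    witnesses: dict[str, tuple[str, str]]  # class -> one pair of disjoint ancestors


class EntailmentIndex:
    """Answers "does the aligned ontology entail mapping m?" queries.

    Built once from two ontologies and a mapping set; equivalence axioms,
    bidirectional mapping pairs, and any other subsumption cycles are
    contracted into components (via strongly-connected components of the
    merged graph), after which entailment of ``x ⊑ y`` is reachability of
    ``y``'s component from ``x``'s, and ``x ≡ y`` holds iff the two classes
    share a component.
    """

    def __init__(self, o1: Ontology, o2: Ontology, mappings: Iterable[Mapping]) -> None:
        mappings = list(mappings)
        g = nx.DiGraph()
        g.add_nodes_from(o1.classes)
        g.add_nodes_from(o2.classes)
        for onto in (o1, o2):
            g.add_edges_from(onto.subsumptions)
            for pair in onto.equivalences:
                a, b = sorted(pair)
                g.add_edge(a, b)
                g.add_edge(b, a)
        unknown: set[str] = set()
        for m in mappings:
            for ent in (m.source, m.target):
                if ent not in g:
                    unknown.add(ent)
                    g.add_node(ent)
            if m.relation is Relation.SUBSUMED_BY:
                g.add_edge(m.source, m.target)
            elif m.relation is Relation.SUBSUMES:
                g.add_edge(m.target, m.source)
            else:
                g.add_edge(m.source, m.target)
                g.add_edge(m.target, m.source)
        if unknown:
            log.warning(
                "%d mapped identifiers not present in either ontology (added as isolated nodes)",
                len(unknown),
            )
        cond = nx.condensation(g)
        self._comp_of: dict[str, int] = cond.graph["mapping"]
        self._dag: nx.DiGraph = cond
        self._reach_cache: dict[int, frozenset[int]] = {}
        self._warned_unknown: set[str] = set()
        self._disjoint_pairs: set[frozenset[int]] = set()
        for onto in (o1, o2):
            for pair in onto.disjointness:
                a, b = sorted(pair)
                self._disjoint_pairs.add(frozenset((self._comp_of[a], self._comp_of[b])))
        self.n_classes = g.number_of_nodes()
        self.classes: frozenset[str] = frozenset(g.nodes)

    # -- queries ------------------------------------------------------------

    def _reachable(self, comp: int) -> frozenset[int]:
        cached = self._reach_cache.get(comp)
        if cached is None:
            cached = frozenset(nx.descendants(self._dag, comp)) | {comp}
            self._reach_cache[comp] = cached
        return cached

    def entails_subsumption(self, sub: str, sup: str) -> bool:
        """Does the aligned ontology entail ``sub ⊑ sup``? Reflexive and transitive."""
        if sub not in self._comp_of or sup not in self._comp_of:
            for ent in (sub, sup):
                if ent not in self._comp_of and ent not in self._warned_unknown:
                    self._warned_unknown.add(ent)
                    log.warning("unknown identifier %r queried; treated as not entailed", ent)
            return False
        return self._comp_of[sup] in self._reachable(self._comp_of[sub])

    def entails(self, m: Mapping) -> bool:
        if m.relation is Relation.SUBSUMED_BY:
            return self.entails_subsumption(m.source, m.target)
        if m.relation is Relation.SUBSUMES:
            return self.entails_subsumption(m.target, m.source)
        # equivalence requires both directions, i.e. a shared component
        return (
            m.source in self._comp_of
            and m.target in self._comp_of
            and self._comp_of[m.source] == self._comp_of[m.target]
        )

    def count_entailed(self, mappings: Iterable[Mapping]) -> int:
        return sum(1 for m in mappings if self.entails(m))

    # -- coherence ----------------------------------------------------------

    def check_coherence(self) -> CoherenceReport:
        """Find classes subsumed by both members of a declared disjoint pair.

        With no disjointness axioms every class is satisfiable, which is the
        regime the phenotype/disease track ontologies were in.
        """
        if not self._disjoint_pairs:
            return CoherenceReport(True, frozenset(), {})
        bad: dict[str, tuple[str, str]] = {}
        comp_members: dict[int, list[str]] = {}
        for cls, comp in self._comp_of.items():
            comp_members.setdefault(comp, []).append(cls)
        pair_list = [tuple(sorted(p)) if len(p) == 2 else (next(iter(p)),) * 2
                     for p in self._disjoint_pairs]
        for cls in sorted(self.classes):
            up = self._reachable(self._comp_of[cls])
            for ca, cb in pair_list:
                if ca in up and cb in up:
                    wa = min(comp_members[ca])
                    wb = min(comp_members[cb])
                    bad[cls] = (wa, wb) if wa <= wb else (wb, wa)
                    break
        return CoherenceReport(not bad, frozenset(bad), bad)


def build_index(o1: Ontology, o2: Ontology, mappings: Iterable[Mapping] | Alignment) -> EntailmentIndex:
    """Build the entailment index for the aligned ontology O1 ∪ O2 ∪ M."""
    if isinstance(mappings, Alignment):
        mappings = mappings.mappings
    return EntailmentIndex(o1, o2, mappings)
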