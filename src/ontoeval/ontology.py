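"""Class hierarchies: the ontology container, OBO/edge-list I/O, and metrics.

Only the told taxonomic structure is represented — atomic subsumption
(child, parent) edges, equivalence pairs, and optional disjointness pairs.
This is all the evaluation consumes; richer OWL axioms must be compiled
down to this form before loading.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx
import obonet

__all__ = [
    "Ontology",
    "OntologyMetrics",
    "OntologyError",
    "parse_obo",
    "parse_edgelist",
    "write_edgelist",
    "compute_metrics",
]


class OntologyError(ValueError):
    """Raised for malformed or cyclic ontology inputs."""


def _frozen_pair(a: str, b: str) -> frozenset[str]:
    return frozenset((a, b))


@dataclass
class Ontology:
    """A labeled class hierarchy with told axioms.

    ``subsumptions`` holds ordered (child, parent) pairs; ``equivalences``
    and ``disjointness`` hold unordered pairs.  The hierarchy may be a
    multi-rooted DAG with multiple inheritance, as biomedical ontologies
    usually are.
    """

    ontology_id: str = ""
    classes: set[str] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)
    subsumptions: set[tuple[str, str]] = field(default_factory=set)
    equivalences: set[frozenset[str]] = field(default_factory=set)
    disjointness: set[frozenset[str]] = field(default_factory=set)

    def add_class(self, ident: str, label: str | None = None) -> None:
        self.classes.add(ident)
        if label is not None:
            self.labels[ident] = label

    def add_subsumption(self, child: str, parent: str) -> None:
        if child == parent:
            raise OntologyError(f"self-loop subsumption on {child!r}")
        self.classes.update((child, parent))
        self.subsumptions.add((child, parent))

    def add_equivalence(self, a: str, b: str) -> None:
        self.classes.update((a, b))
        self.equivalences.add(_frozen_pair(a, b))

    def add_disjointness(self, a: str, b: str) -> None:
        if a == b:
            raise OntologyError(f"class {a!r} declared disjoint with itself")
        self.classes.update((a, b))
        self.disjointness.add(_frozen_pair(a, b))

    def graph(self) -> nx.DiGraph:
        """Directed child→parent graph over told subsumptions (classes as nodes)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        g.add_edges_from(self.subsumptions)
        return g

    def validate(self) -> None:
        """Check acyclicity of told subsumption after contracting equivalences."""
        g = self.graph()
        for pair in self.equivalences:
            a, b = sorted(pair)
            g.add_edge(a, b)
            g.add_edge(b, a)
        # equivalence pairs form 2-cycles by construction; any SCC that is
        # held together by a subsumption edge is a genuine hierarchy cycle
        for comp in nx.strongly_connected_components(g):
            sub_edges = [e for e in self.subsumptions if e[0] in comp and e[1] in comp]
            if sub_edges:
                raise OntologyError(
                    f"cycle in told subsumption hierarchy through {sorted(comp)[:6]}"
                )

    def roots(self) -> set[str]:
        has_parent = {c for c, _ in self.subsumptions}
        return self.classes - has_parent


@dataclass(frozen=True)
class OntologyMetrics:
    """Summary statistics mirroring how ontology repositories describe a hierarchy."""

    n_classes: int
    max_depth: int
    avg_children: float  # leaves excluded from the mean


# ---------------------------------------------------------------------------
# OBO flat files (delegated to obonet)
# ---------------------------------------------------------------------------

def parse_obo(document: str | IO[str], ontology_id: str = "") -> Ontology:
    """Load an OBO 1.2/1.4 flat file.

    Non-obsolete ``[Term]`` stanzas become classes; ``is_a`` tags become
    subsumption edges; ``disjoint_from`` tags become disjointness pairs.
    Obsolete terms and their axioms are dropped (obonet does this for us).
    """
    if isinstance(document, str):
        document = io.StringIO(document)
    graph = obonet.read_obo(document, ignore_obsolete=True)
    onto = Ontology(ontology_id=ontology_id or (graph.graph.get("ontology") or ""))
    for node, data in graph.nodes(data=True):
        onto.add_class(node, data.get("name"))
    for node, data in graph.nodes(data=True):
        for parent in data.get("is_a", []):
            if parent in graph:
                onto.add_subsumption(node, parent)
        for other in data.get("disjoint_from", []):
            if other in graph:
                onto.add_disjointness(node, other)
        for eq in data.get("equivalent_to", []):
            if eq in graph:
                onto.add_equivalence(node, eq)
    onto.validate()
    return onto


# ---------------------------------------------------------------------------
# Edge-list TSV
# ---------------------------------------------------------------------------

def parse_edgelist(document: str | IO[str], ontology_id: str = "") -> Ontology:
    """Parse a two/three-column TSV edge list.

    Rows are ``child<TAB>parent`` for subsumption, with an optional third
    column ``equiv`` or ``disjoint`` to assert those axioms instead.
    Single-column rows declare isolated classes.
    """
    if isinstance(document, str):
        document = io.StringIO(document)
    onto = Ontology(ontology_id=ontology_id)
    for lineno, line in enumerate(document, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) == 1:
            onto.add_class(fields[0])
            continue
        if len(fields) not in (2, 3):
            raise OntologyError(f"line {lineno}: expected 1-3 columns, got {len(fields)}")
        a, b = fields[0], fields[1]
        kind = fields[2].lower() if len(fields) == 3 and fields[2] else "is_a"
        if kind in ("is_a", "subclassof"):
            onto.add_subsumption(a, b)
        elif kind.startswith("equiv"):
            onto.add_equivalence(a, b)
        elif kind.startswith("disjoint"):
            onto.add_disjointness(a, b)
        else:
            raise OntologyError(f"line {lineno}: unknown axiom kind {fields[2]!r}")
    try:
        onto.validate()
    except OntologyError:
        raise
    return onto


def write_edgelist(onto: Ontology, stream: IO[str] | None = None) -> str:
    lines = []
    mentioned: set[str] = set()
    for child, parent in sorted(onto.subsumptions):
        lines.append(f"{child}\t{parent}")
        mentioned.update((child, parent))
    for pair in sorted(onto.equivalences, key=sorted):
        a, b = sorted(pair)
        lines.append(f"{a}\t{b}\tequiv")
        mentioned.update((a, b))
    for pair in sorted(onto.disjointness, key=sorted):
        a, b = sorted(pair)
        lines.append(f"{a}\t{b}\tdisjoint")
        mentioned.update((a, b))
    for cls in sorted(onto.classes - mentioned):
        lines.append(cls)
    text = "\n".join(lines) + ("\n" if lines else "")
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(onto: Ontology) -> OntologyMetrics:
    """Class count, maximum depth, and mean number of children over non-leaves.

    Depth counts nodes on the longest leaf→root told-subsumption path, so an
    isolated class sits at depth 1.  The children average excludes leaves,
    matching the convention used by ontology repositories.
    """
    onto.validate()
    g = onto.graph()  # child -> parent
    if not onto.classes:
        return OntologyMetrics(0, 0, 0.0)
    # longest path in the DAG, in edges; +1 converts to node count
    max_depth = (nx.dag_longest_path_length(g) if g.number_of_edges() else 0) + 1
    children_of: dict[str, int] = {}
    for child, parent in onto.subsumptions:
        children_of[parent] = children_of.get(parent, 0) + 1
    avg = (sum(children_of.values()) / len(children_of)) if children_of else 0.0
    return OntologyMetrics(len(onto.classes), max_depth, avg)
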