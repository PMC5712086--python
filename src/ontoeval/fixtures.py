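"""Synthetic ontology pairs, ground-truth alignments, and simulated matchers.

Real evaluation campaigns pair large curated hierarchies (tens of
thousands of classes) with a dozen system submissions; this module emulates
the same shapes at desk scale so every evaluation component can be
exercised without downloading anything.  It generates:

* two multi-rooted DAG hierarchies built root-down, the second a perturbed
  structural mirror of the first so that a ground-truth alignment exists by
  construction;
* a truth alignment that is mostly equivalence with a configurable
  subsumption fraction, mirroring curated mapping sets that contain both;
* per-system alignments hitting configured precision/recall targets, whose
  false mappings are preferentially drawn between *relatives* of true
  matches (siblings, parents) — structured near-misses, which is what makes
  semantic and standard scores diverge on real systems.

All randomness flows from one integer seed through named per-component
streams, so individual pieces are independently reproducible.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field

import networkx as nx

from .mappings import Alignment, Mapping, Relation
from .ontology import Ontology

__all__ = ["FixtureSpec", "Fixture", "gen_ontology_pair", "gen_system_alignment", "gen_fixture"]

# Default system roster shaped like an evaluation campaign: eleven systems
# in seven independent families, two of which submit several variants.
_DEFAULT_SYSTEMS: dict[str, str] = {
    "MatcherA": "MatcherA",
    "MatcherB": "MatcherB",
    "MatcherC": "MatcherC",
    "GraphMap": "GraphMap",
    "GraphMapBio": "GraphMap",
    "GraphMapLt": "GraphMap",
    "PhenoNetF": "PhenoNet",
    "PhenoNetM": "PhenoNet",
    "PhenoNetP": "PhenoNet",
    "LexMatch": "LexMatch",
    "XAlign": "XAlign",
}

_DEFAULT_TARGETS: dict[str, tuple[float, float]] = {
    "MatcherA": (0.95, 0.85),
    "MatcherB": (0.80, 0.60),
    "MatcherC": (0.90, 0.80),
    "GraphMap": (0.95, 0.90),
    "GraphMapBio": (0.93, 0.88),
    "GraphMapLt": (0.97, 0.70),
    "PhenoNetF": (0.85, 0.85),
    "PhenoNetM": (0.85, 0.80),
    "PhenoNetP": (0.80, 0.55),
    "LexMatch": (0.70, 0.40),
    "XAlign": (0.90, 0.75),
}


def _stream(seed: int, name: str) -> random.Random:
    """Independent deterministic RNG stream derived from (seed, name)."""
    return random.Random((seed * 1_000_003 + zlib.crc32(name.encode())) % 2**31)


@dataclass
class FixtureSpec:
    """Knobs for fixture generation; defaults emulate a desk-scale track."""

    n_classes: int = 300
    max_depth: int = 6
    branching: float = 2.0
    n_truth_mappings: int = 80
    equivalence_fraction: float = 0.75
    systems: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TARGETS)
    )
    families: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_SYSTEMS))
    confusability: float = 0.6
    rewire_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.max_depth < 1 or self.n_truth_mappings < 1:
            raise ValueError("counts must be positive")
        for p in (self.equivalence_fraction, self.confusability, self.rewire_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for name, (p, r) in self.systems.items():
            if not (0.0 < p <= 1.0) or not (0.0 < r <= 1.0):
                raise ValueError(f"{name}: precision/recall targets must lie in (0, 1]")
        if self.n_truth_mappings > self.n_classes:
            raise ValueError("more truth mappings requested than classes available")


@dataclass
class Fixture:
    """A complete synthetic evaluation scenario with generation bookkeeping."""

    o1: Ontology
    o2: Ontology
    truth: Alignment
    systems: list[Alignment]
    spec: FixtureSpec
    # system name -> {"true": TP count, "false": FP count}
    bookkeeping: dict[str, dict[str, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Hierarchy generation
# ---------------------------------------------------------------------------

def _level_sizes(n: int, depth: int, branching: float) -> list[int]:
    weights = [max(branching, 1.0) ** k for k in range(depth)]
    total = sum(weights)
    sizes = [max(1, round(n * w / total)) for w in weights]
    # adjust the deepest level so counts sum exactly to n
    while sum(sizes) > n:
        i = max(range(depth), key=lambda k: sizes[k])
        if sizes[i] == 1:
            break
        sizes[i] -= 1
    sizes[-1] += n - sum(sizes)
    if sizes[-1] < 1:
        sizes[-1] = 1
    return sizes


def _gen_dag(n: int, depth: int, branching: float, rng: random.Random, prefix: str) -> tuple[Ontology, list[list[str]]]:
    onto = Ontology(ontology_id=prefix)
    levels: list[list[str]] = []
    idx = 0
    for size in _level_sizes(n, depth, branching):
        levels.append([f"{prefix}:{idx + i:04d}" for i in range(size)])
        idx += size
    for l, nodes in enumerate(levels):
        for node in nodes:
            onto.add_class(node, f"synthetic class {node}")
            if l == 0:
                continue
            onto.add_subsumption(node, rng.choice(levels[l - 1]))
            if l >= 2 and rng.random() < 0.15:  # multiple inheritance
                upper = rng.randrange(l)
                extra = rng.choice(levels[upper])
                if (node, extra) not in onto.subsumptions:
                    onto.add_subsumption(node, extra)
    return onto, levels


def gen_ontology_pair(spec: FixtureSpec) -> tuple[Ontology, Ontology, Alignment]:
    """Generate the hierarchy pair and the ground-truth alignment.

    The second ontology mirrors the first's DAG with fresh identifiers,
    then a fraction of its edges is rewired so the structures are similar
    but not identical.  Truth mappings link structurally corresponding
    nodes: an ``equivalence_fraction`` of them as ≡, the rest as ⊑ from a
    first-ontology node to the counterpart of one of its ancestors.
    """
    rng = _stream(spec.seed, "ontology-pair")
    o1, levels1 = _gen_dag(spec.n_classes, spec.max_depth, spec.branching, rng, "O1")

    # mirror with fresh ids, then rewire a fraction of edges within levels
    counterpart = {}
    o2 = Ontology(ontology_id="O2")
    level_of: dict[str, int] = {}
    for l, nodes in enumerate(levels1):
        for node in nodes:
            twin = node.replace("O1:", "O2:")
            counterpart[node] = twin
            level_of[twin] = l
            o2.add_class(twin, f"synthetic class {twin}")
    levels2 = [[counterpart[n] for n in nodes] for nodes in levels1]
    for child, parent in sorted(o1.subsumptions):
        c2, p2 = counterpart[child], counterpart[parent]
        if rng.random() < spec.rewire_fraction:
            p2 = rng.choice(levels2[max(level_of[c2] - 1, 0)])
            if p2 == c2:
                p2 = counterpart[parent]
        o2.add_subsumption(c2, p2)
    o2.validate()

    g2 = o2.graph()
    truth: list[Mapping] = []
    chosen = rng.sample(sorted(o1.classes), spec.n_truth_mappings)
    for node in chosen:
        twin = counterpart[node]
        if rng.random() < spec.equivalence_fraction:
            truth.append(Mapping(node, twin, Relation.EQUIVALENT))
        else:
            ancestors = sorted(nx.descendants(g2, twin))  # child->parent edges: parents are descendants
            target = rng.choice(ancestors) if ancestors else twin
            truth.append(Mapping(node, target, Relation.SUBSUMED_BY))
    return o1, o2, Alignment(truth, system_name="truth", ontology1_id="O1", ontology2_id="O2")


# ---------------------------------------------------------------------------
# Simulated system alignments
# ---------------------------------------------------------------------------

def _relatives(node: str, g: nx.DiGraph) -> list[str]:
    """Siblings and parents of a node — the lexically plausible near-misses."""
    parents = list(g.successors(node))
    out = set(parents)
    for p in parents:
        out.update(g.predecessors(p))
    out.discard(node)
    return sorted(out)


def gen_system_alignment(
    truth: Alignment,
    precision_target: float,
    recall_target: float,
    seed: int,
    o2: Ontology | None = None,
    confusability: float = 0.6,
    system_name: str = "system",
    family: str | None = None,
) -> tuple[Alignment, dict[str, int]]:
    """Simulate one matcher's output at given precision/recall targets.

    Each truth mapping is recalled independently with probability
    ``recall_target``; false mappings are then added until the true/false
    ratio matches ``precision_target``.  With probability ``confusability``
    a false mapping is a near-miss (a true match's target replaced by one
    of its siblings or parents in the second hierarchy); otherwise it pairs
    the source with a uniformly random second-ontology class.  Returns the
    alignment and the exact true/false bookkeeping counts.
    """
    if not (0.0 < precision_target <= 1.0) or not (0.0 < recall_target <= 1.0):
        raise ValueError("precision and recall targets must lie in (0, 1]")
    rng = random.Random(seed)
    truth_keys = truth.keys()
    truth_pairs = {(s, t) for (s, t, _r) in truth_keys}
    g2 = o2.graph() if o2 is not None else None

    mappings: list[Mapping] = []
    for m in truth.sorted_mappings():
        if rng.random() < recall_target:
            mappings.append(Mapping(m.source, m.target, m.relation, round(rng.uniform(0.7, 1.0), 3)))
    n_true = len(mappings)
    n_false = round(n_true * (1.0 - precision_target) / precision_target)

    used: set[tuple[str, str]] = {(m.source, m.target) for m in mappings}
    all_targets = sorted({m.target for m in truth} | (set(o2.classes) if o2 else set()))
    all_sources = sorted({m.source for m in truth})
    attempts = 0
    added = 0
    while added < n_false and attempts < 50 * max(n_false, 1):
        attempts += 1
        template = truth.sorted_mappings()[rng.randrange(len(truth))]
        if g2 is not None and rng.random() < confusability:
            pool = _relatives(template.target, g2)
            if not pool:
                continue
            cand = (template.source, rng.choice(pool), template.relation)
        else:
            cand = (rng.choice(all_sources), rng.choice(all_targets), template.relation)
        src, tgt, rel = cand
        if src == tgt or (src, tgt) in used or (src, tgt, rel.value) in truth_keys or (src, tgt) in truth_pairs:
            continue
        mappings.append(Mapping(src, tgt, rel, round(rng.uniform(0.3, 0.9), 3)))
        used.add((src, tgt))
        added += 1

    alignment = Alignment(
        mappings,
        system_name=system_name,
        family=family or system_name,
        ontology1_id=truth.ontology1_id,
        ontology2_id=truth.ontology2_id,
    )
    return alignment, {"true": n_true, "false": added}


def gen_fixture(spec: FixtureSpec | None = None, **overrides) -> Fixture:
    """Generate a full scenario: hierarchy pair, truth, and all system alignments."""
    if spec is None:
        spec = FixtureSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a FixtureSpec or keyword overrides, not both")
    o1, o2, truth = gen_ontology_pair(spec)
    systems: list[Alignment] = []
    bookkeeping: dict[str, dict[str, int]] = {}
    for name, (p, r) in spec.systems.items():
        alignment, counts = gen_system_alignment(
            truth,
            p,
            r,
            seed=_stream(spec.seed, f"system:{name}").randrange(2**31),
            o2=o2,
            confusability=spec.confusability,
            system_name=name,
            family=spec.families.get(name, name),
        )
        systems.append(alignment)
        bookkeeping[name] = counts
    return Fixture(o1=o1, o2=o2, truth=truth, systems=systems, spec=spec, bookkeeping=bookkeeping)
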