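import random

import pytest

from ontoeval import Alignment, Mapping, Ontology, Relation


def make_ontology(ontology_id, subsumptions=(), equivalences=(), disjoint=(), classes=()):
    onto = Ontology(ontology_id=ontology_id)
    for c in classes:
        onto.add_class(c)
    for child, parent in subsumptions:
        onto.add_subsumption(child, parent)
    for a, b in equivalences:
        onto.add_equivalence(a, b)
    for a, b in disjoint:
        onto.add_disjointness(a, b)
    return onto


def random_mapping(rng: random.Random, n_entities: int = 20) -> Mapping:
    s = f"A{rng.randrange(n_entities)}"
    t = f"B{rng.randrange(n_entities)}"
    rel = rng.choice(list(Relation))
    return Mapping(s, t, rel, round(rng.uniform(0.01, 1.0), 3))


def random_alignment(rng: random.Random, size: int = 10) -> Alignment:
    return Alignment(
        (random_mapping(rng) for _ in range(size)),
        system_name=f"sys{rng.randrange(100)}",
    )


@pytest.fixture
def chain():
    """a ⊑ b in O1, b ≡ c via mapping, c ⊑ d in O2: the classic cross-ontology chain."""
    o1 = make_ontology("O1", subsumptions=[("a", "b")])
    o2 = make_ontology("O2", subsumptions=[("c", "d")])
    mapping = Mapping("b", "c", Relation.EQUIVALENT)
    return o1, o2, mapping
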