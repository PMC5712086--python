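"""Standard and semantic precision / recall / F-measure.

Standard scores intersect a system alignment with a reference alignment on
exact (source, target, relation) triples:

    P = |M_S ∩ M_RA| / |M_S|,  R = |M_S ∩ M_RA| / |M_RA|,  F = 2PR/(P+R)

Semantic scores replace set membership by entailment: a system mapping is
semantically correct when the reference-aligned ontology entails it, and a
reference mapping is semantically found when the system-aligned ontology
entails it.  Before semantic scoring, equivalence mappings are split into
their two directed subsumptions (both in numerator and denominator, so the
fractions stay in [0, 1]).

Against a highly incomplete but precise baseline only semantic recall is
meaningful; precision and F are reported as not applicable in that mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .entailment import EntailmentIndex, build_index, split_equivalence
from .mappings import Alignment
from .ontology import Ontology

__all__ = [
    "MetricsReport",
    "f_measure",
    "round2",
    "standard_prf",
    "semantic_precision",
    "semantic_recall",
    "evaluate",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals, as evaluation tables conventionally print."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class MetricsReport:
    """One system's scores against one reference."""

    system_name: str
    reference_name: str
    n_mappings: int
    precision: float
    recall: float
    f_measure: float
    semantic: bool = False
    notes: list[str] = field(default_factory=list)

    def rounded(self) -> tuple[float, float, float]:
        return (round2(self.precision), round2(self.f_measure), round2(self.recall))


def standard_prf(system: Alignment, reference: Alignment) -> MetricsReport:
    """Exact-intersection precision, recall and F-measure."""
    notes: list[str] = []
    inter = len(system.keys() & reference.keys())
    if len(system) == 0:
        p = 0.0
        notes.append("precision undefined: empty system alignment")
    else:
        p = inter / len(system)
    if len(reference) == 0:
        raise ValueError("reference alignment is empty; recall undefined")
    r = inter / len(reference)
    return MetricsReport(
        system_name=system.system_name,
        reference_name=reference.system_name,
        n_mappings=len(system),
        precision=p,
        recall=r,
        f_measure=f_measure(p, r),
        semantic=False,
        notes=notes,
    )


def semantic_precision(system: Alignment, ref_index: EntailmentIndex) -> float:
    """Fraction of split system mappings entailed by the reference-aligned ontology."""
    split = split_equivalence(system.mappings)
    if not split:
        return 0.0
    return ref_index.count_entailed(split) / len(split)


def semantic_recall(reference: Alignment, sys_index: EntailmentIndex) -> float:
    """Fraction of split reference mappings entailed by the system-aligned ontology."""
    split = split_equivalence(reference.mappings)
    if not split:
        raise ValueError("reference alignment is empty; semantic recall undefined")
    return sys_index.count_entailed(split) / len(split)


def evaluate(
    system: Alignment,
    reference: Alignment,
    o1: Ontology | None = None,
    o2: Ontology | None = None,
    mode: str = "standard",
) -> MetricsReport:
    """Score ``system`` against ``reference`` in one of three modes.

    ``standard``
        exact-intersection P/R/F; no ontologies needed.
    ``semantic``
        entailment-based P/R over the two aligned ontologies, F over the
        semantic P/R; requires ``o1`` and ``o2``.  Incoherence of either
        aligned ontology is flagged in the notes, never silently repaired.
    ``baseline``
        semantic recall only, for incomplete-but-precise references;
        precision and F are reported as 0 with a not-applicable note.
    """
    if mode == "standard":
        return standard_prf(system, reference)
    if mode not in ("semantic", "baseline"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    if o1 is None or o2 is None:
        raise ValueError(f"mode {mode!r} requires both ontologies")

    notes: list[str] = []
    sys_index = build_index(o1, o2, system)
    sys_coh = sys_index.check_coherence()
    if not sys_coh.coherent:
        notes.append(
            f"INCOHERENT system-aligned ontology: {len(sys_coh.unsatisfiable)} unsatisfiable classes"
        )
    r = semantic_recall(reference, sys_index)

    if mode == "baseline":
        notes.append("baseline reference: only semantic recall is meaningful")
        return MetricsReport(
            system_name=system.system_name,
            reference_name=reference.system_name,
            n_mappings=len(system),
            precision=0.0,
            recall=r,
            f_measure=0.0,
            semantic=True,
            notes=notes,
        )

    ref_index = build_index(o1, o2, reference)
    ref_coh = ref_index.check_coherence()
    if not ref_coh.coherent:
        notes.append(
            f"INCOHERENT reference-aligned ontology: {len(ref_coh.unsatisfiable)} unsatisfiable classes"
        )
    if len(system) == 0:
        notes.append("precision undefined: empty system alignment")
        p = 0.0
    else:
        p = semantic_precision(system, ref_index)
    return MetricsReport(
        system_name=system.system_name,
        reference_name=reference.system_name,
        n_mappings=len(system),
        precision=p,
        recall=r,
        f_measure=f_measure(p, r),
        semantic=True,
        notes=notes,
    )
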