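"""Unique mappings, sampled manual assessment, and contribution statistics.

A system's *unique* mappings are those no other participating system
proposed explicitly and that the vote-2 consensus aligned ontology does not
entail — i.e. the genuinely novel part of its output.  Because novelty says
nothing about correctness, a sample (up to a cap, conventionally 30) is
drawn for manual review; the assessed precision then weights each system's
share of the pooled unique mappings into a positive and a negative
contribution:

    PC_i = |U_i| · P_i / Σ_j |U_j|        (share of correct novel mappings)
    NC_i = |U_i| · (1 − P_i) / Σ_j |U_j|  (share of incorrect novel mappings)

so that Σ_i (PC_i + NC_i) = 1 over any batch.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .entailment import EntailmentIndex
from .mappings import Alignment, Mapping, Relation
from .metrics import round2

__all__ = [
    "UniqueSet",
    "AssessmentRecord",
    "unique_mappings",
    "sample_for_assessment",
    "write_review_sheet",
    "read_verdicts",
    "contributions",
]


@dataclass
class UniqueSet:
    """A system's unique mappings, with a note on how they were selected."""

    system_name: str
    mappings: set[Mapping]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.mappings)


@dataclass
class AssessmentRecord:
    """Assessment outcome and contribution shares for one system."""

    system_name: str
    n_unique: int
    n_sampled: int
    n_correct: int
    precision_est: float
    positive_contribution: float
    negative_contribution: float


def unique_mappings(
    system: Alignment,
    others: Sequence[Alignment],
    consensus2_index: EntailmentIndex | None = None,
    equivalence_only: bool = True,
    family_exclusive: bool = False,
    relation_loose: bool = False,
    families: dict[str, str] | None = None,
) -> UniqueSet:
    """Extract the mappings only this system proposed.

    A mapping is retained iff (a) no other system proposed the same
    (source, target, relation) triple explicitly, and (b) the vote-2
    consensus aligned ontology does not entail it.  By default only
    equivalence mappings are considered, since subsumption-producing
    systems flood the pool otherwise.

    ``family_exclusive`` ignores proposals from systems in the same family
    when testing (a).  ``relation_loose`` lets an ≡ proposal elsewhere block
    a subsumption proposal on the same pair (and vice versa).
    """
    families = families or {}
    my_family = families.get(system.system_name, system.system_name)
    pool = system.restrict(Relation.EQUIVALENT) if equivalence_only else system

    other_keys: set[tuple[str, str, str]] = set()
    other_pairs: set[tuple[str, str]] = set()
    for other in others:
        if other.system_name == system.system_name:
            continue
        if family_exclusive and families.get(other.system_name, other.system_name) == my_family:
            continue
        other_keys |= other.keys()
        other_pairs |= {(s, t) for (s, t, _r) in other.keys()}

    kept: set[Mapping] = set()
    for m in pool:
        if m.key in other_keys:
            continue
        if relation_loose and (m.source, m.target) in other_pairs:
            continue
        if consensus2_index is not None and consensus2_index.entails(m):
            continue
        kept.add(m)
    scope = "equivalence mappings" if equivalence_only else "all mappings"
    return UniqueSet(
        system_name=system.system_name,
        mappings=kept,
        provenance=(
            f"{scope} of {system.system_name} proposed by no other system "
            f"and not entailed by the vote-2 consensus aligned ontology"
        ),
    )


def sample_for_assessment(u: UniqueSet, cap: int = 30, seed: int = 0) -> list[Mapping]:
    """Uniform sample without replacement of up to ``cap`` unique mappings.

    Deterministic for a given seed; when the unique set is not larger than
    the cap, everything is returned (in canonical order).
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    ordered = sorted(u.mappings, key=lambda m: m.key)
    if len(ordered) <= cap:
        return ordered
    rng = random.Random(seed)
    return rng.sample(ordered, cap)


def write_review_sheet(
    sample: Iterable[Mapping],
    labels1: dict[str, str] | None = None,
    labels2: dict[str, str] | None = None,
    stream: IO[str] | None = None,
) -> str:
    """Emit the TSV review sheet a curator fills in (verdict column empty)."""
    labels1 = labels1 or {}
    labels2 = labels2 or {}
    lines = ["source\tsource_label\ttarget\ttarget_label\trelation\tverdict"]
    for m in sample:
        lines.append(
            f"{m.source}\t{labels1.get(m.source, '')}\t{m.target}\t"
            f"{labels2.get(m.target, '')}\t{m.relation.value}\t"
        )
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def read_verdicts(document: str | IO[str]) -> tuple[int, int]:
    """Count (assessed, correct) from a filled review sheet.

    Verdicts are ``correct`` / ``incorrect`` (case-insensitive); blank rows
    are treated as not assessed.
    """
    if hasattr(document, "read"):
        document = document.read()  # type: ignore[union-attr]
    assessed = correct = 0
    for lineno, line in enumerate(str(document).splitlines(), start=1):
        if lineno == 1 or not line.strip():
            continue
        fields = line.split("\t")
        verdict = fields[5].strip().lower() if len(fields) >= 6 else ""
        if not verdict:
            continue
        if verdict not in ("correct", "incorrect"):
            raise ValueError(f"line {lineno}: unknown verdict {verdict!r}")
        assessed += 1
        correct += verdict == "correct"
    return assessed, correct


def contributions(
    records: Sequence[tuple[str, int, float]] | Sequence[tuple[str, int, int, int]],
) -> list[AssessmentRecord]:
    """Positive/negative contribution of each system's unique mappings.

    ``records`` is either ``(system, n_unique, precision_est)`` or
    ``(system, n_unique, n_sampled, n_correct)`` tuples; the pooled total
    Σ|U_j| is the contribution denominator.  A final aggregate row named
    ``Total`` carries the pooled count, the count-weighted mean precision,
    and the summed contributions (which total 1 by construction).
    """
    parsed: list[tuple[str, int, int, int, float]] = []
    for rec in records:
        if len(rec) == 3:
            name, n_unique, prec = rec  # type: ignore[misc]
            n_sampled, n_correct = 0, 0
            p = float(prec)
        else:
            name, n_unique, n_sampled, n_correct = rec  # type: ignore[misc]
            if n_sampled == 0:
                p = 0.0
            else:
                p = n_correct / n_sampled
        if n_unique < 0:
            raise ValueError(f"{name}: negative unique-mapping count")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}: precision estimate {p} outside [0, 1]")
        parsed.append((str(name), int(n_unique), n_sampled, n_correct, p))

    total = sum(n for _, n, _, _, _ in parsed)
    if total == 0:
        raise ValueError("no unique mappings in the batch; contributions undefined")

    out: list[AssessmentRecord] = []
    pc_sum = nc_sum = 0.0
    weighted_p = 0.0
    for name, n_unique, n_sampled, n_correct, p in parsed:
        pc = n_unique * p / total
        nc = n_unique * (1.0 - p) / total
        pc_sum += pc
        nc_sum += nc
        weighted_p += n_unique * p
        out.append(
            AssessmentRecord(
                system_name=name,
                n_unique=n_unique,
                n_sampled=n_sampled,
                n_correct=n_correct,
                precision_est=p,
                positive_contribution=pc,
                negative_contribution=nc,
            )
        )
    out.append(
        AssessmentRecord(
            system_name="Total",
            n_unique=total,
            n_sampled=sum(r.n_sampled for r in out),
            n_correct=sum(r.n_correct for r in out),
            precision_est=weighted_p / total,
            positive_contribution=pc_sum,
            negative_contribution=nc_sum,
        )
    )
    return out


def contribution_table(records: Sequence[AssessmentRecord]) -> str:
    """CSV report: unique count, assessed precision, PC%, NC% per system."""
    lines = ["system,unique_mappings,precision,positive_contrib,negative_contrib"]
    for r in records:
        lines.append(
            f"{r.system_name},{r.n_unique},{round2(r.precision_est):.2f},"
            f"{round2(100 * r.positive_contribution):.2f}%,"
            f"{round2(100 * r.negative_contribution):.2f}%"
        )
    return "\n".join(lines) + "\n"
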