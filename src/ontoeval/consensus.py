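"""Consensus (silver standard) alignments by family-deduplicated voting.

Each entity pair proposed by at least ``min_votes`` independent system
*families* enters the consensus.  Variants of one tool form a family and
together cast a single vote per pair, which keeps prolific tool families
from dominating the silver standard.  When both equivalence and
subsumption proposals meet on a pair, equivalence prevails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mappings import Alignment, Mapping, Relation

__all__ = ["ConsensusSpec", "VoteTable", "build_vote_table", "consensus", "threshold_sweep"]


@dataclass
class ConsensusSpec:
    """Voting configuration: minimum family votes and the system→family map."""

    min_votes: int = 2
    families: dict[str, str] = field(default_factory=dict)
    equivalence_only: bool = False

    def __post_init__(self) -> None:
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")

    def family_of(self, system_name: str) -> str:
        return self.families.get(system_name, system_name)


@dataclass
class _PairVotes:
    """Per-(source, target) ballot: what each family proposed."""

    equiv_families: set[str] = field(default_factory=set)
    # direction -> families proposing that subsumption direction
    sub_families: dict[Relation, set[str]] = field(default_factory=dict)
    conflict_families: set[str] = field(default_factory=set)

    def record(self, family: str, relation: Relation) -> None:
        if relation is Relation.EQUIVALENT:
            self.equiv_families.add(family)
        else:
            self.sub_families.setdefault(relation, set()).add(family)
            # one family proposing both directions amounts to equivalence
            other = Relation.SUBSUMES if relation is Relation.SUBSUMED_BY else Relation.SUBSUMED_BY
            if family in self.sub_families.get(other, set()):
                self.conflict_families.add(family)

    def families(self) -> set[str]:
        out = set(self.equiv_families)
        for fams in self.sub_families.values():
            out |= fams
        return out

    def resolved_equivalent(self) -> bool:
        """Equivalence prevails if any family proposed ≡ (or both directions)."""
        return bool(self.equiv_families or self.conflict_families)


class VoteTable:
    """Family votes aggregated per (source, target) entity pair."""

    def __init__(self, n_families: int) -> None:
        self.n_families = n_families
        self._pairs: dict[tuple[str, str], _PairVotes] = {}

    def record(self, family: str, m: Mapping) -> None:
        self._pairs.setdefault((m.source, m.target), _PairVotes()).record(family, m.relation)

    def pairs(self) -> dict[tuple[str, str], _PairVotes]:
        return self._pairs

    def __len__(self) -> int:
        return len(self._pairs)


def build_vote_table(alignments: list[Alignment], spec: ConsensusSpec) -> VoteTable:
    """Aggregate family votes over the systems' alignments.

    All alignments must concern the same ontology pair in the same
    orientation.  Within a family an equivalence proposal absorbs
    subsumption proposals for the same pair; a family proposing both
    subsumption directions is resolved to equivalence as well.
    """
    pairs = {(a.ontology1_id, a.ontology2_id) for a in alignments if a.ontology1_id or a.ontology2_id}
    if len(pairs) > 1:
        raise ValueError(f"alignments concern different ontology pairs: {sorted(pairs)}")
    families = {spec.family_of(a.system_name) for a in alignments}
    table = VoteTable(n_families=len(families))
    for alignment in alignments:
        family = spec.family_of(alignment.system_name)
        for m in alignment:
            if spec.equivalence_only and m.relation is not Relation.EQUIVALENT:
                continue
            table.record(family, m)
    return table


def consensus(table: VoteTable, min_votes: int) -> Alignment:
    """Mappings whose family-vote count reaches ``min_votes``.

    The consensus relation is ≡ as soon as any voting family proposed ≡
    (equivalence prevails over subsumption); otherwise each proposed
    subsumption direction is kept as its own mapping, with the pair's
    family count deciding inclusion per direction.  Confidence is the vote
    fraction (votes / contributing families).
    """
    if min_votes < 1:
        raise ValueError("min_votes must be >= 1")
    out: list[Mapping] = []
    denom = max(table.n_families, 1)
    for (source, target), votes in table.pairs().items():
        if votes.resolved_equivalent():
            n = len(votes.families())
            if n >= min_votes:
                out.append(Mapping(source, target, Relation.EQUIVALENT, min(n / denom, 1.0)))
        else:
            for direction, fams in votes.sub_families.items():
                if len(fams) >= min_votes:
                    out.append(Mapping(source, target, direction, min(len(fams) / denom, 1.0)))
    return Alignment(out, system_name=f"consensus-v{min_votes}")


def threshold_sweep(table: VoteTable) -> list[tuple[int, int]]:
    """Consensus size at every vote threshold 1..n_families (non-increasing)."""
    return [(v, len(consensus(table, v))) for v in range(1, max(table.n_families, 1) + 1)]
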