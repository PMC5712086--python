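"""Simulated domain expert for interactive matching evaluation.

The oracle holds a reference alignment as ground truth and answers
mapping-validity queries, flipping its answer independently with a
configured error rate.  Like a human expert it answers the same question
the same way every time (first answer cached), while every query — repeated
or not — counts as a request.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .mappings import Alignment, Mapping
from .metrics import MetricsReport

__all__ = ["Oracle", "make_oracle", "gain_report"]


@dataclass
class Oracle:
    """Reference-backed validity oracle with a symmetric error rate."""

    reference: Alignment
    error_rate: float = 0.0
    seed: int = 0
    relation_sensitive: bool = True
    n_requests: int = 0
    transcript: list[tuple[Mapping, bool]] = field(default_factory=list)
    _cache: dict[tuple, bool] = field(default_factory=dict)
    _rng: random.Random = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError(f"error_rate must lie in [0, 1], got {self.error_rate}")
        self._rng = random.Random(self.seed)

    def _query_key(self, m: Mapping) -> tuple:
        return m.key if self.relation_sensitive else (m.source, m.target)

    def _truth(self, m: Mapping) -> bool:
        if self.relation_sensitive:
            return m in self.reference
        return any((m.source, m.target) == (s, t) for (s, t, _r) in self.reference.keys())

    def ask(self, m: Mapping) -> bool:
        """Answer whether ``m`` belongs to the reference; may err, never wavers."""
        self.n_requests += 1
        key = self._query_key(m)
        answer = self._cache.get(key)
        if answer is None:
            answer = self._truth(m)
            if self._rng.random() < self.error_rate:
                answer = not answer
            self._cache[key] = answer
        self.transcript.append((m, answer))
        return answer

    def transcript_tsv(self) -> str:
        lines = ["source\ttarget\trelation\tanswer"]
        for m, ans in self.transcript:
            lines.append(f"{m.source}\t{m.target}\t{m.relation.value}\t{str(ans).lower()}")
        return "\n".join(lines) + "\n"


def make_oracle(reference: Alignment, error_rate: float = 0.0, seed: int = 0) -> Oracle:
    """Initialize an oracle with zero requests; error_rate 0 is a perfect user."""
    return Oracle(reference=reference, error_rate=error_rate, seed=seed)


def gain_report(before: MetricsReport, after: MetricsReport, oracle: Oracle) -> tuple[float, int]:
    """F-measure gain from interaction, and the number of requests it cost."""
    if before.reference_name != after.reference_name:
        raise ValueError("reports were computed against different references")
    return after.f_measure - before.f_measure, oracle.n_requests
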