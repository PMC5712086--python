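"""Mappings, alignments, and readers/writers for the RDF Alignment and TSV formats.

A *mapping* (correspondence) links an entity of a source ontology to an
entity of a target ontology with a relation — subsumption in either
direction or equivalence — and a confidence in ``(0, 1]``.  An *alignment*
is a named set of mappings between one ontology pair, typically the output
of one matching system.

Two mappings are considered equal when they agree on the
``(source, target, relation)`` triple; confidence is carried but never
enters equality or set membership, because two systems proposing the same
correspondence at different confidence agree on the correspondence itself.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator

from lxml import etree

__all__ = [
    "Relation",
    "Mapping",
    "Alignment",
    "normalize_mapping",
    "parse_rdf_alignment",
    "write_rdf_alignment",
    "parse_tsv",
    "write_tsv",
    "AlignmentParseError",
]


class AlignmentParseError(ValueError):
    """Raised when an alignment document cannot be parsed or validated."""


class Relation(enum.Enum):
    """Mapping relation: source ⊑ target, source ⊒ target, or source ≡ target."""

    SUBSUMED_BY = "<"
    SUBSUMES = ">"
    EQUIVALENT = "="

    @classmethod
    def from_symbol(cls, symbol: str) -> "Relation":
        s = symbol.strip()
        aliases = {
            "<": cls.SUBSUMED_BY,
            ">": cls.SUBSUMES,
            "=": cls.EQUIVALENT,
            "subClassOf": cls.SUBSUMED_BY,
            "superClassOf": cls.SUBSUMES,
            "equivalent": cls.EQUIVALENT,
            "&lt;": cls.SUBSUMED_BY,
            "&gt;": cls.SUBSUMES,
        }
        if s not in aliases:
            raise AlignmentParseError(f"unknown relation symbol {symbol!r}")
        return aliases[s]


@dataclass(frozen=True)
class Mapping:
    """One correspondence between an entity of ontology 1 and one of ontology 2.

    ``source`` always lives in the first ontology of the pair and ``target``
    in the second; direction of subsumption is carried by ``relation``, so
    cross-ontology orientation is never swapped.
    """

    source: str
    target: str
    relation: Relation = Relation.EQUIVALENT
    confidence: float = field(default=1.0, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", self.source.strip())
        object.__setattr__(self, "target", self.target.strip())
        if not self.source or not self.target:
            raise ValueError("mapping entities must be non-empty identifiers")
        if self.source == self.target:
            raise ValueError(f"mapping must link distinct entities, got {self.source!r} twice")
        if not (0.0 < self.confidence <= 1.0):
            raise ValueError(
                f"confidence must lie in (0, 1], got {self.confidence!r} "
                f"for {self.source} {self.relation.value} {self.target}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity triple used for set semantics (confidence excluded)."""
        return (self.source, self.target, self.relation.value)

    def converse(self) -> "Mapping":
        """The same correspondence read from the other ontology's side."""
        conv = {
            Relation.SUBSUMED_BY: Relation.SUBSUMES,
            Relation.SUBSUMES: Relation.SUBSUMED_BY,
            Relation.EQUIVALENT: Relation.EQUIVALENT,
        }
        return Mapping(self.target, self.source, conv[self.relation], self.confidence)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.source} {self.relation.value} {self.target} ({self.confidence:g})"


def normalize_mapping(m: Mapping) -> Mapping:
    """Return the canonical form of ``m``.

    Canonicalization preserves cross-ontology orientation (source stays in
    ontology 1) and therefore never swaps entities; it trims identifier
    whitespace (done in the constructor) and is idempotent.  Subsumption
    direction is kept on the relation itself.
    """
    return replace(m)


def _sort_key(m: Mapping) -> tuple[str, str, str]:
    return m.key


class Alignment:
    """A named set of mappings between one ontology pair.

    Mappings are stored with set semantics on ``(source, target, relation)``:
    duplicates collapse, and the first confidence seen for a triple wins.
    """

    def __init__(
        self,
        mappings: Iterable[Mapping] = (),
        system_name: str = "unnamed",
        family: str | None = None,
        ontology1_id: str = "",
        ontology2_id: str = "",
    ) -> None:
        self.system_name = system_name
        self.family = family if family is not None else system_name
        self.ontology1_id = ontology1_id
        self.ontology2_id = ontology2_id
        self._mappings: dict[tuple[str, str, str], Mapping] = {}
        for m in mappings:
            self.add(m)

    def add(self, m: Mapping) -> None:
        self._mappings.setdefault(normalize_mapping(m).key, m)

    @property
    def mappings(self) -> set[Mapping]:
        return set(self._mappings.values())

    def sorted_mappings(self) -> list[Mapping]:
        return sorted(self._mappings.values(), key=_sort_key)

    def __len__(self) -> int:
        return len(self._mappings)

    def __iter__(self) -> Iterator[Mapping]:
        return iter(self.sorted_mappings())

    def __contains__(self, m: Mapping) -> bool:
        return m.key in self._mappings

    def keys(self) -> set[tuple[str, str, str]]:
        return set(self._mappings)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.keys() == other.keys()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.system_name!r}, {len(self)} mappings)"

    def restrict(self, relation: Relation) -> "Alignment":
        """Sub-alignment containing only mappings with the given relation."""
        return Alignment(
            (m for m in self if m.relation is relation),
            system_name=self.system_name,
            family=self.family,
            ontology1_id=self.ontology1_id,
            ontology2_id=self.ontology2_id,
        )


# ---------------------------------------------------------------------------
# RDF Alignment format (INRIA Alignment API XML)
# ---------------------------------------------------------------------------

_ALIGN_NS = "http://knowledgeweb.semanticweb.org/heterogeneity/alignment"
_RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
_XSD = "http://www.w3.org/2001/XMLSchema#float"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def parse_rdf_alignment(document: str | bytes | IO) -> Alignment:
    """Parse an RDF Alignment XML document into an :class:`Alignment`.

    One mapping is produced per ``Cell``; relation symbols ``=``, ``<`` and
    ``>`` map to equivalence and the two subsumption directions, ``measure``
    becomes the confidence, and duplicate cells collapse.
    """
    if isinstance(document, str):
        data = document.encode("utf-8")
    elif isinstance(document, bytes):
        data = document
    else:
        raw = document.read()
        data = raw.encode("utf-8") if isinstance(raw, str) else raw
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise AlignmentParseError(
            f"malformed RDF Alignment XML at line {exc.lineno}, column {exc.position[1]}: {exc.msg}"
        ) from exc

    onto = {"onto1": "", "onto2": ""}
    mappings: list[Mapping] = []
    for cell in root.iter():
        name = _localname(cell.tag)
        if name in ("onto1", "onto2"):
            ref = cell.find(f"{{{_ALIGN_NS}}}Ontology")
            if ref is not None:
                onto[name] = ref.get(f"{{{_RDF_NS}}}about", "") or ""
            elif cell.text and cell.text.strip():
                onto[name] = cell.text.strip()
        if name != "Cell":
            continue
        entity1 = entity2 = relation = measure = None
        for child in cell:
            cname = _localname(child.tag)
            if cname == "entity1":
                entity1 = child.get(f"{{{_RDF_NS}}}resource") or (child.text or "").strip()
            elif cname == "entity2":
                entity2 = child.get(f"{{{_RDF_NS}}}resource") or (child.text or "").strip()
            elif cname == "relation":
                relation = (child.text or "").strip()
            elif cname == "measure":
                measure = (child.text or "").strip()
        if not entity1 or not entity2:
            raise AlignmentParseError(
                f"Cell at line {cell.sourceline} is missing entity1 or entity2"
            )
        try:
            rel = Relation.from_symbol(relation if relation else "=")
        except AlignmentParseError as exc:
            raise AlignmentParseError(
                f"Cell at line {cell.sourceline} ({entity1}, {entity2}): {exc}"
            ) from exc
        conf = float(measure) if measure not in (None, "") else 1.0
        try:
            mappings.append(Mapping(entity1, entity2, rel, conf))
        except ValueError as exc:
            raise AlignmentParseError(f"Cell at line {cell.sourceline}: {exc}") from exc
    return Alignment(mappings, ontology1_id=onto["onto1"], ontology2_id=onto["onto2"])


def write_rdf_alignment(alignment: Alignment, stream: IO[str] | None = None) -> str:
    """Serialize an alignment to RDF Alignment XML with deterministic cell order."""
    nsmap = {None: _ALIGN_NS, "rdf": _RDF_NS}
    root = etree.Element(f"{{{_RDF_NS}}}RDF", nsmap=nsmap)
    al = etree.SubElement(root, f"{{{_ALIGN_NS}}}Alignment")
    etree.SubElement(al, f"{{{_ALIGN_NS}}}xml").text = "yes"
    etree.SubElement(al, f"{{{_ALIGN_NS}}}level").text = "0"
    etree.SubElement(al, f"{{{_ALIGN_NS}}}type").text = "??"
    for tag, value in (("onto1", alignment.ontology1_id), ("onto2", alignment.ontology2_id)):
        el = etree.SubElement(al, f"{{{_ALIGN_NS}}}{tag}")
        if value:
            onto = etree.SubElement(el, f"{{{_ALIGN_NS}}}Ontology")
            onto.set(f"{{{_RDF_NS}}}about", value)
    for m in alignment.sorted_mappings():
        map_el = etree.SubElement(al, f"{{{_ALIGN_NS}}}map")
        cell = etree.SubElement(map_el, f"{{{_ALIGN_NS}}}Cell")
        etree.SubElement(cell, f"{{{_ALIGN_NS}}}entity1").set(f"{{{_RDF_NS}}}resource", m.source)
        etree.SubElement(cell, f"{{{_ALIGN_NS}}}entity2").set(f"{{{_RDF_NS}}}resource", m.target)
        meas = etree.SubElement(cell, f"{{{_ALIGN_NS}}}measure")
        meas.set(f"{{{_RDF_NS}}}datatype", _XSD)
        meas.text = repr(m.confidence)
        etree.SubElement(cell, f"{{{_ALIGN_NS}}}relation").text = m.relation.value
    text = etree.tostring(root, xml_declaration=True, encoding="utf-8", pretty_print=True).decode(
        "utf-8"
    )
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def parse_tsv(document: str | IO[str]) -> Alignment:
    """Parse the tab-separated alignment dialect.

    Columns: source, target, relation (``<``/``>``/``=`` or the word forms),
    confidence (optional, default 1.0).  A header row is auto-detected,
    ``#`` comment lines and blank lines are ignored, and a bare two-column
    row defaults to an equivalence at confidence 1.0.
    """
    if isinstance(document, str):
        document = io.StringIO(document)
    mappings: list[Mapping] = []
    for lineno, line in enumerate(document, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and _looks_like_header(fields):
            continue
        if len(fields) < 2 or len(fields) > 4:
            raise AlignmentParseError(
                f"line {lineno}: expected 2-4 tab-separated columns, got {len(fields)}"
            )
        source, target = fields[0], fields[1]
        rel = Relation.from_symbol(fields[2]) if len(fields) >= 3 and fields[2].strip() else Relation.EQUIVALENT
        try:
            conf = float(fields[3]) if len(fields) == 4 and fields[3].strip() else 1.0
        except ValueError as exc:
            raise AlignmentParseError(f"line {lineno}: bad confidence {fields[3]!r}") from exc
        try:
            mappings.append(Mapping(source, target, rel, conf))
        except ValueError as exc:
            raise AlignmentParseError(f"line {lineno}: {exc}") from exc
    return Alignment(mappings)


def _looks_like_header(fields: list[str]) -> bool:
    lowered = [f.strip().lower() for f in fields[:2]]
    return lowered[:1] == ["source"] or lowered == ["entity1", "entity2"]


def write_tsv(alignment: Alignment, stream: IO[str] | None = None, header: bool = True) -> str:
    lines = []
    if header:
        lines.append("source\ttarget\trelation\tconfidence")
    for m in alignment.sorted_mappings():
        lines.append(f"{m.source}\t{m.target}\t{m.relation.value}\t{m.confidence:g}")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text
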