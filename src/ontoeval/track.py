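"""End-to-end track evaluation: config, pipeline, and report bundle.

`run_track` executes the full evaluation a campaign organiser would run:
load the ontology pair and every system's alignment, build consensus
alignments at each vote threshold, check coherence of every aligned
ontology, score each system (semantic P/R/F against each consensus,
semantic recall against the baseline and any curated set), extract unique
mappings against the vote-2 consensus, emit review sheets, and — when
filled review sheets are supplied — the contribution report.  Outputs are
plain CSV/TSV plus a JSON manifest with input hashes; a fixed seed makes
the whole bundle byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .consensus import ConsensusSpec, build_vote_table, consensus as build_consensus, threshold_sweep
from .entailment import build_index
from .mappings import Alignment, parse_rdf_alignment, parse_tsv, write_rdf_alignment, write_tsv
from .metrics import evaluate, round2, standard_prf
from .ontology import Ontology, parse_edgelist, parse_obo
from .unique import contribution_table, contributions, sample_for_assessment, unique_mappings, write_review_sheet

__all__ = ["TrackConfig", "load_config", "run_track", "load_ontology", "load_alignment"]


@dataclass
class TrackConfig:
    """Declarative description of one evaluation run."""

    ontology1: Path
    ontology2: Path
    systems: list[tuple[str, str, Path]]  # (name, family, path)
    output_dir: Path
    baseline: Path | None = None
    curated: Path | None = None
    verdicts: dict[str, Path] = field(default_factory=dict)  # system -> filled review sheet
    vote_thresholds: tuple[int, ...] = (2, 3)
    assessment_cap: int = 30
    equivalence_only_consensus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.systems:
            raise ValueError("at least one system alignment is required")
        if any(v < 1 for v in self.vote_thresholds):
            raise ValueError("vote thresholds must be >= 1")
        if self.assessment_cap < 1:
            raise ValueError("assessment cap must be >= 1")


def load_config(path: str | Path) -> TrackConfig:
    """Read the YAML run description."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    base = path.parent

    def resolve(p: str | None) -> Path | None:
        return (base / p) if p else None

    systems = [
        (s["name"], s.get("family", s["name"]), base / s["path"])
        for s in data.get("systems", [])
    ]
    return TrackConfig(
        ontology1=base / data["ontology1"],
        ontology2=base / data["ontology2"],
        systems=systems,
        output_dir=base / data.get("output_dir", "ontoeval-out"),
        baseline=resolve(data.get("baseline")),
        curated=resolve(data.get("curated")),
        verdicts={k: base / v for k, v in (data.get("verdicts") or {}).items()},
        vote_thresholds=tuple(data.get("vote_thresholds", [2, 3])),
        assessment_cap=int(data.get("assessment_cap", 30)),
        equivalence_only_consensus=bool(data.get("equivalence_only_consensus", False)),
        seed=int(data.get("seed", 0)),
    )


def load_ontology(path: str | Path, ontology_id: str = "") -> Ontology:
    """Dispatch on extension: ``.obo`` flat files, anything else edge-list TSV."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".obo":
        return parse_obo(text, ontology_id=ontology_id or path.stem)
    return parse_edgelist(text, ontology_id=ontology_id or path.stem)


def load_alignment(path: str | Path, system_name: str = "", family: str = "") -> Alignment:
    """Dispatch on extension: ``.rdf``/``.xml`` RDF Alignment, else TSV."""
    path = Path(path)
    if path.suffix.lower() in (".rdf", ".xml"):
        alignment = parse_rdf_alignment(path.read_text())
    else:
        alignment = parse_tsv(path.read_text())
    if system_name:
        alignment.system_name = system_name
        alignment.family = family or system_name
    return alignment


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt(x: float) -> str:
    return f"{round2(x):.2f}"


def run_track(config: TrackConfig) -> dict:
    """Execute the evaluation pipeline; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "inputs": {}, "outputs": [], "stages": []}

    def stage(name: str, **info) -> None:
        manifest["stages"].append({"stage": name, **info})

    def emit(name: str, text: str) -> None:
        (out / name).write_text(text)
        manifest["outputs"].append(name)

    # -- load ---------------------------------------------------------------
    o1 = load_ontology(config.ontology1, "O1")
    o2 = load_ontology(config.ontology2, "O2")
    manifest["inputs"][str(config.ontology1)] = _sha256(config.ontology1)
    manifest["inputs"][str(config.ontology2)] = _sha256(config.ontology2)
    systems: list[Alignment] = []
    families: dict[str, str] = {}
    for name, family, path in config.systems:
        alignment = load_alignment(path, system_name=name, family=family)
        systems.append(alignment)
        families[name] = family
        manifest["inputs"][str(path)] = _sha256(path)
    stage("load", n_systems=len(systems), o1_classes=len(o1.classes), o2_classes=len(o2.classes))

    # -- consensus ----------------------------------------------------------
    spec = ConsensusSpec(
        min_votes=min(config.vote_thresholds),
        families=families,
        equivalence_only=config.equivalence_only_consensus,
    )
    table = build_vote_table(systems, spec)
    sweep = threshold_sweep(table)
    emit("consensus_sweep.csv", "vote,n_mappings\n" + "\n".join(f"{v},{n}" for v, n in sweep) + "\n")
    consensuses: dict[int, Alignment] = {}
    for v in sorted(set(config.vote_thresholds)):
        c = build_consensus(table, v)
        consensuses[v] = c
        emit(f"consensus_v{v}.rdf", write_rdf_alignment(c))
        emit(f"consensus_v{v}.tsv", write_tsv(c))
    stage("consensus", sizes={v: len(c) for v, c in consensuses.items()})

    # -- coherence ----------------------------------------------------------
    coherence_rows = []
    indexes: dict[str, object] = {}
    for alignment in list(consensuses.values()) + systems:
        idx = build_index(o1, o2, alignment)
        indexes[alignment.system_name] = idx
        rep = idx.check_coherence()
        coherence_rows.append(f"{alignment.system_name},{str(rep.coherent).lower()},{len(rep.unsatisfiable)}")
    emit("coherence.csv", "alignment,coherent,n_unsatisfiable\n" + "\n".join(coherence_rows) + "\n")
    stage("coherence", checked=len(coherence_rows))

    # -- semantic P/R/F against each consensus ------------------------------
    header = ["system", "mappings"]
    for v in sorted(consensuses):
        header += [f"precision_{v}", f"f_measure_{v}", f"recall_{v}"]
    header.append("notes")
    rows = []
    for system in systems:
        cells = [system.system_name, str(len(system))]
        notes: list[str] = []
        for v in sorted(consensuses):
            rep = evaluate(system, consensuses[v], o1, o2, mode="semantic")
            p, f, r = rep.rounded()
            cells += [_fmt(p), _fmt(f), _fmt(r)]
            notes += [n for n in rep.notes if n not in notes]
        cells.append("; ".join(notes))
        rows.append(",".join(cells))
    emit("results_vs_consensus.csv", ",".join(header) + "\n" + "\n".join(rows) + "\n")
    stage("semantic_vs_consensus", n_rows=len(rows))

    # -- baseline recall ----------------------------------------------------
    if config.baseline is not None:
        baseline = load_alignment(config.baseline, system_name="baseline")
        manifest["inputs"][str(config.baseline)] = _sha256(config.baseline)
        rows = []
        for system in systems:
            rep = evaluate(system, baseline, o1, o2, mode="baseline")
            rows.append(f"{system.system_name},{_fmt(rep.recall)}")
        emit("recall_vs_baseline.csv", "system,semantic_recall\n" + "\n".join(rows) + "\n")
        stage("baseline", n_rows=len(rows))

    # -- curated recall ------------------------------------------------------
    if config.curated is not None:
        curated = load_alignment(config.curated, system_name="curated")
        manifest["inputs"][str(config.curated)] = _sha256(config.curated)
        rows = []
        scored = systems + list(consensuses.values())
        for alignment in scored:
            std = standard_prf(alignment, curated) if len(alignment) else None
            sem = evaluate(alignment, curated, o1, o2, mode="baseline")
            std_r = _fmt(std.recall) if std else "-"
            rows.append(f"{alignment.system_name},{std_r},{_fmt(sem.recall)}")
        emit("recall_vs_curated.csv", "system,standard_recall,semantic_recall\n" + "\n".join(rows) + "\n")
        stage("curated", n_rows=len(rows))

    # -- unique mappings and assessment --------------------------------------
    v2 = min(consensuses)
    c2_index = build_index(o1, o2, consensuses[v2])
    unique_rows = []
    assessment_inputs = []
    for system in systems:
        u = unique_mappings(system, [s for s in systems if s is not system], c2_index, families=families)
        unique_rows.append(f"{system.system_name},{len(u)}")
        sample = sample_for_assessment(u, cap=config.assessment_cap, seed=config.seed) if len(u) else []
        emit(
            f"review_{system.system_name}.tsv",
            write_review_sheet(sample, o1.labels, o2.labels),
        )
        verdict_path = config.verdicts.get(system.system_name)
        if verdict_path is not None:
            from .unique import read_verdicts

            n_sampled, n_correct = read_verdicts(verdict_path.read_text())
            manifest["inputs"][str(verdict_path)] = _sha256(verdict_path)
            assessment_inputs.append((system.system_name, len(u), n_sampled, n_correct))
    emit("unique_counts.csv", "system,n_unique\n" + "\n".join(unique_rows) + "\n")
    stage("unique", n_systems=len(unique_rows))

    if assessment_inputs and any(n for _, n, _, _ in assessment_inputs):
        records = contributions(assessment_inputs)
        emit("contributions.csv", contribution_table(records))
        stage("contributions", n_rows=len(records))

    manifest_text = json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    (out / "manifest.json").write_text(manifest_text)
    return manifest
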