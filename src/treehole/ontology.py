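"""The Tree Hole knowledge graph: four ontologies and subclass reasoning.

The graph holds four independent ontologies — ``suicide`` (methods and
plans), ``time`` (absolute and relative time), ``space`` (locations), and
``wish`` (subjective suicidal wishes).  Each concept carries surface forms,
the lexical variants matched in comment text; the rule engine only asks two
questions of the graph: "is concept X a subclass of root Y?" and "which
spans of this text mention a concept under root Y?".

Reasoning is deliberately limited to reflexive-transitive subclass
reachability; there is no OWL/RDF machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

ONTOLOGY_NAMES = ("suicide", "time", "space", "wish")


class OntologyError(ValueError):
    """Raised for malformed, cyclic or dangling ontology definitions."""


@dataclass(frozen=True)
class Concept:
    """A node in one ontology.

    ``surface_forms`` are the strings matched (case-insensitively) in
    preprocessed text; internal nodes may have none.
    """

    id: str
    label: str
    surface_forms: tuple[str, ...]
    parent_ids: tuple[str, ...]
    ontology: str


@dataclass(frozen=True)
class Mention:
    """A surface-form match in a text.

    ``span`` is a 0-based half-open character interval; ``matched_root`` is
    the designated root the query was made against (e.g. ``suicidePlan``).
    ``negated`` is filled in later by the rule engine's negation detector.
    """

    concept_id: str
    matched_root: str
    ontology: str
    span: tuple[int, int]
    surface: str
    negated: bool = False


@dataclass
class KnowledgeGraph:
    """Four ontologies plus their designated root concepts."""

    ontologies: dict[str, dict[str, Concept]]
    roots: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in ONTOLOGY_NAMES if n not in self.ontologies]
        extra = [n for n in self.ontologies if n not in ONTOLOGY_NAMES]
        if missing or extra:
            raise OntologyError(
                f"graph must contain exactly the four ontologies {ONTOLOGY_NAMES}; "
                f"missing={missing} unexpected={extra}"
            )
        for name, concepts in self.ontologies.items():
            for cid, concept in concepts.items():
                for pid in concept.parent_ids:
                    if pid not in concepts:
                        raise OntologyError(
                            f"concept {cid!r} in ontology {name!r} has dangling parent {pid!r}"
                        )
            cycle = _find_cycle(concepts)
            if cycle:
                raise OntologyError(
                    f"ontology {name!r} parent relation is cyclic: {' -> '.join(cycle)}"
                )
        for name, root_ids in self.roots.items():
            for rid in root_ids:
                if rid not in self.ontologies.get(name, {}):
                    raise OntologyError(f"designated root {rid!r} missing from ontology {name!r}")

    def concept(self, concept_id: str, ontology: str) -> Concept:
        try:
            return self.ontologies[ontology][concept_id]
        except KeyError:
            raise OntologyError(f"unknown concept {concept_id!r} in ontology {ontology!r}") from None

    def iter_concepts(self, ontology: str) -> Iterator[Concept]:
        yield from self.ontologies[ontology].values()


def _find_cycle(concepts: dict[str, Concept]) -> list[str] | None:
    """Iterative DFS over parent links; returns one cycle if any."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = {cid: WHITE for cid in concepts}
    for start in concepts:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, Iterator[str]]] = [(start, iter(concepts[start].parent_ids))]
        color[start] = GREY
        while stack:
            node, parents = stack[-1]
            advanced = False
            for pid in parents:
                if color[pid] == GREY:
                    path = [n for n, _ in stack]
                    return path[path.index(pid):] + [pid] if pid in path else [node, pid, node]
                if color[pid] == WHITE:
                    color[pid] = GREY
                    stack.append((pid, iter(concepts[pid].parent_ids)))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return None


def is_subclass_of(graph: KnowledgeGraph, concept_id: str, ancestor_id: str, ontology: str) -> bool:
    """Reflexive-transitive reachability of ``ancestor_id`` via parent links."""
    graph.concept(ancestor_id, ontology)  # existence check
    seen: set[str] = set()
    frontier = [concept_id]
    while frontier:
        cid = frontier.pop()
        if cid == ancestor_id:
            return True
        if cid in seen:
            continue
        seen.add(cid)
        frontier.extend(graph.concept(cid, ontology).parent_ids)
    return False


def find_mentions(
    text: str, ancestor_id: str, ontology: str, graph: KnowledgeGraph
) -> list[Mention]:
    """All maximal, case-insensitive surface-form matches under one root.

    Overlapping shorter matches are suppressed (longest-match-wins, earlier
    start breaks ties); spans are 0-based half-open offsets into ``text``.
    """
    lowered = text.lower()
    candidates: list[tuple[int, int, str, str]] = []
    for concept in graph.iter_concepts(ontology):
        if not concept.surface_forms:
            continue
        if not is_subclass_of(graph, concept.id, ancestor_id, ontology):
            continue
        for form in concept.surface_forms:
            needle = form.lower()
            start = lowered.find(needle)
            while start != -1:
                candidates.append((start, start + len(needle), concept.id, form))
                start = lowered.find(needle, start + 1)
    # longest-match-wins: accept by decreasing length, then position
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    accepted: list[tuple[int, int, str, str]] = []
    for cand in candidates:
        if all(cand[1] <= a[0] or cand[0] >= a[1] for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: c[0])
    return [
        Mention(concept_id=cid, matched_root=ancestor_id, ontology=ontology,
                span=(s, e), surface=text[s:e])
        for s, e, cid, _ in accepted
    ]


def _parse_concept(raw: dict, ontology: str) -> Concept:
    try:
        return Concept(
            id=raw["id"],
            label=raw.get("label", raw["id"]),
            surface_forms=tuple(raw.get("surface_forms", ())),
            parent_ids=tuple(raw.get("parents", ())),
            ontology=ontology,
        )
    except (KeyError, TypeError) as exc:
        raise OntologyError(f"malformed concept record {raw!r}: {exc}") from exc


def load_graph(path: str | Path) -> KnowledgeGraph:
    """Load a knowledge graph from the documented JSON schema.

    Schema: ``{"ontologies": [{"ontology": name, "roots": [...],
    "concepts": [{"id", "label", "surface_forms", "parents"}]}]}``.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise OntologyError(f"cannot parse {path}: {exc}") from exc
    ontologies: dict[str, dict[str, Concept]] = {}
    roots: dict[str, tuple[str, ...]] = {}
    for block in doc.get("ontologies", []):
        name = block.get("ontology")
        concepts: dict[str, Concept] = {}
        for raw in block.get("concepts", []):
            concept = _parse_concept(raw, name)
            if concept.id in concepts:
                raise OntologyError(f"duplicate concept id {concept.id!r} in ontology {name!r}")
            concepts[concept.id] = concept
        ontologies[name] = concepts
        roots[name] = tuple(block.get("roots", ()))
    return KnowledgeGraph(ontologies=ontologies, roots=roots)


def save_graph(graph: KnowledgeGraph, path: str | Path) -> None:
    doc = {
        "ontologies": [
            {
                "ontology": name,
                "roots": list(graph.roots.get(name, ())),
                "concepts": [
                    {
                        "id": c.id,
                        "label": c.label,
                        "surface_forms": list(c.surface_forms),
                        "parents": list(c.parent_ids),
                    }
                    for c in graph.ontologies[name].values()
                ],
            }
            for name in ONTOLOGY_NAMES
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=2, sort_keys=True)
        fh.write("\n")


def default_graph_path() -> Path:
    """Path of the bundled (synthetic surface form) fixture graph."""
    return Path(str(resources.files("treehole").joinpath("data/graph.json")))


def load_default_graph() -> KnowledgeGraph:
    return load_graph(default_graph_path())
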