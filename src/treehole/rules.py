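"""Distant-supervision rule engine: slot-sequence rules over graph mentions.

Each rule is an ordered alternation of ``free_text`` and ``concept`` slots,
mirroring logic-program clauses of the form::

    statement(suicideRisk(8, [Plan, Time])) -->
        uninterestedText(_L1),
        rdfsSubclassOf(Plan, suicidePlan, suicideOntology),
        uninterestedText(_L2),
        rdfsSubclassOf(Time, future, timeOntology),
        uninterestedText(_L3).

A rule matches a comment when its concept slots can be bound, in order, to
non-overlapping, non-negated mentions whose concepts fall under the slot's
designated root.  Free-text slots absorb arbitrary (possibly empty) gaps.
The comment's risk level is the maximum level over all matching rules, 0
when none match; level >= 6 binarizes to "high".
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .ontology import KnowledgeGraph, Mention, find_mentions
from .preprocess import CommentRecord

logger = logging.getLogger(__name__)

HIGH_RISK_THRESHOLD = 6  # level >= 6 is "high risk"


@dataclass(frozen=True)
class RuleSlot:
    kind: str  # "concept" | "free_text"
    root_id: str | None = None
    ontology: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("concept", "free_text"):
            raise ValueError(f"unknown slot kind {self.kind!r}")
        if self.kind == "concept" and (self.root_id is None or self.ontology is None):
            raise ValueError("concept slot needs root_id and ontology")


@dataclass(frozen=True)
class Rule:
    rule_id: str
    level: int
    slots: tuple[RuleSlot, ...]
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 10:
            raise ValueError(f"rule level {self.level} outside 1..10")
        concept_slots = self.concept_slots()
        if not concept_slots:
            raise ValueError(f"rule {self.rule_id!r} has no concept slot")
        # no two concept slots adjacent: a free_text slot must separate them
        kinds = [s.kind for s in self.slots]
        for a, b in zip(kinds, kinds[1:]):
            if a == b == "concept":
                raise ValueError(f"rule {self.rule_id!r} has adjacent concept slots")

    def concept_slots(self) -> tuple[RuleSlot, ...]:
        return tuple(s for s in self.slots if s.kind == "concept")


@dataclass(frozen=True)
class RuleMatch:
    rule_id: str
    level: int
    mentions: tuple[Mention, ...]


@dataclass(frozen=True)
class RiskAssessment:
    comment_id: str
    level: int
    binary: str  # "high" | "low"
    matches: tuple[RuleMatch, ...] = ()

    def __post_init__(self) -> None:
        if self.binary != ("high" if self.level >= HIGH_RISK_THRESHOLD else "low"):
            raise ValueError("binary label inconsistent with level")
        if self.level == 0 and self.matches:
            raise ValueError("level 0 must have no matches")


@dataclass(frozen=True)
class NegationConfig:
    cues: tuple[str, ...] = ("not", "never", "wont", "won't", "refuse", "quit", "gave up")
    window: int = 8
    clause_boundaries: str = ",.;:!?、，。；：！？"

    @classmethod
    def from_file(cls, path: str | Path) -> "NegationConfig":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            cues=tuple(doc["cues"]),
            window=int(doc.get("window", 8)),
            clause_boundaries=doc.get("clause_boundaries", cls.clause_boundaries),
        )


def detect_negation(
    text: str,
    mention: Mention,
    cue_lexicon: Sequence[str],
    window: int = 8,
    clause_boundaries: str = ",.;:!?、，。；：！？",
) -> bool:
    """True iff a negation cue governs the mention.

    A cue governs when it ends within ``window`` characters before the
    mention start and no clause-boundary punctuation intervenes between the
    cue and the mention.  Cues with Latin/digit edges only match at word
    boundaries (so "knot" never triggers the cue "not").
    """
    start = mention.span[0]
    if not 0 <= start <= mention.span[1] <= len(text):
        raise ValueError(f"mention span {mention.span} outside text bounds")
    for cue in cue_lexicon:
        pattern = re.compile(
            r"(?<![A-Za-z0-9])" + re.escape(cue.lower()) + r"(?![A-Za-z0-9])",
            re.IGNORECASE,
        )
        for hit in pattern.finditer(text):
            cue_end = hit.end()
            if cue_end <= start and start - cue_end <= window:
                between = text[cue_end:start]
                if not any(ch in clause_boundaries for ch in between):
                    return True
    return False


def collect_mentions(
    text: str,
    graph: KnowledgeGraph,
    rules: Iterable[Rule],
    neg_config: NegationConfig | None = None,
) -> list[Mention]:
    """All mentions for every (root, ontology) any rule binds, negation-marked."""
    neg = neg_config or NegationConfig()
    queries = {(s.root_id, s.ontology) for r in rules for s in r.concept_slots()}
    mentions: list[Mention] = []
    for root_id, ontology in sorted(queries):
        for m in find_mentions(text, root_id, ontology, graph):
            negated = detect_negation(
                text, m, neg.cues, neg.window, neg.clause_boundaries
            )
            mentions.append(replace(m, negated=negated))
    mentions.sort(key=lambda m: (m.span, m.matched_root))
    return mentions


def match_rule(text: str, rule: Rule, mentions: Sequence[Mention]) -> list[RuleMatch]:
    """All assignments of non-negated mentions to the rule's concept slots.

    Slots must be filled in order by mentions with strictly increasing,
    non-overlapping spans; free-text slots match any gap, so they impose no
    constraint beyond the ordering.
    """
    slots = rule.concept_slots()
    usable = [m for m in mentions if not m.negated]
    results: list[RuleMatch] = []

    def extend(slot_idx: int, min_start: int, chosen: list[Mention]) -> None:
        if slot_idx == len(slots):
            results.append(RuleMatch(rule.rule_id, rule.level, tuple(chosen)))
            return
        slot = slots[slot_idx]
        for m in usable:
            if m.span[0] < min_start:
                continue
            if m.matched_root == slot.root_id and m.ontology == slot.ontology:
                chosen.append(m)
                extend(slot_idx + 1, m.span[1], chosen)
                chosen.pop()

    extend(0, 0, [])
    return results


def assess_risk(
    record: CommentRecord,
    graph: KnowledgeGraph,
    rules: Sequence[Rule],
    neg_config: NegationConfig | None = None,
) -> RiskAssessment:
    """Risk level of one preprocessed comment: max level over matched rules."""
    mentions = collect_mentions(record.text, graph, rules, neg_config)
    matches: list[RuleMatch] = []
    for rule in rules:
        matches.extend(match_rule(record.text, rule, mentions))
    level = max((m.level for m in matches), default=0)
    return RiskAssessment(
        comment_id=record.comment_id,
        level=level,
        binary="high" if level >= HIGH_RISK_THRESHOLD else "low",
        matches=tuple(matches),
    )


def label_corpus(
    records: Sequence[CommentRecord],
    graph: KnowledgeGraph,
    rules: Sequence[Rule],
    neg_config: NegationConfig | None = None,
) -> list[tuple[CommentRecord, str, int]]:
    """Zero-cost annotation tier: (record, binary label, level) per record."""
    out = []
    n_high = 0
    for rec in records:
        assessment = assess_risk(rec, graph, rules, neg_config)
        n_high += assessment.binary == "high"
        out.append((rec, assessment.binary, assessment.level))
    logger.info(
        "rule labeling: %d records, %d high, %d low", len(out), n_high, len(out) - n_high
    )
    return out


def _parse_slot(raw: dict) -> RuleSlot:
    return RuleSlot(
        kind=raw["kind"],
        root_id=raw.get("root"),
        ontology=raw.get("ontology"),
    )


def load_rules(path: str | Path) -> list[Rule]:
    """Load rules from JSON: list of {rule_id, level, slots, extrapolated}."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    raw_rules = doc["rules"] if isinstance(doc, dict) else doc
    return [
        Rule(
            rule_id=r["rule_id"],
            level=int(r["level"]),
            slots=tuple(_parse_slot(s) for s in r["slots"]),
            extrapolated=bool(r.get("extrapolated", False)),
        )
        for r in raw_rules
    ]


def default_rules_path() -> Path:
    return Path(str(resources.files("treehole").joinpath("data/rules.json")))


def default_negation_path() -> Path:
    return Path(str(resources.files("treehole").joinpath("data/negation.json")))


def load_default_rules() -> list[Rule]:
    return load_rules(default_rules_path())


def load_default_negation() -> NegationConfig:
    return NegationConfig.from_file(default_negation_path())
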