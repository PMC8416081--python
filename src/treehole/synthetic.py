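"""Synthetic corpora and user records with known ground truth.

Comments are assembled from templates over the fixture graph's synthetic
surface forms: filler tokens, optionally a negation cue, and concept terms
(method / plan / future-time / wish) whose combination determines the gold
risk level by construction.  On negation-free, single-clause, non-obscure
comments the rule engine recovers the gold binary label exactly; realistic
noise enters through (a) negations placed beyond the engine's scope window
and (b) "obscure" comments whose text underdetermines the label, emulating
the context-dependent cases that only expert annotators resolve.

Per-user activity records are drawn so that a configurable subset of the
ten psychological features differs between classes by a standardized mean
difference delta — high-risk users self-focus more, post more at night,
and engage/receive less socially.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ontology import KnowledgeGraph, is_subclass_of, load_default_graph
from .pipeline import AnnotationTier
from .preprocess import CommentRecord
from .psych_features import FEATURE_NAMES, UserActivityRecord
from .rules import HIGH_RISK_THRESHOLD, Rule, label_corpus, load_default_rules

FILLER = (
    "daylight", "window", "garden", "paper", "hollow", "river", "walking",
    "thinking", "about", "the", "grey", "morning", "evening", "rain",
    "street", "dream", "slow", "empty", "corner", "silence",
)

NEG_CUES = ("not", "never")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    ``high_fraction`` defaults to 0.05: high-risk comments are a small
    minority of daily traffic.  ``obscure_rate`` is the fraction of
    comments whose text underdetermines the gold label (resolved only by
    the expert tier); ``negation_rate`` is the fraction of low-risk
    comments phrased as negated risk statements, half of which place the
    cue beyond the rule engine's scope window.
    """

    n_comments: int = 1000
    high_fraction: float = 0.05
    negation_rate: float = 0.1
    easy_noise_rate: float = 0.05
    obscure_rate: float = 0.15
    psych_effect_size: float = 1.0
    n_informative_features: int = 4
    n_easy: int | None = None
    n_hard: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("high_fraction", "negation_rate", "easy_noise_rate", "obscure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.psych_effect_size < 0:
            raise ValueError("psych_effect_size must be non-negative")
        if not 0 <= self.n_informative_features <= len(FEATURE_NAMES):
            raise ValueError("n_informative_features must be within 0..10")


def _surface_pool(graph: KnowledgeGraph, root: str, ontology: str) -> list[str]:
    forms = []
    for concept in graph.iter_concepts(ontology):
        if concept.surface_forms and is_subclass_of(graph, concept.id, root, ontology):
            forms.extend(concept.surface_forms)
    return sorted(forms)


def _fill(rng: np.random.Generator, lo: int, hi: int) -> list[str]:
    return list(rng.choice(FILLER, size=rng.integers(lo, hi + 1)))


def _compose(rng: np.random.Generator, terms: Sequence[str], negate: str | None = None,
             far_negation: bool = False) -> str:
    """Filler-padded sentence with concept terms in order.

    ``negate`` prefixes the first term with a cue; when ``far_negation``
    the cue is separated from the term by enough filler to fall outside
    the default 8-character scope window.
    """
    words = _fill(rng, 3, 5)
    for i, term in enumerate(terms):
        if i == 0 and negate is not None:
            words.append(negate)
            if far_negation:
                words.extend(_fill(rng, 2, 3))
        words.append(term)
        words.extend(_fill(rng, 2, 4))
    while len(words) < 7:  # survive the <=5-word preprocessing filter
        words.extend(_fill(rng, 2, 3))
    return " ".join(words)


def generate_corpus(
    cfg: GeneratorConfig, graph: KnowledgeGraph | None = None
) -> list[tuple[CommentRecord, int, str]]:
    """(record, gold level, gold binary) triples, one synthetic user each."""
    graph = graph or load_default_graph()
    rng = np.random.default_rng(cfg.seed)
    methods = _surface_pool(graph, "suicideMethod", "suicide")
    plans = _surface_pool(graph, "suicidePlan", "suicide")
    futures = _surface_pool(graph, "future", "time")
    wishes = _surface_pool(graph, "suicideWish", "wish")

    def pick(pool: list[str]) -> str:
        return str(rng.choice(pool))

    out: list[tuple[CommentRecord, int, str]] = []
    for i in range(cfg.n_comments):
        high = rng.random() < cfg.high_fraction
        obscure = rng.random() < cfg.obscure_rate
        if high:
            if obscure:
                # text looks like a mild wish; only expert context reveals risk
                level = 7
                text = _compose(rng, [pick(wishes)])
            else:
                level = int(rng.choice([6, 7, 8, 9]))
                if level == 6:
                    text = _compose(rng, [pick(plans)])
                elif level == 7:
                    text = _compose(rng, [pick(methods)])
                elif level == 8:
                    pair = [pick(plans), pick(futures)]
                    rng.shuffle(pair)
                    text = _compose(rng, pair)
                else:
                    pair = [pick(methods), pick(futures)]
                    rng.shuffle(pair)
                    text = _compose(rng, pair)
        else:
            if rng.random() < cfg.negation_rate:
                # a denied risk statement; half escape the scope window
                level = 2
                far = bool(rng.random() < 0.5)
                terms = [pick(methods)] if rng.random() < 0.5 else [pick(plans)]
                text = _compose(rng, terms, negate=str(rng.choice(NEG_CUES)), far_negation=far)
            elif obscure:
                level = int(rng.choice([0, 4]))
                text = _compose(rng, [pick(wishes)] if level == 4 else [])
            else:
                level = int(rng.choice([0, 4, 5]))
                if level == 0:
                    text = _compose(rng, [])
                elif level == 4:
                    text = _compose(rng, [pick(wishes)])
                else:
                    pair = [pick(wishes), pick(futures)]
                    rng.shuffle(pair)
                    text = _compose(rng, pair)
        hour = int(rng.integers(0, 24))
        rec = CommentRecord(
            comment_id=f"c{i:06d}",
            user_id=f"u{i:06d}",
            text=text,
            timestamp=f"2020-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
                      f"T{hour:02d}:{int(rng.integers(0, 60)):02d}:00",
        )
        out.append((rec, level, "high" if level >= HIGH_RISK_THRESHOLD else "low"))
    return out


# (base mean, spread, direction of the high-risk shift) per feature, on the
# scale of the extracted feature; the shift is direction * delta * spread.
_FEATURE_MODELS: dict[str, tuple[float, float, float]] = {
    "self_focus_rate": (1.0, 0.25, +1.0),
    "night_activity_rate": (0.25, 0.08, +1.0),
    "social_support_rate": (1.0, 0.25, -1.0),
    "social_activity_rate": (0.45, 0.08, -1.0),
    "willingness_to_express_rate": (0.8, 0.25, -1.0),
    "interaction_rate": (0.8, 0.25, -1.0),
    "collective_attention_rate": (0.4, 0.12, -1.0),
    "originality_rate": (0.6, 0.08, -1.0),
    "link_rate": (0.2, 0.06, -1.0),
    "self_description_length": (60.0, 20.0, -1.0),
}

# priority order in which features become informative
INFORMATIVE_ORDER: tuple[str, ...] = tuple(_FEATURE_MODELS)


def _draw_rate(rng: np.random.Generator, name: str, informative: bool,
               high: bool, delta: float, lo: float = 0.0, hi: float | None = None) -> float:
    base, spread, direction = _FEATURE_MODELS[name]
    mean = base + (direction * delta * spread if informative and high else 0.0)
    value = rng.normal(mean, spread)
    return float(np.clip(value, lo, hi if hi is not None else np.inf))


def generate_users(
    cfg: GeneratorConfig, user_ids_with_class: Sequence[tuple[str, str]]
) -> list[UserActivityRecord]:
    """Activity records whose informative features separate the classes."""
    rng = np.random.default_rng(cfg.seed + 1)
    informative = set(INFORMATIVE_ORDER[: cfg.n_informative_features])
    delta = cfg.psych_effect_size
    out: list[UserActivityRecord] = []
    for user_id, label in user_ids_with_class:
        high = label == "high"

        def rate(name: str, hi: float | None = None) -> float:
            return _draw_rate(rng, name, name in informative, high, delta, hi=hi)

        n_posts = int(1 + rng.poisson(40))
        n_followers = int(1 + rng.poisson(80))
        n_likes_made = int(1 + rng.poisson(60))
        out.append(
            UserActivityRecord(
                user_id=user_id,
                bio_bytes=int(round(rate("self_description_length"))),
                n_posts=n_posts,
                n_original=int(round(rate("originality_rate", hi=1.0) * n_posts)),
                n_with_links=int(round(rate("link_rate", hi=1.0) * n_posts)),
                total_mentions=int(round(rate("interaction_rate") * n_posts)),
                total_first_person_plural=int(
                    round(rate("collective_attention_rate") * n_posts)
                ),
                total_first_person_singular=int(
                    round(rate("self_focus_rate") * n_posts)
                ),
                n_night_posts=int(round(rate("night_activity_rate", hi=1.0) * n_posts)),
                n_followers=n_followers,
                n_mutual_follows=int(
                    round(rate("social_activity_rate", hi=1.0) * n_followers)
                ),
                n_comments_made=int(
                    round(rate("willingness_to_express_rate") * n_likes_made)
                ),
                n_likes_made=n_likes_made,
                n_comments_received=int(round(rate("social_support_rate") * n_posts)),
            )
        )
    return out


def generate_tiers(
    corpus_with_gold: Sequence[tuple[CommentRecord, int, str]],
    cfg: GeneratorConfig,
    graph: KnowledgeGraph | None = None,
    rules: Sequence[Rule] | None = None,
) -> tuple[AnnotationTier, AnnotationTier, AnnotationTier]:
    """(free, easy, hard) tiers over the generated corpus.

    free: rule-engine labels on every comment.  easy: gold labels flipped
    independently at ``easy_noise_rate`` (student errors), optionally
    subsampled to ``n_easy``.  hard: gold labels exactly, optionally
    subsampled to ``n_hard``.
    """
    graph = graph or load_default_graph()
    rules = list(rules) if rules is not None else load_default_rules()
    rng = np.random.default_rng(cfg.seed + 2)
    records = [rec for rec, _, _ in corpus_with_gold]
    gold = [binary for _, _, binary in corpus_with_gold]

    free_rows = label_corpus(records, graph, rules)
    free = AnnotationTier(
        "free", "rules", tuple((rec, lab) for rec, lab, _ in free_rows)
    )

    flip = rng.random(len(records)) < cfg.easy_noise_rate
    easy_labels = [
        ("low" if g == "high" else "high") if f else g for g, f in zip(gold, flip)
    ]
    easy_idx = _subsample(rng, len(records), cfg.n_easy)
    easy = AnnotationTier(
        "easy",
        "correction_file",
        tuple((records[i], easy_labels[i]) for i in easy_idx),
    )

    hard_idx = _subsample(rng, len(records), cfg.n_hard)
    hard = AnnotationTier(
        "hard",
        "correction_file",
        tuple((records[i], gold[i]) for i in hard_idx),
    )
    return free, easy, hard


def _subsample(rng: np.random.Generator, n: int, size: int | None) -> np.ndarray:
    if size is None or size >= n:
        return np.arange(n)
    return np.sort(rng.choice(n, size=size, replace=False))
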