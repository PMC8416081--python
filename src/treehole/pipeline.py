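"""End-to-end orchestration of the three-tier annotation workflow.

The workflow mirrors the staged annotation design: rules produce the free
tier at zero cost; a correction file by non-expert annotators upgrades it
to the easy tier; a smaller expert correction file defines the hard tier,
on which the psychology-fusion model is trained and evaluated.  Human
interaction is modeled as flat correction files (comment_id -> binary
label), which keeps every stage reproducible from disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml
from sklearn.model_selection import train_test_split

from . import io
from .evaluation import evaluate
from .models import (
    ModelConfig,
    TrainedModel,
    predict_labels,
    save_model,
    train_model1,
    train_model2,
    train_model3,
)
from .ontology import load_graph
from .preprocess import CommentRecord, preprocess_corpus
from .psych_features import (
    UserActivityRecord,
    extract_features,
    normalize_cohort,
)
from .rules import NegationConfig, label_corpus, load_rules

logger = logging.getLogger(__name__)

LabeledRecord = tuple[CommentRecord, str]  # (record, binary label)


@dataclass(frozen=True)
class AnnotationTier:
    name: str  # free | easy | hard
    source: str  # rules | correction_file
    records: tuple[LabeledRecord, ...]

    def __post_init__(self) -> None:
        if self.name not in ("free", "easy", "hard"):
            raise ValueError(f"unknown tier {self.name!r}")
        if self.name == "free" and self.source != "rules":
            raise ValueError("the free tier derives only from rules")
        if self.name in ("easy", "hard") and self.source != "correction_file":
            raise ValueError(f"the {self.name} tier must come from a correction file")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    corpus: str
    users: str | None = None
    graph: str | None = None
    rules: str | None = None
    negation: str | None = None
    easy_corrections: str | None = None
    hard_corrections: str | None = None
    out_dir: str = "treehole_run"
    seed: int = 0
    test_fraction: float = 0.2
    model: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def validate_paths(self) -> None:
        for name in ("corpus", "users", "graph", "rules", "negation",
                     "easy_corrections", "hard_corrections"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config path {name}={value!r} does not exist")


def stage_seeds(root_seed: int, n: int = 4) -> list[int]:
    """Independent per-stage seeds derived from one root seed."""
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def apply_corrections(
    base_labels: Sequence[LabeledRecord],
    corrections: Mapping[str, str] | str | Path,
) -> list[LabeledRecord]:
    """Overlay corrected binary labels; unknown comment ids are skipped.

    Idempotent: applying the same corrections twice changes nothing more.
    """
    if not isinstance(corrections, Mapping):
        corrections = {
            str(row["comment_id"]): row["binary"] for row in io.read_jsonl(corrections)
        }
    known = {rec.comment_id for rec, _ in base_labels}
    for cid in corrections:
        if cid not in known:
            logger.warning("correction for unknown comment_id %r skipped", cid)
    flips = 0
    out: list[LabeledRecord] = []
    for rec, label in base_labels:
        corrected = corrections.get(rec.comment_id, label)
        flips += corrected != label
        out.append((rec, corrected))
    logger.info("applied corrections: %d labels flipped", flips)
    return out


def _split(
    labeled: Sequence[LabeledRecord], test_fraction: float, seed: int
) -> tuple[list[LabeledRecord], list[LabeledRecord]]:
    labels = [lab for _, lab in labeled]
    idx = np.arange(len(labeled))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    return [labeled[i] for i in train_idx], [labeled[i] for i in test_idx]


def _eval_block(model: TrainedModel, test: Sequence[LabeledRecord],
                features: Mapping[str, Any] | None = None) -> dict:
    texts = [rec.text for rec, _ in test]
    gold = [lab for _, lab in test]
    if features is not None:
        feats = [features[rec.user_id] for rec, _ in test]
        pred = predict_labels(model, texts, feats)
    else:
        pred = predict_labels(model, texts)
    return evaluate(list(zip(gold, pred))).to_dict()


def run_full(config: RunConfig) -> dict:
    """Execute preprocess -> rules -> model1 -> model2 -> model3 -> report.

    Returns (and writes to ``out_dir/report.json``) a JSON-serializable
    report with per-stage metric blocks and artifact paths.  Stops after
    model2, with an explicit notice, when no hard-tier correction file is
    configured.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}, "artifacts": {}}

    def model_config(stage_idx: int) -> ModelConfig:
        return ModelConfig(**{"seed": seeds[stage_idx], **config.model})

    # -- preprocess ---------------------------------------------------
    try:
        raw = [CommentRecord.from_dict(d) for d in io.read_jsonl(config.corpus)]
        pre_report: dict[str, int] = {}
        clean = preprocess_corpus(raw, report=pre_report)
        io.write_jsonl(out_dir / "clean.jsonl", (r.to_dict() for r in clean))
    except Exception as exc:
        raise StageError("preprocess", exc) from exc
    report["stages"]["preprocess"] = pre_report
    report["artifacts"]["clean"] = str(out_dir / "clean.jsonl")

    # -- free tier (rules) --------------------------------------------
    try:
        graph = load_graph(config.graph) if config.graph else _default_graph()
        ruleset = load_rules(config.rules) if config.rules else _default_rules()
        neg = (
            NegationConfig.from_file(config.negation)
            if config.negation
            else _default_negation()
        )
        rows = label_corpus(clean, graph, ruleset, neg)
        free_tier = AnnotationTier(
            "free", "rules", tuple((rec, lab) for rec, lab, _ in rows)
        )
        io.write_jsonl(
            out_dir / "free_labels.jsonl",
            ({**rec.to_dict(), "binary": lab, "level": lvl} for rec, lab, lvl in rows),
        )
    except Exception as exc:
        raise StageError("rule_labeling", exc) from exc
    n_high = sum(lab == "high" for _, lab in free_tier.records)
    report["stages"]["free_tier"] = {
        "n": len(free_tier.records), "high": n_high,
        "low": len(free_tier.records) - n_high,
    }
    report["artifacts"]["free_labels"] = str(out_dir / "free_labels.jsonl")

    # -- model1 on free labels ----------------------------------------
    try:
        cfg1 = model_config(0)
        train1, test1 = _split(list(free_tier.records), config.test_fraction, seeds[0])
        model1 = train_model1([(r.text, lab) for r, lab in train1], cfg1)
        save_model(model1, out_dir / "model1.npz")
        report["stages"]["model1"] = _eval_block(model1, test1)
    except Exception as exc:
        raise StageError("model1", exc) from exc
    report["artifacts"]["model1"] = str(out_dir / "model1.npz")

    if not config.easy_corrections:
        report["notice"] = "no easy-tier corrections configured; stopped after model1"
        io.write_json(out_dir / "report.json", report)
        return report

    # -- easy tier + model2 -------------------------------------------
    try:
        easy_labels = apply_corrections(list(free_tier.records), config.easy_corrections)
        easy_tier = AnnotationTier("easy", "correction_file", tuple(easy_labels))
        io.write_jsonl(
            out_dir / "easy_labels.jsonl",
            ({**rec.to_dict(), "binary": lab} for rec, lab in easy_tier.records),
        )
        cfg2 = model_config(1)
        train2, test2 = _split(list(easy_tier.records), config.test_fraction, seeds[1])
        model2 = train_model2(model1, [(r.text, lab) for r, lab in train2], cfg2)
        save_model(model2, out_dir / "model2.npz")
        report["stages"]["model2"] = _eval_block(model2, test2)
    except Exception as exc:
        raise StageError("model2", exc) from exc
    report["artifacts"]["model2"] = str(out_dir / "model2.npz")

    if not config.hard_corrections:
        report["notice"] = "no hard-tier corrections configured; stopped after model2"
        io.write_json(out_dir / "report.json", report)
        return report

    # -- hard tier + features + model3 --------------------------------
    try:
        hard_map = {
            str(row["comment_id"]): row["binary"]
            for row in io.read_jsonl(config.hard_corrections)
        }
        hard_records = [
            (rec, hard_map[rec.comment_id])
            for rec, _ in easy_tier.records
            if rec.comment_id in hard_map
        ]
        hard_tier = AnnotationTier("hard", "correction_file", tuple(hard_records))
        io.write_jsonl(
            out_dir / "hard_labels.jsonl",
            ({**rec.to_dict(), "binary": lab} for rec, lab in hard_tier.records),
        )
        if not config.users:
            raise ValueError("hard tier configured but no user activity file given")
        users = [UserActivityRecord.from_dict(d) for d in io.read_jsonl(config.users)]
        vectors = normalize_cohort([extract_features(u) for u in users])
        feature_map = {u.user_id: v for u, v in zip(users, vectors)}
        cfg3 = model_config(2)
        train3, test3 = _split(list(hard_tier.records), config.test_fraction, seeds[2])
        model3 = train_model3(
            model1,
            [(r.text, feature_map[r.user_id], lab) for r, lab in train3],
            cfg3,
        )
        save_model(model3, out_dir / "model3.npz")
        report["stages"]["model2_on_hard"] = _eval_block(model2, test3)
        report["stages"]["model3"] = _eval_block(model3, test3, features=feature_map)
    except Exception as exc:
        raise StageError("model3", exc) from exc
    report["artifacts"]["model3"] = str(out_dir / "model3.npz")

    io.write_json(out_dir / "report.json", report)
    report["artifacts"]["report"] = str(out_dir / "report.json")
    return report


def _default_graph():
    from .ontology import load_default_graph

    return load_default_graph()


def _default_rules():
    from .rules import load_default_rules

    return load_default_rules()


def _default_negation():
    from .rules import load_default_negation

    return load_default_negation()
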