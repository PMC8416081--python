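"""Precision / recall / F1 / accuracy and the fivefold CV protocol.

The positive class is "high" risk throughout.  Undefined precision or
recall (zero denominator) is reported as 0 with a warning flag rather than
NaN, so aggregate tables stay numeric.  Cross-validation metrics are
aggregated by pooling fold-level confusion counts (micro averaging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

POSITIVE = "high"


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f1: float
    accuracy: float
    tp: int
    fp: int
    fn: int
    tn: int
    undefined: bool = False  # a zero-denominator metric was clamped to 0

    def to_dict(self) -> dict:
        return {
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "counts": {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn},
        }


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    denom = precision + recall
    return 2.0 * precision * recall / denom if denom else 0.0


def confusion(pairs: Sequence[tuple[str, str]]) -> tuple[int, int, int, int]:
    tp = fp = fn = tn = 0
    for gold, pred in pairs:
        if pred == POSITIVE:
            if gold == POSITIVE:
                tp += 1
            else:
                fp += 1
        else:
            if gold == POSITIVE:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def from_counts(tp: int, fp: int, fn: int, tn: int) -> EvalResult:
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    undefined = False
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        precision, undefined = 0.0, True
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        recall, undefined = 0.0, True
    if undefined:
        warnings.warn("zero-denominator precision/recall reported as 0", stacklevel=3)
    return EvalResult(
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        accuracy=(tp + tn) / total,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        undefined=undefined,
    )


def evaluate(pairs: Sequence[tuple[str, str]]) -> EvalResult:
    """Metrics from (gold, predicted) binary label pairs."""
    return from_counts(*confusion(pairs))


def kfold(
    labels: Sequence[str],
    k: int = 5,
    stratified: bool = True,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (train_idx, test_idx) splits over the label sequence.

    Stratified splits keep per-fold class proportions within one item of
    the global proportions; each class therefore needs at least ``k``
    members.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    y = np.asarray(labels)
    if stratified:
        classes, counts = np.unique(y, return_counts=True)
        for cls, cnt in zip(classes, counts):
            if cnt < k:
                raise ValueError(
                    f"class {cls!r} has only {cnt} members, fewer than k={k}"
                )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y)]


def pooled_cv_result(fold_results: Sequence[EvalResult]) -> EvalResult:
    """Micro-average: sum fold confusion counts, recompute the metrics."""
    return from_counts(
        sum(r.tp for r in fold_results),
        sum(r.fp for r in fold_results),
        sum(r.fn for r in fold_results),
        sum(r.tn for r in fold_results),
    )
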