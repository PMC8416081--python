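"""The ten user-level psychological features fused into the final model.

Each feature is a simple ratio (or length) over a user's raw social-media
activity counts; high- and low-risk users differ systematically on several
of them (self-focus, nighttime activity, social engagement), which is what
makes the fusion informative when the text alone is ambiguous.

All rates are computed within-user; any zero denominator yields 0 so the
fusion input stays dense.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

FEATURE_NAMES: tuple[str, ...] = (
    "self_description_length",
    "originality_rate",
    "link_rate",
    "interaction_rate",
    "collective_attention_rate",
    "self_focus_rate",
    "night_activity_rate",
    "social_activity_rate",
    "willingness_to_express_rate",
    "social_support_rate",
)


@dataclass(frozen=True)
class UserActivityRecord:
    """Raw per-user counts from which the ten features derive.

    Night posts are those published between 22:00 and 06:00.
    """

    user_id: str
    bio_bytes: int = 0
    n_posts: int = 0
    n_original: int = 0
    n_with_links: int = 0
    total_mentions: int = 0
    total_first_person_plural: int = 0
    total_first_person_singular: int = 0
    n_night_posts: int = 0
    n_followers: int = 0
    n_mutual_follows: int = 0
    n_comments_made: int = 0
    n_likes_made: int = 0
    n_comments_received: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "user_id":
                continue
            v = getattr(self, f.name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v!r}")
        for bounded in ("n_original", "n_with_links", "n_night_posts"):
            if getattr(self, bounded) > self.n_posts:
                raise ValueError(f"{bounded} exceeds n_posts")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "UserActivityRecord":
        kwargs = {f.name: d[f.name] for f in fields(cls) if f.name in d}
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class PsychFeatureVector:
    self_description_length: float
    originality_rate: float
    link_rate: float
    interaction_rate: float
    collective_attention_rate: float
    self_focus_rate: float
    night_activity_rate: float
    social_activity_rate: float
    willingness_to_express_rate: float
    social_support_rate: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PsychFeatureVector":
        values = list(values)
        if len(values) != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} values, got {len(values)}")
        return cls(**dict(zip(FEATURE_NAMES, map(float, values))))

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in FEATURE_NAMES}


def count_features() -> int:
    """Number of psychological features in the vector (ten)."""
    return len(FEATURE_NAMES)


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def extract_features(rec: UserActivityRecord) -> PsychFeatureVector:
    """Compute the ten features from one user's raw activity counts."""
    return PsychFeatureVector(
        self_description_length=float(rec.bio_bytes),
        originality_rate=_ratio(rec.n_original, rec.n_posts),
        link_rate=_ratio(rec.n_with_links, rec.n_posts),
        interaction_rate=_ratio(rec.total_mentions, rec.n_posts),
        collective_attention_rate=_ratio(rec.total_first_person_plural, rec.n_posts),
        self_focus_rate=_ratio(rec.total_first_person_singular, rec.n_posts),
        night_activity_rate=_ratio(rec.n_night_posts, rec.n_posts),
        social_activity_rate=_ratio(rec.n_mutual_follows, rec.n_followers),
        willingness_to_express_rate=_ratio(rec.n_comments_made, rec.n_likes_made),
        social_support_rate=_ratio(rec.n_comments_received, rec.n_posts),
    )


def normalize_cohort(vectors: Sequence[PsychFeatureVector]) -> list[PsychFeatureVector]:
    """Center and scale each feature to unit variance across the cohort.

    Constant features map to 0.  Requires at least two vectors.
    """
    if len(vectors) < 2:
        raise ValueError("cohort normalization needs at least 2 vectors")
    matrix = np.vstack([v.as_array() for v in vectors])
    scaled = StandardScaler().fit_transform(matrix)
    return [PsychFeatureVector.from_array(row) for row in scaled]


def feature_table(
    records: Iterable[UserActivityRecord], normalize: bool = False
) -> pd.DataFrame:
    """Feature matrix indexed by user_id with the fixed column order."""
    records = list(records)
    vectors = [extract_features(r) for r in records]
    if normalize:
        vectors = normalize_cohort(vectors)
    return pd.DataFrame(
        [v.to_dict() for v in vectors],
        index=pd.Index([r.user_id for r in records], name="user_id"),
        columns=list(FEATURE_NAMES),
    )
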