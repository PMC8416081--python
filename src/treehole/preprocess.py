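"""Corpus cleaning applied before annotation or training.

Three cleaning steps: duplicate removal, emoji removal, and removal of
too-short comments (five words or fewer).  "Word" is defined here as one
CJK character, plus one per whitespace-delimited non-CJK token — a fixed
convention that avoids a segmenter dependency while behaving sensibly for
mixed Chinese/Latin text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from datetime import datetime
from typing import Any, Iterable


@dataclass(frozen=True)
class CommentRecord:
    comment_id: str
    user_id: str
    text: str
    timestamp: str = "1970-01-01T00:00:00"

    def __post_init__(self) -> None:
        datetime.fromisoformat(self.timestamp)  # must parse

    def to_dict(self) -> dict[str, Any]:
        return {
            "comment_id": self.comment_id,
            "user_id": self.user_id,
            "text": self.text,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CommentRecord":
        return cls(
            comment_id=str(d["comment_id"]),
            user_id=str(d["user_id"]),
            text=d["text"],
            timestamp=d.get("timestamp", "1970-01-01T00:00:00"),
        )


# Unicode blocks treated as emoji / pictographs.  Fixed list, so stripping
# is bit-exact across platforms.
EMOJI_RANGES: tuple[tuple[int, int], ...] = (
    (0x1F300, 0x1F5FF),  # misc symbols and pictographs
    (0x1F600, 0x1F64F),  # emoticons
    (0x1F680, 0x1F6FF),  # transport and map symbols
    (0x1F900, 0x1F9FF),  # supplemental symbols and pictographs
    (0x1FA70, 0x1FAFF),  # symbols and pictographs extended-A
    (0x2600, 0x26FF),    # miscellaneous symbols
    (0x2700, 0x27BF),    # dingbats
    (0x2B00, 0x2BFF),    # misc symbols and arrows (hearts, stars)
    (0xFE00, 0xFE0F),    # variation selectors
    (0x200D, 0x200D),    # zero width joiner
    (0x1F1E6, 0x1F1FF),  # regional indicators
)

_EMOJI_RE = re.compile(
    "[" + "".join(f"{chr(a)}-{chr(b)}" for a, b in EMOJI_RANGES) + "]"
)

# CJK unified ideographs (base + extension A) and CJK punctuation-free hanzi
_CJK_RE = re.compile("[㐀-䶿一-鿿豈-﫿]")


def strip_emoji(text: str) -> str:
    """Remove all code points in the documented emoji blocks."""
    return _EMOJI_RE.sub("", text)


def token_count(text: str) -> int:
    """Number of CJK characters plus whitespace-delimited non-CJK tokens."""
    cjk = len(_CJK_RE.findall(text))
    non_cjk = _CJK_RE.sub(" ", text)
    words = len(non_cjk.split())
    return cjk + words


def _normalize_ws(text: str) -> str:
    return " ".join(text.split())


def clean_text(text: str) -> str:
    return _normalize_ws(strip_emoji(text))


MIN_TOKENS = 6  # comments with <= 5 words are dropped


def preprocess_corpus(
    records: Iterable[CommentRecord],
    report: dict[str, int] | None = None,
) -> list[CommentRecord]:
    """Deduplicate, strip emoji, and drop too-short comments.

    Duplicates are exact text matches after emoji stripping and whitespace
    normalization; the first occurrence survives.  Order is preserved and
    the operation is idempotent.  ``report``, if given, is filled with
    per-rule removal counts.
    """
    counts = {"input": 0, "duplicate": 0, "too_short": 0, "kept": 0}
    seen: set[str] = set()
    out: list[CommentRecord] = []
    for rec in records:
        counts["input"] += 1
        text = clean_text(rec.text)
        if text in seen:
            counts["duplicate"] += 1
            continue
        seen.add(text)
        if token_count(text) < MIN_TOKENS:
            counts["too_short"] += 1
            continue
        out.append(replace(rec, text=text))
        counts["kept"] += 1
    if report is not None:
        report.update(counts)
    return out
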