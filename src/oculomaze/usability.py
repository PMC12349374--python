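"""System Usability Scale (SUS) scoring and cohort aggregation.

The SUS is a 10-item Likert questionnaire (1-5 per item).  Odd items are
positively worded and contribute ``value - 1``; even items are negatively
worded and contribute ``5 - value``; the sum is scaled by 2.5 onto 0-100.
Scores are banded 0-50 "Unacceptable", 51-68 "Marginal", 69-100
"Acceptable".
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "SUSResponse",
    "SUSRecord",
    "sus_score",
    "sus_category",
    "aggregate_sus",
    "truncate2",
]


@dataclass(frozen=True)
class SUSResponse:
    """One completed questionnaire: exactly 10 Likert values in 1..5."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValueError(f"SUS has exactly 10 items, got {len(self.items)}")
        for i, v in enumerate(self.items, start=1):
            if not (isinstance(v, int) and 1 <= v <= 5):
                raise ValueError(f"item {i} must be an integer in 1..5, got {v!r}")
        object.__setattr__(self, "items", tuple(self.items))


@dataclass(frozen=True)
class SUSRecord:
    """One respondent: demographics plus the final 0-100 score."""

    id: str
    score: float
    age: Optional[int] = None
    sex: Optional[str] = None
    visual_condition: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 100.0):
            raise ValueError(f"score must be in [0, 100], got {self.score}")
        # Item-derived scores are always multiples of 2.5; a precomputed
        # score that is not is unusual but admissible.
        if (self.score * 4) % 10 != 0:
            logger.warning("score %s is not a multiple of 2.5", self.score)


def sus_score(resp: SUSResponse) -> float:
    """Scale a questionnaire onto 0-100."""
    odd = sum(resp.items[i] - 1 for i in range(0, 10, 2))
    even = sum(5 - resp.items[i] for i in range(1, 10, 2))
    return (odd + even) * 2.5


def sus_category(score: float) -> str:
    """Band a score: <=50 Unacceptable, <=68 Marginal, else Acceptable."""
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score must be in [0, 100], got {score}")
    if score <= 50.0:
        return "Unacceptable"
    if score <= 68.0:
        return "Marginal"
    return "Acceptable"


def truncate2(value: float) -> float:
    """Truncate (not round) to 2 decimals, the convention used for the
    published acceptance percentages (13/15 -> 86.66)."""
    return math.floor(value * 100.0) / 100.0


def aggregate_sus(records: Sequence[SUSRecord]) -> dict:
    """Cohort summary: mean, sample STD, category counts and rates.

    Rates are percentages truncated to 2 decimals; the marginal rate is
    the complement so the three rates total 100 up to truncation loss.
    """
    if not records:
        raise ValueError("aggregate_sus requires at least one record")
    scores = [r.score for r in records]
    n = len(scores)
    counts = {"Acceptable": 0, "Marginal": 0, "Unacceptable": 0}
    for s in scores:
        counts[sus_category(s)] += 1
    acceptance = truncate2(100.0 * counts["Acceptable"] / n)
    unacceptable = truncate2(100.0 * counts["Unacceptable"] / n)
    marginal = round(100.0 - acceptance - unacceptable, 2)
    return {
        "n": n,
        "mean": statistics.fmean(scores),
        "sample_std": statistics.stdev(scores) if n >= 2 else None,
        "counts": counts,
        "acceptance_rate_pct": acceptance,
        "marginal_rate_pct": marginal,
        "unacceptable_rate_pct": unacceptable,
    }
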