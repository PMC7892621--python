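"""Intake questionnaire: PGSI scoring, gambling frequency and types.

The Problem Gambling Severity Index (PGSI) is a 9-item screener; items are
scored 0-3 and summed to a 0-27 total.  Gambling frequency is an ordinal
0-4 ("not at all" through "once per day or more"); last-year gambling types
are a multi-select over 12 forms plus a none-option.  Only the numeric coding
is modeled here — the instrument text belongs to the validated questionnaire.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "GAMBLING_TYPES",
    "FREQUENCY_LABELS",
    "PgsiBand",
    "SurveyResponse",
    "score_pgsi",
    "count_gambling_types",
    "classify_pgsi",
]

#: The 12 last-year gambling forms offered by the intake survey.
GAMBLING_TYPES = (
    "lottery",
    "sports_betting",
    "race_betting",
    "cards",
    "casino_slots",
    "festival",
    "dice",
    "online_lottery",
    "online_betting",
    "online_cards",
    "online_slots",
    "other",
)

FREQUENCY_LABELS = (
    "not_at_all",        # 0
    "a_few_times",       # 1
    "once_a_month",      # 2
    "once_per_week",     # 3
    "once_per_day_or_more",  # 4
)

N_PGSI_ITEMS = 9


class PgsiBand(str, enum.Enum):
    """Standard PGSI interpretive bands."""

    non_problem = "non_problem"      # 0
    low_risk = "low_risk"            # 1-2
    moderate_risk = "moderate_risk"  # 3-7
    problem_gambling = "problem_gambling"  # >= 8


@dataclass(frozen=True)
class SurveyResponse:
    """One participant's intake questionnaire."""

    study_id: str
    age: float
    sex: str  # "male" | "female"
    gambling_frequency: int  # ordinal 0-4
    gambling_types: tuple[str, ...] = ()  # empty tuple encodes "none"
    pgsi_items: tuple[int, ...] = field(default=(0,) * N_PGSI_ITEMS)

    def __post_init__(self):
        if self.gambling_frequency not in range(5):
            raise ValueError(f"gambling_frequency {self.gambling_frequency} not in 0..4")
        unknown = set(self.gambling_types) - set(GAMBLING_TYPES)
        if unknown:
            raise ValueError(f"unknown gambling types: {sorted(unknown)}")
        score_pgsi(self.pgsi_items)  # validates count and range

    @property
    def pgsi_total(self) -> int:
        return score_pgsi(self.pgsi_items)

    @property
    def any_gambling(self) -> bool:
        return len(self.gambling_types) > 0


def score_pgsi(items: Sequence[int]) -> int:
    """Sum the 9 PGSI items (each 0-3) to the 0-27 total score."""
    if len(items) != N_PGSI_ITEMS:
        raise ValueError(f"expected {N_PGSI_ITEMS} PGSI items, got {len(items)}")
    for i, item in enumerate(items, start=1):
        if item not in (0, 1, 2, 3):
            raise ValueError(f"PGSI item {i} = {item!r} not in 0..3")
    return int(sum(items))


def count_gambling_types(response: "SurveyResponse | Sequence[str]") -> int:
    """Number of distinct gambling forms selected (none -> 0)."""
    types = response.gambling_types if isinstance(response, SurveyResponse) else response
    return len(set(types))


def classify_pgsi(total: int) -> PgsiBand:
    """Map a PGSI total to the instrument's standard risk band."""
    if not 0 <= total <= 27:
        raise ValueError(f"PGSI total {total} not in 0..27")
    if total == 0:
        return PgsiBand.non_problem
    if total <= 2:
        return PgsiBand.low_risk
    if total <= 7:
        return PgsiBand.moderate_risk
    return PgsiBand.problem_gambling
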