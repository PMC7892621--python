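"""Behavioral data-quality screening: response variation and completion time.

Indiscriminate, repetitive responding in a binary-choice block is screened by
a response-variation score — the percentage of trials on which a designated
reference option was chosen.  Scores outside a configurable 10-90% range flag
a participant as likely poor quality.  Completion time is summarized but, in
line with the screening methodology this implements, never used for
exclusion: a long duration may simply mean the participant paused between
phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .design import ExperimentDesign, GameType
from .engine import ParticipantSession, TrialRecord, records_to_frame

__all__ = [
    "QualityReport",
    "response_variation_score",
    "flag_low_variation",
    "completion_time_summary",
    "cohort_quality_report",
]


@dataclass(frozen=True)
class QualityReport:
    """Per-participant variation scores/flags plus cohort summaries."""

    participants: pd.DataFrame  # study_id, variation_score, flagged, duration_min
    n_participants: int
    n_flagged: int
    pct_flagged: float
    variation_mean: float
    variation_sd: float
    duration: dict = field(default_factory=dict)
    lower: float = 10.0
    upper: float = 90.0

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "n_flagged": self.n_flagged,
            "pct_flagged": self.pct_flagged,
            "variation_mean": self.variation_mean,
            "variation_sd": self.variation_sd,
            "bounds": [self.lower, self.upper],
            "duration": self.duration,
            "participants": self.participants.to_dict(orient="records"),
        }


def _choice_responses(trials) -> pd.Series:
    if isinstance(trials, pd.DataFrame):
        df = trials
    else:
        df = records_to_frame(list(trials))
    df = df[df["game_type"] != GameType.slot.value]
    return df["response"]


def response_variation_score(
    trials: Union[pd.DataFrame, Sequence[TrialRecord]],
    reference_option: Optional[str] = None,
) -> float:
    """Percentage of choice trials on which the reference option was chosen.

    The reference defaults to the first option listed in the block design
    (callers that only have a trial log may pass it explicitly).  The score
    is order-invariant; 50% means equal response frequencies.
    """
    responses = _choice_responses(trials)
    if responses.empty:
        raise ValueError("no choice-game trials: variation score undefined")
    if reference_option is None:
        reference_option = sorted(responses.unique())[0]
    return float(100.0 * (responses == reference_option).mean())


def flag_low_variation(score: float, lower: float = 10.0, upper: float = 90.0) -> bool:
    """True iff the variation score lies strictly outside [lower, upper]."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"variation score {score} not in [0, 100]")
    return score < lower or score > upper


def completion_time_summary(
    durations_min: Sequence[float],
    thresholds_min: Sequence[float] = (15.0, 20.0),
) -> dict:
    """Mean/SD/min/max of session durations plus counts above thresholds.

    Durations are reported for transparency only; they are not a quality
    indicator and never drive exclusion.
    """
    arr = np.asarray(list(durations_min), dtype=float)
    if arr.size == 0:
        raise ValueError("no durations supplied")
    summary = {
        "n": int(arr.size),
        "mean_min": float(arr.mean()),
        "sd_min": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min_min": float(arr.min()),
        "max_min": float(arr.max()),
    }
    summary["n_above_threshold"] = {
        f"{thr:g}": int((arr > thr).sum()) for thr in thresholds_min
    }
    return summary


def cohort_quality_report(
    sessions: Sequence[ParticipantSession],
    design: Optional[ExperimentDesign] = None,
    block_index: int = 0,
    lower: float = 10.0,
    upper: float = 90.0,
) -> QualityReport:
    """Screen a cohort: variation score and flag per participant, plus
    cohort-level flag counts and duration summary.

    The score is computed on the choice block at ``block_index`` (by default
    the first block), with the reference option taken from the design when
    one is supplied.
    """
    if not sessions:
        raise ValueError("empty cohort")
    reference: Optional[str] = None
    if design is not None:
        # all arms are expected to share the reference option of the block
        block = design.arms[0].blocks[block_index]
        if block.options:
            reference = block.options[0].option_id
    rows = []
    for s in sessions:
        recs = [r for r in s.records if r.block_index == block_index]
        score = response_variation_score(recs, reference_option=reference)
        rows.append(
            {
                "study_id": s.study_id,
                "variation_score": score,
                "flagged": flag_low_variation(score, lower, upper),
                "duration_min": s.duration_min,
            }
        )
    table = pd.DataFrame(rows)
    n = len(table)
    n_flagged = int(table["flagged"].sum())
    return QualityReport(
        participants=table,
        n_participants=n,
        n_flagged=n_flagged,
        pct_flagged=100.0 * n_flagged / n,
        variation_mean=float(table["variation_score"].mean()),
        variation_sd=float(table["variation_score"].std(ddof=1)) if n > 1 else 0.0,
        duration=completion_time_summary(table["duration_min"]),
        lower=lower,
        upper=upper,
    )
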