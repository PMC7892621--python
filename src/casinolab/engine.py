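"""Trial-by-trial game engine: outcome draws, balance accounting, logging.

Every gamble is resolved by an independent Bernoulli draw (sampling with
replacement, as in real casino games) from the win probability of the chosen
option — or, for the slot machine, of the visual theme independently sampled
for that trial.  The engine logs one long-format record per trial and typed
events for between-block messages, and provides the closed-form expectations
(balance trajectory, return to player) the mechanics audits compare against.

Balance convention: ``balance_in`` is the pre-bet balance; on every trial
``balance_out = balance_in - bet_size + outcome_credit`` where
``outcome_credit`` is 0 on a loss and ``win_amount`` (plus the bet, when the
block returns bets on wins) on a win.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

from .design import (
    ExperimentDesign,
    GameBlockSpec,
    GameType,
    InvalidDesignError,
    validate_design,
)

if TYPE_CHECKING:  # pragma: no cover
    from .policies import AgentPolicy
    from .survey import SurveyResponse

__all__ = [
    "TrialRecord",
    "SessionEvent",
    "SessionState",
    "ParticipantSession",
    "GameView",
    "sample_theme",
    "resolve_trial",
    "run_block",
    "run_session",
    "expected_balance_trajectory",
    "expected_per_trial_change",
    "return_to_player",
    "block_outcome_mixture",
    "records_to_frame",
]

TRIAL_COLUMNS = [
    "study_id",
    "timestamp_ms",
    "arm_id",
    "game_type",
    "block_index",
    "trial_number",
    "balance_in",
    "theme_id",
    "response",
    "outcome",
    "outcome_credit",
    "balance_out",
]


@dataclass(frozen=True)
class TrialRecord:
    """One long-format row per gamble."""

    study_id: str
    timestamp_ms: int
    arm_id: str
    game_type: str
    block_index: int
    trial_number: int  # 1-based within block
    balance_in: float
    theme_id: Optional[str]
    response: str
    outcome: str  # "win" | "loss"
    outcome_credit: float
    balance_out: float


@dataclass(frozen=True)
class SessionEvent:
    """Typed non-trial log event (messages shown between blocks)."""

    study_id: str
    timestamp_ms: int
    event_type: str
    payload: str


@dataclass
class SessionState:
    """Mutable per-session state carried across blocks."""

    study_id: str
    arm_id: str
    balance: float
    rng: np.random.Generator
    clock_ms: int = 0
    records: list[TrialRecord] = field(default_factory=list)
    events: list[SessionEvent] = field(default_factory=list)
    _block_counts: dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class GameView:
    """What a participant (agent policy) can see on the current trial."""

    game_type: str
    block_index: int
    trial_number: int
    options: tuple[str, ...]
    balance: Optional[float]  # None when the design hides the balance
    last_response: Optional[str] = None
    last_outcome: Optional[str] = None


@dataclass(frozen=True)
class ParticipantSession:
    """Survey response plus the full trial/event log of one participant."""

    study_id: str
    arm_id: str
    survey: Optional["SurveyResponse"]
    records: tuple[TrialRecord, ...]
    events: tuple[SessionEvent, ...]

    @property
    def duration_min(self) -> float:
        if not self.records and not self.events:
            return 0.0
        stamps = [r.timestamp_ms for r in self.records] + [e.timestamp_ms for e in self.events]
        return max(stamps) / 60_000.0


def sample_theme(block: GameBlockSpec, rng: np.random.Generator) -> str:
    """Sample the visual theme displayed on one slot trial (with replacement)."""
    if block.game_type is not GameType.slot or not block.themes:
        raise ValueError("sample_theme requires a slot block with themes")
    themes = block.themes
    if len(themes) == 1:
        return themes[0].theme_id
    u = rng.random()
    acc = 0.0
    for t in themes:
        acc += t.display_probability
        if u < acc:
            return t.theme_id
    return themes[-1].theme_id  # guard against float round-off at u ~ 1


def resolve_trial(
    state: SessionState,
    response: str,
    block: GameBlockSpec,
    block_index: int = 0,
    theme_id: Optional[str] = None,
) -> TrialRecord:
    """Resolve one gamble: draw the outcome, update the balance, log a record.

    For slot blocks the displayed theme determines the win probability; it is
    sampled here unless supplied by the caller.
    """
    legal = block.legal_responses()
    if response not in legal:
        raise ValueError(
            f"illegal response {response!r} for {block.game_type.value} block; "
            f"legal options: {legal}"
        )
    if block.game_type is GameType.slot:
        if theme_id is None:
            theme_id = sample_theme(block, state.rng)
        theme = next(t for t in block.themes if t.theme_id == theme_id)
        p, win_amount = theme.win_probability, theme.win_amount
    else:
        option = next(o for o in block.options if o.option_id == response)
        p, win_amount = option.win_probability, option.win_amount
        theme_id = None

    won = state.rng.random() < p
    credit = 0.0
    if won:
        credit = win_amount + (block.bet_size if block.bet_returned_on_win else 0.0)
    balance_in = state.balance
    balance_out = balance_in - block.bet_size + credit
    trial_number = state._block_counts.get(block_index, 0) + 1
    state._block_counts[block_index] = trial_number

    record = TrialRecord(
        study_id=state.study_id,
        timestamp_ms=state.clock_ms,
        arm_id=state.arm_id,
        game_type=block.game_type.value,
        block_index=block_index,
        trial_number=trial_number,
        balance_in=balance_in,
        theme_id=theme_id,
        response=response,
        outcome="win" if won else "loss",
        outcome_credit=credit,
        balance_out=balance_out,
    )
    state.balance = balance_out
    state.records.append(record)
    return record


def run_block(
    state: SessionState,
    block: GameBlockSpec,
    policy: "AgentPolicy",
    block_index: int = 0,
) -> list[TrialRecord]:
    """Run all trials of one block, querying the policy once per trial."""
    out: list[TrialRecord] = []
    last_response: Optional[str] = None
    last_outcome: Optional[str] = None
    options = tuple(block.legal_responses())
    for t in range(1, block.n_trials + 1):
        view = GameView(
            game_type=block.game_type.value,
            block_index=block_index,
            trial_number=t,
            options=options,
            balance=state.balance if block.show_balance else None,
            last_response=last_response,
            last_outcome=last_outcome,
        )
        response, latency_ms = policy.respond(view, state.rng)
        if latency_ms <= 0:
            raise ValueError(f"policy {policy.policy_id} returned non-positive latency")
        state.clock_ms += int(round(latency_ms))
        rec = resolve_trial(state, response, block, block_index=block_index)
        last_response, last_outcome = rec.response, rec.outcome
        out.append(rec)
    return out


def run_session(
    design: ExperimentDesign,
    policy: "AgentPolicy",
    survey: Optional["SurveyResponse"] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    study_id: str = "p0",
) -> ParticipantSession:
    """Run one participant through the design: allocate an arm, play every
    block in order, and log between-block messages as events.

    Fully reproducible: the same (design, policy, seed) triple yields an
    identical record stream.
    """
    violations = validate_design(design)
    if violations:
        raise InvalidDesignError(violations)
    if rng is None:
        rng = np.random.default_rng(seed)

    from .design import allocate_arm

    arm_id = allocate_arm(design, rng)
    arm = next(a for a in design.arms if a.arm_id == arm_id)
    state = SessionState(study_id=study_id, arm_id=arm_id, balance=arm.starting_balance, rng=rng)
    for i, block in enumerate(arm.blocks):
        if block.pre_block_message:
            state.events.append(
                SessionEvent(study_id, state.clock_ms, "pre_block_message", block.pre_block_message)
            )
        run_block(state, block, policy, block_index=i)
    if arm.end_message:
        state.events.append(SessionEvent(study_id, state.clock_ms, "end_message", arm.end_message))
    return ParticipantSession(
        study_id=study_id,
        arm_id=arm_id,
        survey=survey,
        records=tuple(state.records),
        events=tuple(state.events),
    )


def block_outcome_mixture(
    block: GameBlockSpec,
    response_probs: Optional[dict[str, float]] = None,
) -> list[tuple[float, float, float]]:
    """Outcome mixture of a block as (frequency, win_probability, payout)
    per stratum, where payout includes the returned bet when applicable.

    Slot blocks mix over themes by display probability.  Choice blocks need a
    response distribution; when the options are exchangeable (identical
    probability and payout, as in a two-deck card game) none is required.
    """
    ret = block.bet_size if block.bet_returned_on_win else 0.0
    if block.game_type is GameType.slot:
        return [(t.display_probability, t.win_probability, t.win_amount + ret) for t in block.themes]
    options = block.options or ()
    if response_probs is None:
        distinct = {(o.win_probability, o.win_amount) for o in options}
        if len(distinct) != 1:
            raise ValueError(
                "options differ in probability/payout; supply response_probs"
            )
        p, amount = next(iter(distinct))
        return [(1.0, p, amount + ret)]
    total = sum(response_probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"response_probs sum to {total:g}, expected 1")
    return [
        (response_probs[o.option_id], o.win_probability, o.win_amount + ret)
        for o in options
    ]


def marginal_win_probability_of_block(
    block: GameBlockSpec, response_probs: Optional[dict[str, float]] = None
) -> float:
    """Theme- or response-weighted marginal win probability of a block."""
    return sum(f * p for f, p, _ in block_outcome_mixture(block, response_probs))


def expected_per_trial_change(
    block: GameBlockSpec, response_probs: Optional[dict[str, float]] = None
) -> float:
    """Expected balance change per trial: ``-bet + sum_j freq_j p_j payout_j``."""
    mix = block_outcome_mixture(block, response_probs)
    return -block.bet_size + sum(f * p * payout for f, p, payout in mix)


def expected_balance_trajectory(
    block: GameBlockSpec,
    starting_balance: float,
    response_probs: Optional[dict[str, float]] = None,
) -> np.ndarray:
    """Closed-form expected balance after each trial of a block.

    Returns an array of length ``n_trials + 1``: entry ``t`` is
    ``E[B_t] = B_0 + t * (-bet + p_bar * payout)``, with entry 0 the
    starting balance.
    """
    delta = expected_per_trial_change(block, response_probs)
    t = np.arange(block.n_trials + 1)
    return starting_balance + t * delta


def return_to_player(
    block: GameBlockSpec, response_probs: Optional[dict[str, float]] = None
) -> float:
    """Return-to-player rate: expected credits returned per credit wagered.

    RTP < 1 means the house wins on average; RTP = 1 is a fair game.
    """
    if block.bet_size == 0:
        raise ValueError("return_to_player undefined for bet_size 0")
    mix = block_outcome_mixture(block, response_probs)
    return sum(f * p * payout for f, p, payout in mix) / block.bet_size


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Long-format trial-log DataFrame with the canonical column order."""
    df = pd.DataFrame([r.__dict__ for r in records], columns=TRIAL_COLUMNS)
    return df
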