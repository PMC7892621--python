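"""Synthetic agent policies: mappings from game state to (response, latency).

Policies emulate crowdsourced participants playing the casino.  They are
stateless — sequential strategies read the previous trial from the
:class:`~casinolab.engine.GameView` — so a single policy object can serve a
whole cohort.  Latencies are drawn log-normal, calibrated so that a 96-trial
session takes about 10 minutes on average; a per-participant speed multiplier
(``latency_scale``) reproduces between-participant completion-time spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .engine import GameView

__all__ = [
    "AgentPolicy",
    "LatencyModel",
    "RandomResponder",
    "RepetitiveResponder",
    "WinStayLoseShift",
    "random_responder",
    "repetitive_responder",
    "win_stay_lose_shift",
]


@runtime_checkable
class AgentPolicy(Protocol):
    """Contract for synthetic participants."""

    policy_id: str

    def respond(
        self, view: GameView, rng: np.random.Generator
    ) -> tuple[str, float]:  # pragma: no cover - protocol
        """Return (response label, latency in ms > 0) for the current trial."""
        ...


@dataclass
class LatencyModel:
    """Log-normal per-trial response latency.

    Defaults give a per-trial mean of ~6.3 s, i.e. ~10 min over a 96-trial
    session; ``scale`` multiplies every draw (per-participant speed).
    """

    median_ms: float = 5550.0
    sigma: float = 0.5
    scale: float = 1.0

    def draw(self, rng: np.random.Generator) -> float:
        return max(1.0, self.scale * self.median_ms * math.exp(self.sigma * rng.standard_normal()))


class _BasePolicy:
    def __init__(self, policy_id: str, latency: LatencyModel | None = None):
        self.policy_id = policy_id
        self.latency = latency or LatencyModel()

    def _choose(self, view: GameView, rng: np.random.Generator) -> str:
        raise NotImplementedError

    def respond(self, view: GameView, rng: np.random.Generator) -> tuple[str, float]:
        if view.options == ("spin",):
            response = "spin"  # no-choice game: the only legal input
        else:
            response = self._choose(view, rng)
        return response, self.latency.draw(rng)


class RandomResponder(_BasePolicy):
    """Chooses the first option with probability ``p_left``, else uniformly
    among the remaining options; independent across trials."""

    def __init__(self, p_left: float = 0.5, latency: LatencyModel | None = None):
        if not 0.0 <= p_left <= 1.0:
            raise ValueError(f"p_left {p_left} not in [0, 1]")
        super().__init__(f"random(p_left={p_left:g})", latency)
        self.p_left = p_left

    def _choose(self, view: GameView, rng: np.random.Generator) -> str:
        if rng.random() < self.p_left:
            return view.options[0]
        rest = view.options[1:]
        return rest[int(rng.integers(len(rest)))] if len(rest) > 1 else rest[0]


class RepetitiveResponder(_BasePolicy):
    """Indiscriminate responder: always presses the same option.

    Emulates the poor-data-quality pattern of repetitive responding that the
    response-variation screen is designed to flag.
    """

    def __init__(self, fixed_option: str | None = None, latency: LatencyModel | None = None):
        super().__init__(f"repetitive({fixed_option or 'first'})", latency)
        self.fixed_option = fixed_option

    def _choose(self, view: GameView, rng: np.random.Generator) -> str:
        option = self.fixed_option or view.options[0]
        if option not in view.options:
            raise ValueError(f"fixed option {option!r} not legal; options: {view.options}")
        return option


class WinStayLoseShift(_BasePolicy):
    """Sequential strategy with outcome-dependent persistence.

    After a win, repeats the previous response with probability ``stay_prob``;
    after a loss, switches with probability ``shift_prob``; first trial (or
    when not repeating/switching applies) chooses uniformly among the other
    options.  With stay_prob = shift_prob = 0.5 this reduces to a fair random
    responder.  Provides non-trivial response-outcome sequential structure for
    checking that the mechanics audits are robust to agent behavior.
    """

    def __init__(
        self,
        stay_prob: float = 0.8,
        shift_prob: float = 0.8,
        latency: LatencyModel | None = None,
    ):
        for name, p in (("stay_prob", stay_prob), ("shift_prob", shift_prob)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} {p} not in [0, 1]")
        super().__init__(f"wsls(stay={stay_prob:g},shift={shift_prob:g})", latency)
        self.stay_prob = stay_prob
        self.shift_prob = shift_prob

    def _choose(self, view: GameView, rng: np.random.Generator) -> str:
        prev = view.last_response
        if prev is None or prev not in view.options:
            return view.options[int(rng.integers(len(view.options)))]
        others = [o for o in view.options if o != prev]
        if view.last_outcome == "win":
            stay = rng.random() < self.stay_prob
        else:
            stay = not (rng.random() < self.shift_prob)
        if stay or not others:
            return prev
        return others[int(rng.integers(len(others)))]


def random_responder(p_left: float = 0.5, **kwargs) -> RandomResponder:
    return RandomResponder(p_left, **kwargs)


def repetitive_responder(fixed_option: str | None = None, **kwargs) -> RepetitiveResponder:
    return RepetitiveResponder(fixed_option, **kwargs)


def win_stay_lose_shift(stay_prob: float, shift_prob: float, **kwargs) -> WinStayLoseShift:
    return WinStayLoseShift(stay_prob, shift_prob, **kwargs)
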