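"""Experiment design matrix: data model, validation, serialization, arm allocation.

The design matrix fully specifies a between-subjects casino experiment:
experimental arms with allocation percentages, and per arm an ordered list of
game blocks (roulette, card draw, or slot machine) with trial counts, bet
sizes, win amounts and win probabilities per choice option or per randomly
displayed visual theme, plus optional messages shown between blocks.
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

__all__ = [
    "GameType",
    "OptionSpec",
    "ThemeSpec",
    "GameBlockSpec",
    "ArmSpec",
    "ExperimentDesign",
    "DesignParseError",
    "InvalidDesignError",
    "validate_design",
    "allocate_arm",
    "load_design",
    "save_design",
    "replication_design",
]

_SUM_TOL = 1e-9


class GameType(str, enum.Enum):
    """The three supported game mechanics.

    ``roulette`` and ``card`` are binary-choice (instrumental) games with a
    per-option win probability; ``slot`` is a no-choice (Pavlovian-like) game
    whose win probability depends on the visual theme displayed on each trial.
    """

    roulette = "roulette"
    card = "card"
    slot = "slot"


class _Spec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class OptionSpec(_Spec):
    """One choice option of an instrumental game (e.g. a deck, or red/black)."""

    option_id: str
    win_probability: float
    win_amount: float


class ThemeSpec(_Spec):
    """One visual theme of a slot block, sampled independently per trial."""

    theme_id: str
    display_probability: float
    win_probability: float
    win_amount: float


class GameBlockSpec(_Spec):
    """An uninterrupted sequence of trials of one game type."""

    game_type: GameType
    n_trials: int
    bet_size: float
    bet_returned_on_win: bool = False
    show_balance: bool = True
    pre_block_message: Optional[str] = None
    options: Optional[tuple[OptionSpec, ...]] = None
    themes: Optional[tuple[ThemeSpec, ...]] = None

    @property
    def is_choice(self) -> bool:
        return self.game_type is not GameType.slot

    def legal_responses(self) -> list[str]:
        """Response labels the engine accepts for this block."""
        if self.game_type is GameType.slot:
            return ["spin"]
        return [o.option_id for o in self.options or ()]


class ArmSpec(_Spec):
    arm_id: str
    allocation_percent: float
    starting_balance: float
    blocks: tuple[GameBlockSpec, ...]
    end_message: Optional[str] = None


class ExperimentDesign(_Spec):
    design_id: str
    arms: tuple[ArmSpec, ...]
    rng_seed: Optional[int] = None


class DesignParseError(ValueError):
    """A design file could not be parsed into the design data model."""


class InvalidDesignError(ValueError):
    """A structurally parseable design violates design-matrix invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid design: " + "; ".join(violations))


def _check_probability(violations, where, name, value):
    if not 0.0 <= value <= 1.0:
        violations.append(f"{where}: {name} {value} not in [0, 1]")


def validate_design(design: ExperimentDesign) -> list[str]:
    """Check all design-matrix invariants; return human-readable violations.

    An empty list means the design is valid.  Violations are returned rather
    than raised so an administrator can see every problem at once.
    """
    v: list[str] = []
    if not design.arms:
        v.append("design: no arms")
        return v

    arm_ids = [a.arm_id for a in design.arms]
    if len(set(arm_ids)) != len(arm_ids):
        v.append("design: arm_ids not unique")
    total_alloc = sum(a.allocation_percent for a in design.arms)
    if abs(total_alloc - 100.0) > _SUM_TOL:
        v.append(f"design: allocations sum to {total_alloc:g}, expected 100")

    for arm in design.arms:
        where = f"arm {arm.arm_id}"
        if not 0.0 < arm.allocation_percent <= 100.0:
            v.append(f"{where}: allocation_percent {arm.allocation_percent:g} not in (0, 100]")
        if arm.starting_balance < 0:
            v.append(f"{where}: starting_balance {arm.starting_balance:g} < 0")
        for i, block in enumerate(arm.blocks):
            bw = f"{where} block {i} ({block.game_type.value})"
            if block.n_trials < 1:
                v.append(f"{bw}: n_trials {block.n_trials} < 1")
            if block.bet_size <= 0:
                v.append(f"{bw}: bet_size {block.bet_size:g} <= 0")
            if block.game_type is GameType.slot:
                if block.options:
                    v.append(f"{bw}: slot block must not define options")
                if not block.themes:
                    v.append(f"{bw}: slot block needs >= 1 theme")
                else:
                    tot = sum(t.display_probability for t in block.themes)
                    if abs(tot - 1.0) > _SUM_TOL:
                        v.append(f"{bw}: theme probabilities sum to {tot:g}, expected 1")
                    for t in block.themes:
                        tw = f"{bw} theme {t.theme_id}"
                        _check_probability(v, tw, "display_probability", t.display_probability)
                        _check_probability(v, tw, "win_probability", t.win_probability)
                        if t.win_amount < 0:
                            v.append(f"{tw}: win_amount {t.win_amount:g} < 0")
            else:
                if block.themes:
                    v.append(f"{bw}: choice block must not define themes")
                if not block.options or len(block.options) < 2:
                    v.append(f"{bw}: choice block needs >= 2 options")
                else:
                    ids = [o.option_id for o in block.options]
                    if len(set(ids)) != len(ids):
                        v.append(f"{bw}: option_ids not unique")
                    for o in block.options:
                        ow = f"{bw} option {o.option_id}"
                        _check_probability(v, ow, "win_probability", o.win_probability)
                        if o.win_amount < 0:
                            v.append(f"{ow}: win_amount {o.win_amount:g} < 0")
    return v


def allocate_arm(design: ExperimentDesign, rng: np.random.Generator) -> str:
    """Randomly allocate one participant to an arm.

    Draws an arm id with probability ``allocation_percent / 100``,
    independently on every call (the design-matrix analogue of randomized
    assignment at session start).
    """
    violations = validate_design(design)
    if violations:
        raise InvalidDesignError(violations)
    probs = np.array([a.allocation_percent for a in design.arms]) / 100.0
    idx = rng.choice(len(design.arms), p=probs)
    return design.arms[int(idx)].arm_id


def load_design(path: Union[str, Path]) -> ExperimentDesign:
    """Load a design from a YAML or JSON config file.

    YAML is a superset of JSON, so both formats are accepted by the same
    reader.  Malformed structure raises :class:`DesignParseError` naming the
    offending key.
    """
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise DesignParseError(f"{path}: not valid YAML/JSON: {exc}") from exc
    return design_from_dict(payload, source=str(path))


def design_from_dict(payload: dict, source: str = "<dict>") -> ExperimentDesign:
    if not isinstance(payload, dict):
        raise DesignParseError(f"{source}: top level must be a mapping")
    try:
        return ExperimentDesign.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise DesignParseError(f"{source}: invalid field '{loc}': {first['msg']}") from exc


def design_to_dict(design: ExperimentDesign) -> dict:
    return design.model_dump(mode="json", exclude_none=True)


def save_design(design: ExperimentDesign, path: Union[str, Path]) -> None:
    """Write a design config; format chosen by extension (.json else YAML)."""
    path = Path(path)
    payload = design_to_dict(design)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def replication_design() -> ExperimentDesign:
    """The bundled validation design: 40 card trials (two decks at p = 0.45,
    bet 10, win 20, bet not returned), 40 slot trials (themes S1/S2 displayed
    50/50 with win probabilities 0.5/0.2, win 20), then 16 extinction
    (p = 0) card trials."""
    from importlib.resources import files

    text = files("casinolab").joinpath("designs/validation_replication.yaml").read_text()
    return design_from_dict(yaml.safe_load(text), source="validation_replication.yaml")
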