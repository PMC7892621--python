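import numpy as np
import pytest

from casinolab.design import (
    ArmSpec,
    ExperimentDesign,
    GameBlockSpec,
    OptionSpec,
    ThemeSpec,
    replication_design,
)


def make_choice_block(
    p=0.45,
    n_trials=40,
    bet=10.0,
    win=20.0,
    bet_returned=False,
    game_type="card",
    option_ids=("deck_left", "deck_right"),
):
    return GameBlockSpec(
        game_type=game_type,
        n_trials=n_trials,
        bet_size=bet,
        bet_returned_on_win=bet_returned,
        options=tuple(
            OptionSpec(option_id=o, win_probability=p, win_amount=win) for o in option_ids
        ),
    )


def make_slot_block(
    theme_ps=(0.5, 0.2),
    display=(0.5, 0.5),
    n_trials=40,
    bet=10.0,
    win=20.0,
    bet_returned=False,
):
    themes = tuple(
        ThemeSpec(
            theme_id=f"S{i + 1}",
            display_probability=d,
            win_probability=p,
            win_amount=win,
        )
        for i, (d, p) in enumerate(zip(display, theme_ps))
    )
    return GameBlockSpec(
        game_type="slot",
        n_trials=n_trials,
        bet_size=bet,
        bet_returned_on_win=bet_returned,
        themes=themes,
    )


def make_design(blocks, starting_balance=1000.0, design_id="test"):
    return ExperimentDesign(
        design_id=design_id,
        arms=(
            ArmSpec(
                arm_id="main",
                allocation_percent=100.0,
                starting_balance=starting_balance,
                blocks=tuple(blocks),
            ),
        ),
    )


@pytest.fixture(scope="session")
def replication():
    return replication_design()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
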