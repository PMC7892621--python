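"""Mechanics audits: exact counting, the replacement check against a
hand-enumerated fixture, balance-trajectory conformance, and power against
injected violations."""

import numpy as np
import pandas as pd
import pytest

from casinolab.cohort import CohortSpec, generate_cohort
from casinolab.engine import TRIAL_COLUMNS, records_to_frame
from casinolab.mechanics import (
    balance_trajectory_analysis,
    marginal_win_probability,
    mechanics_report,
    observed_win_rates,
    replacement_independence_check,
)

from conftest import make_choice_block, make_slot_block


def _log(outcomes, study_id="p0", theme=None, bet=10.0, win=20.0, start=1000.0):
    """Build a minimal trial log from a W/L string."""
    rows = []
    balance = start
    for t, ch in enumerate(outcomes, start=1):
        won = ch == "W"
        credit = win if won else 0.0
        rows.append(
            {
                "study_id": study_id,
                "timestamp_ms": 1000 * t,
                "arm_id": "main",
                "game_type": "card" if theme is None else "slot",
                "block_index": 0,
                "trial_number": t,
                "balance_in": balance,
                "theme_id": theme,
                "response": "deck_left" if theme is None else "spin",
                "outcome": "win" if won else "loss",
                "outcome_credit": credit,
                "balance_out": balance - bet + credit,
            }
        )
        balance = balance - bet + credit
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@pytest.fixture(scope="module")
def replication_cohort(replication):
    return generate_cohort(replication, CohortSpec(seed=42))


class TestObservedWinRates:
    def test_counts_are_exact(self):
        df = pd.concat([_log("WWWLLLLLLL", theme="A")])
        res = observed_win_rates(df, stratify_by="theme_id")
        row = res["strata"].iloc[0]
        assert (row["n"], row["wins"], row["observed_p"]) == (10, 3, 0.3)
        assert row["ci_low"] < 0.3 < row["ci_high"]

    def test_extinction_block_rate_exactly_zero(self):
        res = observed_win_rates(_log("L" * 16), stratify_by="response")
        assert res["strata"].iloc[0]["observed_p"] == 0.0

    def test_order_invariance_within_strata(self, rng):
        df = _log("WLWWLLLWLW", theme="A")
        shuffled = df.sample(frac=1.0, random_state=0)
        a = observed_win_rates(df)["strata"]
        b = observed_win_rates(shuffled)["strata"]
        pd.testing.assert_frame_equal(a, b)

    def test_replication_cohort_theme_rates_within_3se(self, replication_cohort):
        df = records_to_frame([r for s in replication_cohort for r in s.records])
        slot = df[df["block_index"] == 1]
        strata = observed_win_rates(slot)["strata"].set_index("stratum")
        for theme, p_set in (("S1", 0.5), ("S2", 0.2)):
            row = strata.loc[theme]
            se = np.sqrt(p_set * (1 - p_set) / row["n"])
            assert abs(row["observed_p"] - p_set) < 3 * se


class TestReplacementCheck:
    def test_hand_enumerated_ten_trial_fixture(self):
        # sequence W L W W L L L W L W; by direct enumeration of the 9 pairs:
        # predecessors W at trials 2,4,5,9 -> following outcomes L,W,L,L (1/4)
        # predecessors L at trials 3,6,7,8,10 -> W,L,L,W,W (3/5)
        check = replacement_independence_check(_log("WLWWLLLWLW"))
        assert (check.n_after_win, check.wins_after_win) == (4, 1)
        assert (check.n_after_loss, check.wins_after_loss) == (5, 3)
        assert check.rate_after_win == pytest.approx(0.25)
        assert check.rate_after_loss == pytest.approx(0.6)

    def test_first_trial_of_each_participant_excluded(self):
        df = pd.concat([_log("WW", study_id="a"), _log("LL", study_id="b")])
        check = replacement_independence_check(df)
        assert check.n_after_win + check.n_after_loss == 2

    def test_constructed_alternation_is_detected(self):
        check = replacement_independence_check(_log("WL" * 20))
        assert check.rate_after_win == 0.0
        assert check.rate_after_loss == 1.0
        assert check.difference == -1.0
        assert check.p_value < 1e-6

    def test_single_trial_participants_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            replacement_independence_check(_log("W"))

    def test_replication_cohort_independence_within_3se(self, replication_cohort):
        df = records_to_frame([r for s in replication_cohort for r in s.records])
        check = replacement_independence_check(df[df["block_index"] == 0])
        for rate, n in (
            (check.rate_after_win, check.n_after_win),
            (check.rate_after_loss, check.n_after_loss),
        ):
            assert abs(rate - 0.45) < 3 * np.sqrt(0.45 * 0.55 / n)
        assert check.diff_ci[0] < 0.0 < check.diff_ci[1]


class TestMarginalWinProbability:
    def test_even_theme_mix(self):
        assert marginal_win_probability((0.5, 0.5), (0.5, 0.2)) == pytest.approx(0.35)

    def test_observed_theme_mix(self):
        assert marginal_win_probability((0.515, 0.485), (0.5, 0.2)) == pytest.approx(0.3545)

    def test_single_theme_is_identity(self):
        assert marginal_win_probability((1.0,), (0.2,)) == 0.2

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            marginal_win_probability((0.5, 0.4), (0.5, 0.2))


class TestBalanceTrajectory:
    def test_fair_game_discrepancy_ci_covers_zero(self, rng):
        # p * payout = bet: a martingale, so observed - expected centers on 0
        block = make_choice_block(p=0.5, win=10.0, bet_returned=True, n_trials=50)
        from casinolab.engine import SessionState, run_block
        from casinolab.policies import RandomResponder

        frames = []
        for i in range(50):
            state = SessionState(
                study_id=f"p{i}", arm_id="main", balance=1000.0, rng=rng
            )
            frames.append(records_to_frame(run_block(state, block, RandomResponder())))
        # momentary discrepancies random-walk within a participant, so use the
        # cluster-level CI (independent across the 50 participants)
        res = balance_trajectory_analysis(
            pd.concat(frames), block, 1000.0, cluster_robust=True
        )
        assert res.momentary_discrepancy_ci[0] < 0.0 < res.momentary_discrepancy_ci[1]
        assert res.expected_per_trial_change == 0.0

    def test_replication_cohort_mean_change_within_analytic_se(self, replication_cohort, replication):
        df = records_to_frame([r for s in replication_cohort for r in s.records])
        slot = df[df["block_index"] == 1]
        block = replication.arms[0].blocks[1]
        res = balance_trajectory_analysis(slot, block)
        # per-trial change is -10 + 20 * Bernoulli(0.35): SD ~ 9.54 credits
        sd = 20.0 * np.sqrt(0.35 * 0.65)
        assert abs(res.per_trial_change_mean - (-3.0)) < 3 * sd / np.sqrt(len(slot))
        assert res.implied_rtp == pytest.approx(0.7)

    def test_early_win_excess_skews_momentary_but_not_mean_change(self, replication_cohort, replication):
        # reorder each participant's outcomes so wins come first: the total
        # change is untouched but balances run above expectation mid-block
        df = records_to_frame([r for s in replication_cohort for r in s.records])
        slot = df[df["block_index"] == 1].copy()
        block = replication.arms[0].blocks[1]
        reordered = []
        for sid, grp in slot.groupby("study_id"):
            grp = grp.sort_values("trial_number").copy()
            order = np.argsort(grp["outcome"].to_numpy() != "win", kind="stable")
            for col in ("outcome", "outcome_credit", "theme_id"):
                grp[col] = grp[col].to_numpy()[order]
            change = -block.bet_size + grp["outcome_credit"].to_numpy()
            start = grp["balance_in"].iloc[0]
            bal_out = start + np.cumsum(change)
            grp["balance_in"] = bal_out - change
            grp["balance_out"] = bal_out
            reordered.append(grp)
        injected = pd.concat(reordered)
        base = balance_trajectory_analysis(slot, block)
        skewed = balance_trajectory_analysis(injected, block)
        assert skewed.per_trial_change_mean == pytest.approx(base.per_trial_change_mean)
        assert skewed.momentary_discrepancy_mean > base.momentary_discrepancy_mean
        assert skewed.momentary_discrepancy_mean > 0

    def test_mismatched_records_rejected(self):
        block = make_slot_block(n_trials=5)
        with pytest.raises(ValueError, match="game type"):
            balance_trajectory_analysis(_log("WLWLW"), block, 1000.0)


class TestPowerAgainstViolations:
    def test_wrong_win_probability_is_flagged(self, rng):
        # simulated at p = 0.55 against a programmed 0.45: Wilson CI excludes it
        n = 4000
        seq = "".join("W" if rng.random() < 0.55 else "L" for _ in range(n))
        res = observed_win_rates(_log(seq), stratify_by="response")
        row = res["strata"].iloc[0]
        assert not row["ci_low"] <= 0.45 <= row["ci_high"]

    def test_markov_dependence_is_flagged(self, rng):
        # first-order Markov outcomes with a 10-point persistence effect
        outcomes, prev = [], False
        for _ in range(4000):
            p = 0.50 if prev else 0.40
            prev = rng.random() < p
            outcomes.append("W" if prev else "L")
        check = replacement_independence_check(_log("".join(outcomes)))
        assert check.p_value < 0.001
        assert not check.diff_ci[0] <= 0.0 <= check.diff_ci[1]


class TestMechanicsReportPipeline:
    def test_audits_pass_across_seeds_on_engine_data(self, replication):
        # property: on engine-generated cohorts every audit sits inside 3 SE
        failures = 0
        for seed in range(20):
            sessions = generate_cohort(
                replication, CohortSpec(n_participants=26, seed=seed)
            )
            df = records_to_frame([r for s in sessions for r in s.records])
            slot = df[df["block_index"] == 1]
            strata = observed_win_rates(slot)["strata"].set_index("stratum")
            ok = True
            for theme, p_set in (("S1", 0.5), ("S2", 0.2)):
                row = strata.loc[theme]
                ok &= abs(row["observed_p"] - p_set) < 3 * np.sqrt(p_set * (1 - p_set) / row["n"])
            check = replacement_independence_check(df[df["block_index"] == 0])
            ok &= check.diff_ci[0] < 0.0 < check.diff_ci[1]
            failures += not ok
        assert failures <= 2

    def test_full_report_structure(self, replication_cohort, replication):
        report = mechanics_report(replication_cohort, replication)
        assert report.independence is not None
        assert report.trajectory is not None
        assert "block1_slot" in report.win_rates
        assert set(report.theme_display["theme_id"]) == {"S1", "S2"}
        d = report.to_dict()
        assert {"win_rates", "independence", "trajectory"} <= set(d)
        assert "block1_slot" in report.normality  # Shapiro-Wilk reported

    def test_unknown_block_indices_rejected(self, replication_cohort, replication):
        df = records_to_frame([r for s in replication_cohort for r in s.records])
        df["block_index"] = df["block_index"] + 5
        with pytest.raises(ValueError, match="block indices"):
            mechanics_report(df, replication)
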