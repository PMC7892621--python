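"""Game-mechanics audits: do logged outcomes match the programmed design?

Three audits, usable on any long-format trial log:

* observed vs programmed win rates, stratified by displayed theme or chosen
  option, with Wilson confidence intervals;
* sampling-with-replacement check: the win rate conditional on the previous
  trial's outcome (within participant, within block) should not depend on
  that outcome — a two-proportion z-test quantifies any dependence;
* balance-trajectory conformance: the observed mean balance per trial against
  the closed-form expectation from the programmed return-to-player rate, plus
  the distribution of per-trial balance changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .design import ExperimentDesign, GameBlockSpec, GameType
from .engine import (
    ParticipantSession,
    TrialRecord,
    expected_per_trial_change,
    records_to_frame,
    return_to_player,
)

__all__ = [
    "IndependenceCheck",
    "TrajectoryAnalysis",
    "MechanicsReport",
    "observed_win_rates",
    "replacement_independence_check",
    "marginal_win_probability",
    "balance_trajectory_analysis",
    "mechanics_report",
]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def observed_win_rates(
    records: Union[pd.DataFrame, Sequence[TrialRecord]],
    stratify_by: str = "theme_id",
    ci_level: float = 0.95,
) -> dict:
    """Observed win proportions per stratum with Wilson intervals.

    ``stratify_by`` is ``"theme_id"`` (slot audits) or ``"response"`` (choice
    audits).  Also returns the trial-indexed win-rate series (mean win rate at
    each trial number across participants) for trajectory-style plots.
    """
    df = _as_frame(records)
    if df.empty:
        raise ValueError("no trial records")
    if stratify_by not in ("theme_id", "response"):
        raise ValueError("stratify_by must be 'theme_id' or 'response'")
    wins = df["outcome"] == "win"
    strata = []
    for key, grp in df.groupby(stratify_by, dropna=False, observed=True):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"empty stratum {key!r} omitted")
            continue
        k = int((grp["outcome"] == "win").sum())
        lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="wilson")
        strata.append(
            {
                "stratum": key,
                "n": n,
                "wins": k,
                "observed_p": k / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    by_trial = (
        df.assign(win=wins)
        .groupby("trial_number")["win"]
        .mean()
        .rename("win_rate")
        .reset_index()
    )
    return {"strata": pd.DataFrame(strata), "by_trial": by_trial}


@dataclass(frozen=True)
class IndependenceCheck:
    """Win rates conditional on the preceding trial's outcome."""

    n_after_win: int
    wins_after_win: int
    rate_after_win: float
    ci_after_win: tuple[float, float]
    n_after_loss: int
    wins_after_loss: int
    rate_after_loss: float
    ci_after_loss: tuple[float, float]
    difference: float  # rate_after_win - rate_after_loss
    diff_ci: tuple[float, float]
    z: float
    p_value: float

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def replacement_independence_check(
    records: Union[pd.DataFrame, Sequence[TrialRecord]],
    ci_level: float = 0.95,
) -> IndependenceCheck:
    """Audit that outcome draws were made with replacement.

    Pairs each trial with its immediate predecessor *within participant and
    block* (the first trial of every participant-block contributes no pair),
    then compares P(win | previous win) with P(win | previous loss).  Under
    independent draws at constant p the difference is zero in expectation.
    """
    df = _as_frame(records).sort_values(["study_id", "block_index", "trial_number"])
    if df.empty:
        raise ValueError("no trial records")
    df = df.assign(win=(df["outcome"] == "win").astype(int))
    df["prev_win"] = df.groupby(["study_id", "block_index"])["win"].shift(1)
    paired = df.dropna(subset=["prev_win"])
    if paired.empty:
        raise ValueError("no consecutive trial pairs (need >= 2 trials per participant)")

    out: dict[str, float] = {}
    counts = {}
    for label, prev in (("after_win", 1), ("after_loss", 0)):
        sub = paired[paired["prev_win"] == prev]
        n, k = len(sub), int(sub["win"].sum())
        if n == 0:
            raise ValueError(f"no trials {label.replace('_', ' ')}: cannot condition")
        lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="wilson")
        counts[label] = (n, k)
        out[label] = (n, k, k / n, (float(lo), float(hi)))

    (n1, k1), (n0, k0) = counts["after_win"], counts["after_loss"]
    p1, p0 = k1 / n1, k0 / n0
    z, p_value = proportions_ztest([k1, k0], [n1, n0])
    se = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2)
    return IndependenceCheck(
        n_after_win=n1,
        wins_after_win=k1,
        rate_after_win=p1,
        ci_after_win=out["after_win"][3],
        n_after_loss=n0,
        wins_after_loss=k0,
        rate_after_loss=p0,
        ci_after_loss=out["after_loss"][3],
        difference=p1 - p0,
        diff_ci=(float(p1 - p0 - zcrit * se), float(p1 - p0 + zcrit * se)),
        z=float(z),
        p_value=float(p_value),
    )


def marginal_win_probability(
    theme_freqs: Sequence[float], theme_ps: Sequence[float]
) -> float:
    """Mixture win probability ``sum_j freq_j * p_j`` over displayed themes."""
    freqs = np.asarray(theme_freqs, dtype=float)
    ps = np.asarray(theme_ps, dtype=float)
    if freqs.shape != ps.shape:
        raise ValueError("theme_freqs and theme_ps must have the same length")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"theme frequencies sum to {freqs.sum():g}, expected 1")
    return float(freqs @ ps)


@dataclass(frozen=True)
class TrajectoryAnalysis:
    """Observed vs expected balance development over a block."""

    by_trial: pd.DataFrame  # trial_number, observed_mean, expected, discrepancy
    momentary_discrepancy_mean: float
    momentary_discrepancy_ci: tuple[float, float]
    momentary_discrepancy_skew: float
    per_trial_change_mean: float
    per_trial_change_sd: float
    per_trial_change_ci: tuple[float, float]
    expected_per_trial_change: float
    implied_rtp: float
    n_trials_analyzed: int

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "by_trial"
        }
        d = {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}
        d["by_trial"] = self.by_trial.to_dict(orient="records")
        return d


def _mean_ci(values: np.ndarray, level: float) -> tuple[float, tuple[float, float]]:
    m = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    z = stats.norm.ppf(0.5 + level / 2)
    return m, (m - z * se, m + z * se)


def balance_trajectory_analysis(
    records: Union[pd.DataFrame, Sequence[TrialRecord]],
    block: GameBlockSpec,
    starting_balance: Optional[float] = None,
    ci_level: float = 0.95,
    cluster_robust: bool = False,
) -> TrajectoryAnalysis:
    """Compare observed balance development with the programmed expectation.

    The expected balance after trial t is the closed form
    ``B_0 + t * (-bet + p_bar * payout)``, anchored by default at each
    participant's balance entering the block (``starting_balance`` overrides
    this with a common anchor).  Reports the per-trial observed mean balance
    and its discrepancy from expectation, the distribution of momentary
    discrepancies (an accumulated measure, so early fluctuations propagate
    and can skew it), and the mean per-trial balance change with CI.

    With ``cluster_robust=True`` the CIs are computed over per-participant
    means (for real data where outcomes may not be independent across trials
    of one participant); by default trials are treated as i.i.d., which is
    exact for engine-generated data.
    """
    df = _as_frame(records)
    if df.empty:
        raise ValueError("no trial records")
    if (df["game_type"] != block.game_type.value).any():
        raise ValueError("records do not match the block's game type")
    if df["trial_number"].max() > block.n_trials:
        raise ValueError("records contain trial numbers beyond the block length")

    delta = expected_per_trial_change(block)
    if starting_balance is None:
        first = df.loc[df.groupby("study_id")["trial_number"].idxmin()]
        anchors = (
            first.set_index("study_id")["balance_in"]
            - (first.set_index("study_id")["trial_number"] - 1) * delta
        )
        anchor = df["study_id"].map(anchors).to_numpy()
    else:
        anchor = np.full(len(df), float(starting_balance))
    df = df.assign(
        expected=anchor + df["trial_number"].to_numpy() * delta,
        change=df["balance_out"] - df["balance_in"],
    )
    df["discrepancy"] = df["balance_out"] - df["expected"]

    by_trial = (
        df.groupby("trial_number")
        .agg(observed_mean=("balance_out", "mean"), expected=("expected", "first"))
        .reset_index()
    )
    by_trial["discrepancy"] = by_trial["observed_mean"] - by_trial["expected"]

    if cluster_robust:
        disc = df.groupby("study_id")["discrepancy"].mean().to_numpy()
        chg = df.groupby("study_id")["change"].mean().to_numpy()
    else:
        disc = df["discrepancy"].to_numpy()
        chg = df["change"].to_numpy()
    disc_mean, disc_ci = _mean_ci(disc, ci_level)
    chg_mean, chg_ci = _mean_ci(chg, ci_level)

    return TrajectoryAnalysis(
        by_trial=by_trial,
        momentary_discrepancy_mean=disc_mean,
        momentary_discrepancy_ci=disc_ci,
        momentary_discrepancy_skew=float(stats.skew(disc)) if len(disc) > 2 else 0.0,
        per_trial_change_mean=chg_mean,
        per_trial_change_sd=float(np.std(df["change"].to_numpy(), ddof=1)),
        per_trial_change_ci=chg_ci,
        expected_per_trial_change=expected_per_trial_change(block),
        implied_rtp=return_to_player(block),
        n_trials_analyzed=len(df),
    )


@dataclass(frozen=True)
class MechanicsReport:
    """Full audit of a cohort log against its design."""

    win_rates: dict  # per audited block: strata DataFrame + by-trial series
    independence: Optional[IndependenceCheck]
    trajectory: Optional[TrajectoryAnalysis]
    theme_display: Optional[pd.DataFrame]
    normality: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"win_rates": {}, "normality": self.normality}
        for name, res in self.win_rates.items():
            out["win_rates"][name] = {
                "strata": res["strata"].to_dict(orient="records"),
                "by_trial": res["by_trial"].to_dict(orient="records"),
            }
        out["independence"] = self.independence.to_dict() if self.independence else None
        out["trajectory"] = self.trajectory.to_dict() if self.trajectory else None
        out["theme_display"] = (
            self.theme_display.to_dict(orient="records")
            if self.theme_display is not None
            else None
        )
        return out


def mechanics_report(
    records: Union[pd.DataFrame, Sequence[ParticipantSession]],
    design: ExperimentDesign,
    arm_id: Optional[str] = None,
) -> MechanicsReport:
    """Run every applicable audit of a cohort log against a design.

    Per block: slot blocks get theme-stratified win rates, theme display
    frequencies and the balance-trajectory analysis; constant-probability
    choice blocks get the replacement-independence check.  A Shapiro-Wilk
    statistic on per-participant slot win rates is reported descriptively
    (no pass/fail threshold is imposed on normality).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [r for s in records for r in s.records]
        df = records_to_frame(rows)
    arm = design.arms[0] if arm_id is None else next(a for a in design.arms if a.arm_id == arm_id)
    if arm_id is not None:
        df = df[df["arm_id"] == arm_id]
    if df.empty:
        raise ValueError("no trial records for the requested arm")

    known_blocks = set(range(len(arm.blocks)))
    logged_blocks = set(df["block_index"].unique())
    if not logged_blocks <= known_blocks:
        raise ValueError(
            f"log references block indices {sorted(logged_blocks - known_blocks)} "
            f"absent from design {design.design_id!r}"
        )

    win_rates: dict = {}
    independence = None
    trajectory = None
    theme_display = None
    normality: dict = {}
    for i, block in enumerate(arm.blocks):
        sub = df[df["block_index"] == i]
        if sub.empty:
            continue
        name = f"block{i}_{block.game_type.value}"
        if block.game_type is GameType.slot:
            win_rates[name] = observed_win_rates(sub, stratify_by="theme_id")
            themes = sub["theme_id"].value_counts(normalize=True).rename("display_freq")
            theme_display = themes.reset_index().rename(columns={"index": "theme_id"})
            trajectory = balance_trajectory_analysis(sub, block)
            per_part = (
                sub.assign(win=sub["outcome"] == "win").groupby("study_id")["win"].mean()
            )
            if len(per_part) >= 3 and per_part.nunique() > 1:
                w, p = stats.shapiro(per_part)
                normality[name] = {"shapiro_w": float(w), "p_value": float(p)}
        else:
            win_rates[name] = observed_win_rates(sub, stratify_by="response")
            ps = {o.win_probability for o in block.options}
            if independence is None and len(ps) == 1 and 0.0 < next(iter(ps)) < 1.0:
                independence = replacement_independence_check(sub)
    return MechanicsReport(
        win_rates=win_rates,
        independence=independence,
        trajectory=trajectory,
        theme_display=theme_display,
        normality=normality,
    )
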