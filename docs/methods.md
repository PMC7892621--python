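# Methods

This note documents the statistical models, calibrations and design choices
behind `casinolab`: what the engine computes, what the synthetic cohort
emulates (and does not), and the numerical conventions the audits use.

## 1. Game engine

**Outcome model.** Each trial is an independent Bernoulli draw against the
win probability of the chosen option (instrumental games) or of the visual
theme sampled for that trial (slot). Themes are sampled independently per
trial from their display probabilities — sampling with replacement, like
real casino draws. One PCG64 stream drives a whole session (theme draws,
outcome draws, policy choices, latencies), seeded per participant from a
`SeedSequence` spawn of the cohort seed, so cohorts are reproducible without
coupling participants.

**Balance accounting.** `balance_in` is the pre-bet balance. On every trial
`balance_out = balance_in − bet + credit`, with `credit = 0` on losses and
`credit = win_amount (+ bet if bet_returned_on_win)` on wins. The bundled
replication design uses the validation-era convention (bet *not* returned);
the returned-bet convention is a per-block flag since both exist in
practice and only the return-to-player rate changes.

**Closed forms.** With mixture components `(f_j, p_j, π_j)` (display/response
frequency, win probability, payout):

* expected per-trial change `δ = −b + Σ f_j p_j π_j`;
* expected balance `E[B_t] = B_0 + t·δ` (exact — the balance is a sum of
  i.i.d. per-trial increments);
* `RTP = Σ f_j p_j π_j / b`, undefined at `b = 0`.

For choice blocks whose options differ in probability or payout, these
require an explicit response distribution; when options are exchangeable
(the two-deck card game) no distribution is needed.

**Conventions.** Timestamps are integer milliseconds of simulated session
time; the clock advances by policy-drawn latencies. Messages between blocks
are typed events, not trials. `show_balance` only hides the balance from
the agent's view; it is always logged. The trial log records the 12
long-format columns (`study_id, timestamp_ms, arm_id, game_type,
block_index, trial_number, balance_in, theme_id, response, outcome,
outcome_credit, balance_out`).

**Replication design.** 40 card trials (two decks, p = 0.45, bet 10,
win 20), 40 slot trials (themes S1/S2 displayed 50/50, win p 0.5/0.2,
win 20), 16 extinction card trials (p = 0). The starting balance is not
dictated by the setup being replicated; the bundled design uses 1000
credits, large enough that no 96-trial session can go negative.

## 2. Synthetic participants

**Policies.** Stateless mappings from the visible game state to a response:
`RandomResponder(p_left)` (independent choices), `RepetitiveResponder`
(always the same option — the indiscriminate pattern quality screening
exists to catch), and `WinStayLoseShift(stay, shift)` (sequential
dependence, used to check the audits are robust to structured behavior; at
0.5/0.5 it reduces to the fair random responder). All policies emit "spin"
on slot trials, where the platform offers no choice. Latencies are
log-normal (median 5.55 s, σ = 0.5), calibrated so a 96-trial session takes
~10 minutes; a per-participant log-normal speed multiplier (σ = 0.3, unit
mean) reproduces realistic between-participant spread in completion times.
The default cohort mixes 94% random and 6% repetitive responders — the
share of indiscriminate responders observed in the validation sample this
package replicates.

**Survey generator.** Emulates a crowdsourced general-population gambling
sample, with margins calibrated once against that validation sample
(n = 101): age N(34.89, 10.32²) clipped to 18–80; 65% male; gambling
frequency (ordinal 0–4) with probabilities 10/43/23/22/3 out of 101.
Frequency 0 means no last-year gambling: those participants select no
gambling types and have PGSI total 0 by construction.

The PGSI total is a hurdle: with conditional mean `μ_f = base + slope·f`
(defaults base 0, slope 2.60), a participant is non-zero with probability
63/91 and then draws `1 + NB(ν_f, r)` truncated at 27. The NB mean `ν_f` is
solved numerically *so that the truncated hurdle mean equals `μ_f`
exactly* — this makes the planted slope an unbiased linear-regression
estimand and makes `analytic_pgsi_mean()` exact. Dispersion r = 3.0
reproduces the target SD (analytic 5.51 vs. calibration target 5.46),
giving the required "excess zeros with a long tail" shape.

Item scores are a random composition of the total into nine 0–3 items: each
point goes to a currently-lowest item (balanced) or, with probability
`item_scatter`, to a uniformly random unfilled item. The items therefore
share the single latent "total severity" factor; `item_scatter = 0.25` is
the free consistency calibration, chosen to put Cronbach's α near 0.95.
Because the composition preserves the total exactly, scoring the generated
items recovers the generated totals (round-trip property).

Type counts are `min(Poisson(exp(0.205 + 0.34·f)), available)` for
gamblers, with the intercept fixed from the calibration sample's mean type
count among gamblers (≈2.41); which specific types are selected follows the
per-type endorsement frequencies (without replacement, conditionally
independent of severity given frequency — only margins were available to
calibrate against).

**What the generator does not emulate.** Real crowdsourced data have
participant-level heterogeneity the generator omits: choice preferences
vary across people (the real variation-score SD, ~18%, exceeds the binomial
~8% our homogeneous random responders produce), item responses are not an
exchangeable composition of the total, survey and play behavior are
uncorrelated here, and there is no dropout, no learning, and no reaction to
messages. Passing audits on synthetic cohorts demonstrates that the
*machinery* is correct and calibrated, not that real populations behave
this way.

## 3. Quality screening

The response-variation score is the percentage of choice-block trials on
which a designated reference option (the block's first option) was chosen.
A directional proportion is used rather than a majority-option proportion;
the two differ only in labeling and the 10–90% flag band is symmetric, so
flagging is convention-independent. Bounds are inclusive: exactly 10% or
90% is not flagged ("outside the range" read strictly). Thresholds are
configurable because the right band is setup-dependent; 10/90 are the
screening defaults. For a fair random responder over 40 trials the flag
probability is the exact binomial tail P(Bin(40, ½) ∉ [4, 36]) ≈ 2·10⁻⁸, so
flags are effectively specific to indiscriminate responding. Completion
times are summarized (mean/SD/min/max, counts above 15 and 20 min) but
never used for exclusion — long durations can reflect pauses between
phases, not poor data.

## 4. Mechanics audits

* **Win rates:** exact counts per stratum (theme or option) with Wilson
  95% intervals; a trial-indexed win-rate series is returned for plots.
* **Replacement check:** trials are paired with their immediate predecessor
  within participant and block (never chained across participants or
  blocks; the first trial of each participant-block is excluded), then
  P(win | previous win) and P(win | previous loss) are compared with a
  pooled two-proportion z-test and an unpooled normal CI on the difference.
* **Balance trajectory:** the closed-form expectation is anchored at each
  participant's balance entering the block (a scalar anchor can be forced),
  and the audit reports per-trial observed mean balance vs. expectation,
  the momentary-discrepancy distribution (mean, CI, skew — note the
  discrepancy is an accumulated quantity, so a chance run of early wins
  skews it even when per-trial changes are exactly on target), and the mean
  per-trial balance change with CI.
* CIs treat trials as i.i.d. by default, which is exact for
  engine-generated data; `cluster_robust=True` aggregates per participant
  first for real data or for accumulated quantities. A Shapiro–Wilk
  statistic on per-participant slot win rates is reported descriptively,
  with no pass/fail threshold — normality of sample rates is a qualitative
  check.

## 5. Psychometrics

* **Alpha:** the classical variance-ratio formula. The default CI is
  Feldt's F interval with (n−1, (n−1)(k−1)) degrees of freedom; a
  nonparametric bootstrap (participant resampling, percentile bounds) is
  the alternative. Coverage of the Feldt interval is verified by simulation
  at ~95% on one-factor Gaussian data. Alpha is also recomputed on the
  subsample with PGSI total > 0, since an all-zero floor can inflate
  internal consistency.
* **Parallel analysis:** eigenvalues of the item *correlation* matrix
  (standard for ordinal screening items; polychoric correlation is out of
  scope) against the 95th percentile of eigenvalues from standard-normal
  resamples of the same shape (1000 by default; a column-permutation null
  is available). Counting stops at the first non-exceeding eigenvalue, so
  the retained count is monotone in the percentile.
* **Associations:** OLS point estimates for PGSI ~ no-gambling indicator,
  PGSI ~ type count, and PGSI ~ frequency, with **HC3 robust standard
  errors** — severity totals are floor-censored counts whose variance grows
  with the mean, and homoskedastic SEs demonstrably undercover (≈87% vs.
  ≈95% at n = 101 in the package's own recovery simulations). The type
  count ~ frequency model is a Poisson GLM (log link, IRLS), fitted among
  participants reporting any gambling: non-gamblers' type counts are
  structural zeros created by the skip pattern, not Poisson variation, and
  including them would bias the slope. All p-values are two-sided Wald.

## 6. Problem sizes and tolerances

Stochastic tests use 3-standard-error bands around programmed values
(≈99.7% per check), with repetition-based checks (e.g. 20-seed audit
sweeps, 500-replicate coverage studies, 200-replicate parameter recovery at
n = 101) sized so the whole suite and the acceptance script each run in a
couple of minutes on one core. Monte-Carlo oracles (e.g. the 10⁵-session
balance-trajectory check) are vectorized numpy simulations independent of
the engine code path they validate. Degenerate inputs fail loudly: empty
cohorts, zero bet sizes, constant predictors, zero total-score variance and
out-of-vocabulary responses all raise errors naming the offending quantity.

## 7. Known limitations

Only one win probability/amount per option or theme (no multi-outcome
jackpot tables, no losses-disguised-as-wins accounting); no web UI or
crowdsourcing integration — the design matrix is a YAML/JSON file and the
interface is the library plus CLI; the variation score presumes a
binary-choice block; per-item PGSI calibration is anchored only to
total-score moments, as no item-level margins were available.
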