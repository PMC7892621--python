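# casinolab

A headless, fully seeded **simulated online casino** for behavioral gambling
research, together with the validation analytics such a platform needs before
it can be trusted: game-mechanics audits, behavioral data-quality screening,
and survey psychometrics.

Experimental studies of gambling behavior — reinforcement schedules,
extinction, responsible-gambling messaging — need a casino whose games *look*
like real gambling but whose probabilities, bets, payouts and messages are
fully under experimental control. `casinolab` provides the computational core
of such a platform: a design matrix drives trial-by-trial Bernoulli gambles
logged in long format, synthetic participants (behavioral policies plus a
calibrated survey generator) stand in for crowdsourced workers, and audit
modules verify that the simulated mechanics behave like honest casino games.

## The model

Every gamble is an independent Bernoulli draw (sampling **with
replacement**, as in real casino play). A game block is defined by a bet
size `b`, a win amount `w`, and win probabilities: per choice option for
instrumental games (roulette, a two-deck card game), or per randomly
displayed visual theme for the no-choice slot machine. With theme display
frequencies `f_j` and win probabilities `p_j`, the marginal win probability
is

    p̄ = Σ_j f_j · p_j

and with payout `π = w` (plus `b` when bets are returned on wins):

    return to player   RTP = p̄ · π / b
    expected balance   E[B_t] = B_0 − t · (b − p̄ · π)

The audits compare observed win rates (Wilson CIs), conditional win rates
after wins vs. losses (two-proportion z-test of the with-replacement
property), and observed balance trajectories against these closed forms.
Data-quality screening computes each participant's response-variation score
(% of choice trials on the reference option) and flags scores outside
10–90%. Survey analytics cover Cronbach's α with Feldt or bootstrap CIs,
Horn's parallel analysis, and regression models linking problem-gambling
severity (PGSI) to gambling frequency and breadth.

## Worked example

Simulate the bundled validation design (101 participants; 40 card-draw
trials at p = 0.45, 40 slot trials with themes S1/S2 shown 50/50 at win
probabilities 0.5/0.2, 16 extinction trials; bet 10, win 20), then audit it:

```python
from casinolab import (
    replication_design, generate_cohort, CohortSpec,
    cohort_quality_report, mechanics_report, psychometrics_report,
)
from casinolab.io import survey_to_frame

design = replication_design()
sessions = generate_cohort(design, CohortSpec(n_participants=101, seed=1))

quality = cohort_quality_report(sessions, design)
mech = mechanics_report(sessions, design)
psy = psychometrics_report(survey_to_frame([s.survey for s in sessions]), seed=1)
```

Output (seed 1):

```
trials logged: 9696
flagged 3/101 participants (variation mean 49.6%)
theme S1: win rate 50.9% (n=2037)
theme S2: win rate 20.0% (n=2003)
card game: P(win|prev win) = 43.8%, P(win|prev loss) = 44.7%
mean balance change -2.89 credits/trial (programmed -3.0, RTP 0.7)
PGSI alpha 0.95 (95% CI 0.94-0.96), 1 component(s)
```

Reading this: the slot themes hit their programmed 50%/20% win rates within
sampling error; the card game's win rate does not depend on the previous
outcome (draws are made with replacement); the balance falls by the ~3
credits per trial implied by the 0.7 return-to-player rate; the screening
flags about the expected share of indiscriminate responders (the cohort
plants 6%); and the synthetic PGSI items behave as a highly consistent
one-factor scale.

The same pipeline is available from a shell:

```bash
casinolab make-design --out design.yaml
casinolab simulate --design design.yaml --n 101 --seed 1 --out run/
casinolab validate-mechanics --log run/trials.csv --design design.yaml --out mech.json
casinolab quality --log run/trials.csv --design design.yaml --out quality.json
casinolab psychometrics --survey run/survey.csv --out psy.json
```

## Layout

| module | contents |
| --- | --- |
| `casinolab.design` | design-matrix data model, validation, YAML/JSON I/O, arm allocation |
| `casinolab.engine` | trial resolution, session runner, closed-form expectations |
| `casinolab.policies` | synthetic agent policies (random, repetitive, win-stay/lose-shift) |
| `casinolab.cohort` | survey generator and full-cohort simulation |
| `casinolab.survey` | PGSI scoring, gambling frequency/type coding |
| `casinolab.quality` | response-variation screening, completion-time summaries |
| `casinolab.mechanics` | win-rate, independence and balance-trajectory audits |
| `casinolab.psychometrics` | Cronbach's α, parallel analysis, association models |
| `casinolab.io` / `casinolab.cli` | CSV/JSON formats and the `casinolab` command |

See `docs/methods.md` for the statistical details and design choices.
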