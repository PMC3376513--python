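# stepadvice

Pedometer-based, computer-tailored step advice — and the statistics to
evaluate it in a two-arm trial.

`stepadvice` re-implements, as a reusable Python library and CLI, an
intervention engine that turns a 7-day pedometer log and a short diagnostic
questionnaire into individualized written advice built around the
**10,000 steps/day** goal, together with the evaluation layer needed to
analyze such an intervention in a randomized two-condition,
two-timepoint trial. It is aimed at physical-activity and eHealth
researchers who want to study, extend, or power such computer-tailored
interventions without access to the original web system or trial data.

## What it does

**Step-log processing** (`stepadvice.steplog`). Daily records hold pedometer
steps plus non-ambulatory activities. Each day is credited 150 steps per
minute of biking or swimming, truncated at 20,000 steps/day (to limit
unrealistically high averages), and averaged over valid days; at least 5
valid registration days are required.

**Tailoring engine** (`stepadvice.tailoring`). Participants are classified
into a transtheoretical-model stage of change from their goal status,
intention, and goal tenure:

| goal status | intention / tenure | stage | address mode |
|---|---|---|---|
| below goal | no intention | precontemplation | impersonal ("people could…") |
| below goal | within 6 months | contemplation | personal ("you could…") |
| below goal | within 1 month | preparation | decisive ("you should…") |
| at goal | < 6 months at goal | action | supportive ("you do…") |
| at goal | ≥ 6 months at goal | maintenance | supportive |

The advice document is assembled in a fixed order — introduction, normative
feedback (measured level vs. the goal), progress feedback (second and later
requests), a goal schedule of weekly +500 or +1000 steps/day targets
(below-goal stages only), tips per life domain (work, household, gardening,
leisure, transport), and psychosocially gated information blocks (barriers,
self-efficacy, walking buddy, …). Messages come from an editable YAML
library selected through if–then predicates; every emitted message carries
an audit trace of the rule that admitted it. Rendering to text, Markdown, or
HTML is deterministic.

**Trial statistics** (`stepadvice.trialstats`). Welch two-sample t tests
with Satterthwaite df,

t = (x̄₁ − x̄₂) / √(s₁²/n₁ + s₂²/n₂),

uncorrected Pearson χ² tests, log transformation for skewed minutes/day
outcomes, a condition × time mixed repeated-measures ANOVA (interaction and
time F on 1, N−2 df with per-arm change and 95% CI), baseline-carried-forward
intent-to-treat imputation, and table builders producing the familiar
"mean (SD) per arm, statistic, p" layouts.

**Synthetic cohorts** (`stepadvice.synthcohort`). A seeded generator of
step logs and two-arm cohorts whose baseline marginals, dropout process
(~25%), baseline–post correlation (0.7), and condition effect are
configurable — so the entire pipeline is testable end-to-end with no
external data.

## Worked example

Generate a synthetic 7-day log and questionnaire, then tailor:

```bash
stepadvice summarize-log log2.csv
```

```
participant	log2
mean_steps_per_day	8967.1
n_valid_days	7
any_truncated	False
```

```bash
stepadvice tailor q2.json log2.csv -o advice2.txt
# INFO stepadvice: stage=preparation gap_to_goal=1033 sections=6 -> advice2.txt
```

The participant averages 8,967 steps/day, intends to take more steps within
a month (→ preparation stage, decisive address mode), and is requesting
advice for the second time. The advice file begins:

```
Your step level and the 10,000 steps goal
-----------------------------------------
Your pedometer registration shows an average of 8,967 steps a day. That is
1,033 steps short of the goal of 10,000 steps a day.

Your progress since your previous advice
----------------------------------------
Last time your average was 7,400 steps a day; now it is 8,967. That is an
increase of 1,567 steps a day - a positive evolution, well done!

A schedule toward the goal
--------------------------
...
Increasing by 500 steps per week (3 week(s)):
  week 1: 9467 steps/day
  week 2: 9967 steps/day
  week 3: 10000 steps/day
```

The gap (1,033), the progress category (an increase of 1,567 > the 500-step
stable band → "positive evolution"), and the ⌈(10,000 − 8,967)/500⌉ = 3-week
schedule are all computed from the log.

For the trial side:

```bash
stepadvice simulate spec.yaml -o sim          # cohort CSV from a spec
stepadvice analyze sim_cohort.csv --itt -o t  # baseline/dropout/effects tables
```

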