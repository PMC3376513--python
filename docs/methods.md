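# Methods note

This note documents the computational model behind `stepadvice`: how raw
pedometer logs become a step level, how the step level and questionnaire
become tailored advice, how trial outcomes are analyzed, and how the
synthetic-cohort generator is constructed. Defaults live in
`stepadvice.config.RunConfig` and can be overridden per call or via YAML.

## 1. Step-log processing

A log is a sequence of daily records, each with an optional pedometer count
and zero or more non-ambulatory activities (kind, minutes).

1. **Step conversion.** Minutes of biking or swimming are converted at
   **150 steps per minute** and added to the day's count, because a
   waist-worn pedometer underregisters these activities. Conversion happens
   *before* truncation, so a heavy biking day can hit the cap.
2. **Truncation.** Daily totals are truncated at **20,000 steps/day** to
   keep extreme days from dominating the weekly mean.
3. **Validity.** A day is valid if it has a recorded count. At least
   **5 valid days** (of the intended 7) are required; fewer raises
   `InsufficientDataError`.
4. **Step level** = mean of adjusted, truncated steps over valid days.
   Goal attainment is boundary-inclusive: mean ≥ goal (default **10,000
   steps/day**) counts as "at goal".

| parameter | default | unit | rationale |
|---|---|---|---|
| `goal` | 10,000 | steps/day | step-count counterpart of ≥30 min/day moderate activity |
| `conversion_rate` | 150 | steps/min | pedometer-equivalent credit for biking/swimming |
| `cap` | 20,000 | steps/day | robustness against implausible daily totals |
| `min_valid_days` | 5 | days | minimum for a stable weekly mean |

## 2. Stage classification and tailoring

Stages follow the transtheoretical model, assigned from goal status,
stated intention, and time at goal:

| below goal? | intention / tenure | stage |
|---|---|---|
| yes | none | precontemplation |
| yes | within 6 months | contemplation |
| yes | within 1 month | preparation |
| no | at goal < 6 months | action |
| no | at goal ≥ 6 months | maintenance |

A below-goal participant with missing intention is a validation error (the
rule table is otherwise total; a property test enumerates the full grid).
Each stage maps to an address mode — impersonal, personal, decisive, or
supportive — which selects the phrasing variant of every tip.

**Document assembly order** (fixed, deterministic): introduction →
normative feedback → progress feedback (request ≥ 2 only) → goal schedules
(below-goal stages only) → tips per life domain (work, household,
gardening, leisure, transport) → information blocks.

- **Normative feedback** reports the rounded step level and the gap to the
  goal.
- **Progress feedback** compares to the previous request's level; a change
  within ± **500 steps/day** (`stable_band`) is "stable", above/below is
  positive/negative.
- **Goal schedules**: for each configured increment (default **500 and
  1000 steps/week**), weekly targets `baseline + k·increment`, with the
  final week capped at the goal; empty when already at goal.
- **Psychosocial gating**: 1–5 scales; the barriers block requires
  perceived barriers ≥ **4**, the self-efficacy block requires
  self-efficacy ≤ **2**.

Messages come from a YAML library; each entry carries a section, optional
stage restriction, optional `when` predicates (a small comparison language
over the tailoring context), and a `str.format` template rendered strictly
(a missing placeholder is a `RenderError`, not silent text). Every selected
message keeps its entry id, stage, and predicates as an audit trail. The
five stage introductions are a canonical corpus reproduced verbatim; all
other texts are editable placeholders written in the same register.

## 3. Trial statistics

- **Welch t** from group summaries: t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂) with
  Welch–Satterthwaite df (a pooled-variance Student variant is available
  behind a flag). Cross-checked against `scipy.stats.ttest_ind_from_stats`.
- **Pearson χ²** on r×c contingency tables without continuity correction
  (`scipy.stats.chi2_contingency(correction=False)`).
- **Condition × time mixed ANOVA** (2 arms × 2 timepoints). With one
  between factor at two levels and two timepoints, the Type III
  interaction and time tests reduce exactly to change-score contrasts:
  with per-arm mean changes d̄₁, d̄₂ and pooled change variance s²ₚ,
  F_interaction = (d̄₁−d̄₂)² / (s²ₚ(1/n₁+1/n₂)) and
  F_time = ((d̄₁+d̄₂)/2)² / (s²ₚ(1/n₁+1/n₂)/4), both on (1, N−2) df.
  This equivalence is verified in the tests against a brute-force
  sums-of-squares decomposition and against `pingouin.mixed_anova`.
  Per-arm change and its 95% CI use the one-sample t interval on change
  scores.
- **Skewed outcomes.** Minutes/day outcomes (walking, total physical
  activity) are analyzed on the log(x+1) scale; reported changes remain on
  the raw scale.
- **Intent-to-treat** = baseline observation carried forward (BOCF) for
  participants missing post measurements; the operation is idempotent and
  flags imputed values. BOCF is conservative for a positive intervention
  effect but assumes dropouts did not change.

Assumptions: within-arm normality of change scores (approximately met
after the log transform for the skewed outcomes), homogeneity of change
variance across arms (pooled s²ₚ), and independence between participants.

## 4. Synthetic cohort generator

Per arm, baseline outcomes are drawn independently from truncated normals
matching the baseline marginal means and SDs (steps ~8,600–8,900 (SD
~3,370); BMI ~26; walking 33–45 min/day; total activity 143–164 min/day;
sitting 7 h/day), truncated at 0 and, for steps, at 20,000. Post values are

post = ρ·base + (1−ρ)·μ + secular + effect(arm) + ε,  ε ~ N(0, σ√(1−ρ²)),

with baseline–post correlation ρ = **0.7**, a secular change of **+2,639
steps/day** (zero for other outcomes), an arm-specific injected effect
(zero by default), and clipping to the same [0, cap] range. Defaults:
**46 per arm**, dropout rate **0.25** (dropouts lose their post values),
everything driven by a single seed.

Because of the clipping, an injected effect is recovered with slight
shrinkage; the effect-recovery check therefore allows a 100-step margin on
top of 4 Monte-Carlo standard errors.

## 5. Simulation studies (`scripts/acceptance.py`)

Two studies, sizes chosen as a package-level trade-off between Monte-Carlo
error and runtime:

- **Calibration**: 1,000 null cohorts (no effect, no dropout, 46/arm); the
  fraction of interaction p-values below .05 estimates the type-I-error
  rate (Monte-Carlo SE ≈ 0.7 percentage points at the nominal 5%).
- **Recovery**: 300 cohorts with a +1,500 steps/day effect injected into
  one arm; the mean between-arm difference in change scores estimates the
  effect.

Replicate i uses seed `(base_seed + i) mod 2³¹`, so results are exactly
reproducible for a given `--seed`.

## Limitations

- All message texts other than the five stage introductions are
  placeholders, not a validated intervention corpus.
- The generator draws outcomes independently (no cross-outcome
  correlation), uses completely-at-random dropout, and normal (truncated)
  marginals; real cohorts are skewed and have informative dropout.
- The ANOVA closed form is specific to the 2×2 design; more timepoints or
  arms would need a general mixed-model fit.
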