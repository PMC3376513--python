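"""Seeded synthetic data: step logs and two-arm trial cohorts.

The generator emulates the study conditions the analysis layer assumes: two
arms of 46 participants, baseline outcome marginals matching the observed
baseline table (steps/day around 8600-8900 with SD around 3370, BMI around
26, walking 33-45 min/day, total activity 143-164 min/day, sitting 7 h/day),
a roughly 25% dropout process (23 of 92 in the trial flow), a shared secular
change, and a configurable additive condition effect on the step change.

Baseline values are drawn from normals truncated at 0 (and at the 20,000
steps/day cap for steps); postintervention values are generated conditionally
on baseline with correlation 0.7 and noise SD equal to the baseline SD, then
clipped to the same bounds. Everything is reproducible from ``rng_seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import timedelta
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml
from scipy import stats

from .errors import ValidationError
from .steplog import Activity, DailyRecord, StepLog
from .trialstats import (
    CONDITIONS,
    OUTCOMES,
    ParticipantRecord,
    TrialDataset,
)

__all__ = [
    "DEFAULT_BASELINE_MARGINALS",
    "CohortSpec",
    "generate_cohort",
    "generate_step_log",
    "replicate_interaction_tests",
]

#: per-arm baseline (mean, sd) per outcome; steps in steps/day, walking and
#: total_pa in minutes/day, sitting in hours/day, bmi in kg/m^2
DEFAULT_BASELINE_MARGINALS: dict[str, dict[str, tuple[float, float]]] = {
    "tailored": {
        "bmi": (25.8, 4.3),
        "walking": (33.2, 60.3),
        "total_pa": (142.7, 123.8),
        "steps": (8609.0, 3370.0),
        "sitting": (7.0, 3.1),
    },
    "standard": {
        "bmi": (26.3, 4.6),
        "walking": (44.9, 57.4),
        "total_pa": (163.6, 120.8),
        "steps": (8933.0, 3367.0),
        "sitting": (7.0, 3.4),
    },
}

#: shared time effect per outcome (the overall step level rose by ~2639/day
#: over the trial; other outcomes barely moved)
DEFAULT_SECULAR_CHANGE: dict[str, float] = {
    "bmi": 0.0,
    "walking": 0.0,
    "total_pa": 0.0,
    "steps": 2639.0,
    "sitting": 0.0,
}

STEP_CAP = 20_000.0


def _outcome_bounds(outcome: str) -> tuple[float, float]:
    return (0.0, STEP_CAP) if outcome == "steps" else (0.0, np.inf)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-arm, two-timepoint cohort."""

    n_per_arm: int = 46
    baseline_marginals: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_BASELINE_MARGINALS
    )
    secular_change: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_SECULAR_CHANGE
    )
    #: additive postintervention effect on steps/day, per arm
    condition_effect: Mapping[str, float] = field(
        default_factory=lambda: {"tailored": 0.0, "standard": 0.0}
    )
    dropout_rate: float = 0.25
    baseline_post_correlation: float = 0.7
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ValidationError("n_per_arm must be >= 2")
        if not 0 <= self.dropout_rate <= 1:
            raise ValidationError("dropout_rate must be a probability")
        if not -1 < self.baseline_post_correlation < 1:
            raise ValidationError("baseline_post_correlation must be in (-1, 1)")
        for cond in CONDITIONS:
            if cond not in self.baseline_marginals:
                raise ValidationError(f"baseline_marginals missing arm {cond!r}")
            for out in OUTCOMES:
                if out not in self.baseline_marginals[cond]:
                    raise ValidationError(
                        f"baseline_marginals[{cond!r}] missing outcome {out!r}"
                    )
                _, sd = self.baseline_marginals[cond][out]
                if sd < 0:
                    raise ValidationError(f"sd for {cond}/{out} must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSpec":
        """Load a spec from YAML (JSON is a YAML subset)."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: cohort spec must be a mapping")
        for key in ("baseline_marginals",):
            if key in raw:
                raw[key] = {
                    cond: {out: tuple(ms) for out, ms in outs.items()}
                    for cond, outs in raw[key].items()
                }
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown spec keys {sorted(unknown)}")
        return cls(**raw)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> TrialDataset:
    """Draw a reproducible two-arm cohort from a :class:`CohortSpec`.

    Postintervention values are correlated with baseline (``rho`` from the
    spec) with noise SD equal to the baseline SD; the condition effect is
    added to the steps outcome of the named arm; dropouts lose all
    postintervention values.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rho = spec.baseline_post_correlation
    records = []
    for cond in CONDITIONS:
        n = spec.n_per_arm
        base_vals: dict[str, np.ndarray] = {}
        post_vals: dict[str, np.ndarray] = {}
        for out in OUTCOMES:
            mean, sd = spec.baseline_marginals[cond][out]
            lo, hi = _outcome_bounds(out)
            base = _truncated_normal(rng, mean, sd, lo, hi, n)
            shift = spec.secular_change.get(out, 0.0)
            if out == "steps":
                shift += spec.condition_effect.get(cond, 0.0)
            noise = rng.standard_normal(n) * sd * np.sqrt(1 - rho**2)
            post = base * rho + (1 - rho) * mean + shift + noise
            post = np.clip(post, lo, hi)
            base_vals[out] = base
            post_vals[out] = post
        dropouts = rng.random(n) < spec.dropout_rate
        for i in range(n):
            outcomes = {
                out: (
                    float(base_vals[out][i]),
                    None if dropouts[i] else float(post_vals[out][i]),
                )
                for out in OUTCOMES
            }
            records.append(
                ParticipantRecord(
                    id=f"{cond[0].upper()}{i + 1:03d}",
                    condition=cond,
                    dropout=bool(dropouts[i]),
                    outcomes=outcomes,
                )
            )
    return TrialDataset(records=tuple(records))


def replicate_interaction_tests(
    n_replicates: int,
    spec_template: Optional[CohortSpec] = None,
    base_seed: int = 0,
) -> "np.ndarray":
    """Monte-Carlo study of the time x condition interaction test on steps.

    Generates ``n_replicates`` cohorts from ``spec_template`` (seeds
    ``base_seed + i``), runs the mixed ANOVA on the steps outcome of each,
    and returns an array of shape (n_replicates, 2) holding the interaction
    p value and the between-arm difference in mean step change
    (tailored minus standard). With a zero condition effect the p values
    calibrate the test's type-I error; with an injected effect the second
    column estimates it.
    """
    from .trialstats import mixed_anova  # local import to avoid a cycle

    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    template = spec_template or CohortSpec(dropout_rate=0.0)
    out = np.empty((n_replicates, 2))
    for i in range(n_replicates):
        spec = replace(template, rng_seed=(base_seed + i) % 2**31)
        res = mixed_anova(generate_cohort(spec), "steps")
        by_cond = {a.condition: a.change for a in res.arm_changes}
        out[i, 0] = res.p_interaction
        out[i, 1] = by_cond["tailored"] - by_cond["standard"]
    return out


def generate_step_log(
    mean_level: float,
    day_sd: float,
    n_days: int = 7,
    biking_prob: float = 0.15,
    rng_seed: int = 0,
    participant_id: str = "synthetic",
    start_date: Date = Date(2010, 1, 4),
) -> StepLog:
    """A reproducible daily log: truncated-normal step counts plus occasional
    biking/swimming entries with random durations (10-40 minutes)."""
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    if day_sd < 0:
        raise ValidationError("day_sd must be >= 0")
    if not 0 <= biking_prob <= 1:
        raise ValidationError("biking_prob must be a probability")
    rng = np.random.default_rng(rng_seed)
    steps = _truncated_normal(rng, mean_level, day_sd, 0.0, np.inf, n_days)
    records = []
    for i in range(n_days):
        activities: tuple[Activity, ...] = ()
        if rng.random() < biking_prob:
            kind = "biking" if rng.random() < 0.5 else "swimming"
            minutes = float(rng.integers(10, 41))
            activities = (Activity(kind=kind, minutes=minutes),)
        records.append(
            DailyRecord(
                date=start_date + timedelta(days=i),
                steps=int(round(steps[i])),
                activities=activities,
            )
        )
    return StepLog(participant_id=participant_id, records=tuple(records))
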