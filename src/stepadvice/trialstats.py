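"""Two-arm trial evaluation statistics.

Implements the evaluation layer of a two-condition (tailored vs. standard),
two-timepoint (baseline / postintervention) randomized trial:

* Welch two-sample t tests on group summaries (unequal variances, with
  Satterthwaite degrees of freedom) for quantitative baseline comparisons;
* uncorrected Pearson chi-square tests for qualitative comparisons;
* two-way mixed repeated-measures ANOVA with condition as the
  between-participants factor and time as the within-participants factor,
  reporting F for the time effect and the time x condition interaction plus
  per-arm mean change with a 95% t-based confidence interval;
* log transformation for right-skewed minutes/day outcomes (analysis on the
  log scale, reporting on the raw scale);
* intent-to-treat imputation carrying baseline values forward for dropouts;
* comparison- and effects-table builders producing the familiar
  "mean (SD) per arm, statistic, p" layout.

Significance is conventionally judged at alpha = .05; no multiplicity
adjustment is applied.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "OUTCOMES",
    "CONDITIONS",
    "GroupSummary",
    "TestResult",
    "ArmChange",
    "AnovaResult",
    "ParticipantRecord",
    "TrialDataset",
    "welch_t",
    "chi_square",
    "log_transform_outcome",
    "mixed_anova",
    "intent_to_treat",
    "proportion",
    "TableVariable",
    "build_comparison_table",
    "build_anova_table",
    "format_table",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: outcome keys and their CSV column stems
OUTCOMES = ("bmi", "walking", "total_pa", "steps", "sitting")
_CSV_STEM = {"bmi": "bmi", "walking": "walking", "total_pa": "totalpa",
             "steps": "steps", "sitting": "sitting"}
CONDITIONS = ("tailored", "standard")

#: outcomes analyzed on the log scale (right-skewed minutes/day measures)
LOG_SCALE_OUTCOMES = ("walking", "total_pa")


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, SD of one group -- the 'mean (SD)' cell of a summary table."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError(f"group needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    kind: str = ""


@dataclass(frozen=True)
class ArmChange:
    condition: str
    n: int
    baseline_mean: float
    baseline_sd: float
    post_mean: float
    post_sd: float
    change: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AnovaResult:
    """Mixed repeated-measures ANOVA effects plus per-arm change summaries."""

    outcome: str
    f_time: float
    p_time: float
    f_interaction: float
    p_interaction: float
    df_num: int
    df_den: int
    arm_changes: tuple[ArmChange, ...]


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: condition, dropout flag, per-outcome (base, post) pairs."""

    id: str
    condition: str
    dropout: bool
    outcomes: Mapping[str, tuple[Optional[float], Optional[float]]]
    imputed: bool = False

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"participant {self.id}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValidationError(
                f"participant {self.id}: unknown outcomes {sorted(unknown)}"
            )
        if self.dropout and not self.imputed:
            if not any(post is None for _, post in self.outcomes.values()):
                raise ValidationError(
                    f"participant {self.id}: flagged as dropout but has "
                    "complete postintervention data"
                )


@dataclass(frozen=True)
class TrialDataset:
    records: tuple[ParticipantRecord, ...]

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate participant ids {dupes}")
        present = {r.condition for r in self.records}
        if self.records and present != set(CONDITIONS):
            raise ValidationError(
                f"dataset must contain both arms {CONDITIONS}, found {sorted(present)}"
            )

    def arm(self, condition: str) -> tuple[ParticipantRecord, ...]:
        return tuple(r for r in self.records if r.condition == condition)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {"id": r.id, "condition": r.condition, "dropout": r.dropout}
            for out in OUTCOMES:
                base, post = r.outcomes.get(out, (None, None))
                stem = _CSV_STEM[out]
                row[f"{stem}_base"] = np.nan if base is None else base
                row[f"{stem}_post"] = np.nan if post is None else post
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def welch_t(a: GroupSummary, b: GroupSummary, pooled: bool = False) -> TestResult:
    """Two-sample t test from group summaries.

    Default is the unequal-variance (Welch) form with Welch-Satterthwaite
    degrees of freedom; ``pooled=True`` gives the classic equal-variance test
    with df = n_a + n_b - 2. Two-sided p value.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if pooled:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = float(a.n + b.n - 2)
    else:
        se = math.sqrt(va + vb)
        if va + vb == 0:
            df = float(a.n + b.n - 2)  # limit of the Satterthwaite formula
        else:
            df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    if se == 0:
        t = 0.0 if a.mean == b.mean else math.inf * math.copysign(1, a.mean - b.mean)
    else:
        t = (a.mean - b.mean) / se
    p = float(2 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return TestResult(statistic=t, df=df, p=p, kind="t" if pooled else "welch_t")


def chi_square(table: Sequence[Sequence[float]] | np.ndarray) -> TestResult:
    """Uncorrected Pearson chi-square on an r x c contingency table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValidationError("contingency counts must be >= 0")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValidationError(
            "contingency table has a zero row or column margin "
            "(expected counts undefined)"
        )
    res = stats.chi2_contingency(obs, correction=False)
    return TestResult(
        statistic=float(res.statistic), df=int(res.dof), p=float(res.pvalue),
        kind="chi_square",
    )


def log_transform_outcome(values: Iterable[float], offset: float = 1.0) -> np.ndarray:
    """Natural log of (value + offset) for right-skewed nonnegative outcomes.

    The default offset of 1 keeps zero-inflated minutes/day measures defined
    at zero. Reporting layers always display untransformed means and SDs.
    """
    arr = np.asarray(list(values), dtype=float)
    if (arr < 0).any():
        raise ValidationError("log transform requires nonnegative values")
    return np.log(arr + offset)


def proportion(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator``; rounding is left to display."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValidationError("numerator must lie in [0, denominator]")
    return 100.0 * numerator / denominator


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA (2 arms x 2 timepoints)
# ---------------------------------------------------------------------------

def mixed_anova(
    dataset: TrialDataset,
    outcome: str,
    log_scale: bool = False,
    log_offset: float = 1.0,
) -> AnovaResult:
    """Condition (between) x time (within) ANOVA on one outcome.

    Only participants with both timepoints are included (retained-sample
    behavior; apply :func:`intent_to_treat` first for an ITT analysis).
    With two timepoints the within-participant part of the model reduces
    exactly to an analysis of change scores: the interaction F tests the
    between-arm difference in mean change, and the time F tests the
    (unweighted) average change against zero; both on (1, N-2) degrees of
    freedom with the pooled change-score variance as error term. This equals
    the Type III decomposition of the full mixed model.

    ``log_scale=True`` computes the F tests on log(value + offset) while the
    per-arm change summaries stay on the raw scale.
    """
    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome {outcome!r}")
    arms_raw: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cond in CONDITIONS:
        base, post = [], []
        for r in dataset.arm(cond):
            b, p = r.outcomes.get(outcome, (None, None))
            if b is not None and p is not None:
                base.append(b)
                post.append(p)
        if len(base) < 2:
            raise ValidationError(
                f"outcome '{outcome}': arm '{cond}' has fewer than 2 "
                "participants with both timepoints"
            )
        arms_raw[cond] = (np.asarray(base, float), np.asarray(post, float))

    def _changes(transform: bool) -> dict[str, np.ndarray]:
        out = {}
        for cond, (b, p) in arms_raw.items():
            if transform:
                b = log_transform_outcome(b, log_offset)
                p = log_transform_outcome(p, log_offset)
            out[cond] = p - b
        return out

    d = _changes(log_scale)
    d1, d2 = d[CONDITIONS[0]], d[CONDITIONS[1]]
    n1, n2 = len(d1), len(d2)
    df_den = n1 + n2 - 2
    ss_err = float(((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum())
    s2p = ss_err / df_den
    inv_n = 1 / n1 + 1 / n2
    if s2p == 0:
        f_time = 0.0 if (d1.mean() + d2.mean()) == 0 else math.inf
        f_int = 0.0 if d1.mean() == d2.mean() else math.inf
    else:
        f_time = ((d1.mean() + d2.mean()) / 2) ** 2 / (s2p * inv_n / 4)
        f_int = (d1.mean() - d2.mean()) ** 2 / (s2p * inv_n)
    p_time = float(stats.f.sf(f_time, 1, df_den)) if math.isfinite(f_time) else 0.0
    p_int = float(stats.f.sf(f_int, 1, df_den)) if math.isfinite(f_int) else 0.0

    arm_changes = []
    for cond in CONDITIONS:
        b, p = arms_raw[cond]
        dc = p - b
        n = len(dc)
        se = dc.std(ddof=1) / math.sqrt(n)
        tcrit = float(stats.t.ppf(0.975, n - 1))
        arm_changes.append(
            ArmChange(
                condition=cond,
                n=n,
                baseline_mean=float(b.mean()),
                baseline_sd=float(b.std(ddof=1)),
                post_mean=float(p.mean()),
                post_sd=float(p.std(ddof=1)),
                change=float(dc.mean()),
                ci_low=float(dc.mean() - tcrit * se),
                ci_high=float(dc.mean() + tcrit * se),
            )
        )
    return AnovaResult(
        outcome=outcome,
        f_time=float(f_time),
        p_time=p_time,
        f_interaction=float(f_int),
        p_interaction=p_int,
        df_num=1,
        df_den=df_den,
        arm_changes=tuple(arm_changes),
    )


# ---------------------------------------------------------------------------
# Intent-to-treat imputation
# ---------------------------------------------------------------------------

def intent_to_treat(dataset: TrialDataset) -> TrialDataset:
    """Carry baseline forward: missing postintervention values become the
    participant's baseline value. Idempotent; completers are untouched.
    """
    missing_base = [
        r.id for r in dataset.records
        if any(base is None for base, _ in r.outcomes.values())
    ]
    if missing_base:
        raise ValidationError(
            f"intent-to-treat requires baseline values; missing for ids "
            f"{sorted(missing_base)}"
        )
    new_records = []
    for r in dataset.records:
        filled = {
            out: (base, base if post is None else post)
            for out, (base, post) in r.outcomes.items()
        }
        changed = filled != dict(r.outcomes)
        new_records.append(
            replace(r, outcomes=filled, imputed=r.imputed or changed)
        )
    return TrialDataset(records=tuple(new_records))


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableVariable:
    """One row specification for a comparison table.

    ``kind`` is 'quantitative' (mean (SD) per arm, Welch t) or 'qualitative'
    (n (%) per arm per level, Pearson chi-square).
    """

    label: str
    column: str
    kind: str

    def __post_init__(self):
        if self.kind not in ("quantitative", "qualitative"):
            raise ValidationError(f"unknown variable kind {self.kind!r}")


def build_comparison_table(
    df: pd.DataFrame,
    variables: Sequence[TableVariable],
    group_column: str = "condition",
    groups: Sequence[str] = CONDITIONS,
) -> pd.DataFrame:
    """Group-comparison table: one row per variable, per-arm summary cells,
    the matching test statistic with its df, and the p value."""
    rows = []
    for var in variables:
        if var.column not in df.columns:
            raise ValidationError(f"unknown outcome column {var.column!r}")
        if var.kind == "quantitative":
            summaries = []
            for g in groups:
                vals = df.loc[df[group_column] == g, var.column].dropna()
                summaries.append(GroupSummary(len(vals), vals.mean(), vals.std(ddof=1)))
            res = welch_t(summaries[0], summaries[1])
            cells = {
                g: f"{s.mean:.1f} ({s.sd:.1f}), n={s.n}"
                for g, s in zip(groups, summaries)
            }
            stat_txt = f"t({res.df:.0f}) = {abs(res.statistic):.1f}"
        else:
            sub = df[df[group_column].isin(groups)][[group_column, var.column]].dropna()
            crosstab = pd.crosstab(sub[var.column], sub[group_column])
            crosstab = crosstab.reindex(columns=list(groups))
            # a constant variable admits no test; report the cells alone
            res = chi_square(crosstab.to_numpy()) if len(crosstab) >= 2 else None
            cells = {}
            for g in groups:
                total = int(crosstab[g].sum())
                parts = [
                    f"{level}: {int(cnt)}/{total} ({100 * cnt / total:.0f}%)"
                    for level, cnt in crosstab[g].items()
                ]
                cells[g] = "; ".join(parts)
            stat_txt = "" if res is None else f"chi2({res.df}) = {res.statistic:.1f}"
        rows.append(
            {
                "variable": var.label,
                **cells,
                "test": stat_txt,
                "p": math.nan if res is None else round(res.p, 3),
            }
        )
    return pd.DataFrame(rows)


def build_anova_table(
    dataset: TrialDataset,
    outcomes: Sequence[str] = OUTCOMES,
    itt: bool = False,
) -> pd.DataFrame:
    """Effects table: per arm n, baseline and post mean (SD), change with
    95% CI, and F/p for the interaction and the time effect."""
    if itt:
        dataset = intent_to_treat(dataset)
    rows = []
    for outcome in outcomes:
        res = mixed_anova(dataset, outcome, log_scale=outcome in LOG_SCALE_OUTCOMES)
        for arm in res.arm_changes:
            rows.append(
                {
                    "outcome": outcome,
                    "condition": arm.condition,
                    "n": arm.n,
                    "baseline": f"{arm.baseline_mean:.1f} ({arm.baseline_sd:.1f})",
                    "post": f"{arm.post_mean:.1f} ({arm.post_sd:.1f})",
                    "change (95% CI)": (
                        f"{arm.change:.1f} ({arm.ci_low:.1f} to {arm.ci_high:.1f})"
                    ),
                    "F interaction": round(res.f_interaction, 1),
                    "p interaction": round(res.p_interaction, 3),
                    "F time": round(res.f_time, 1),
                    "p time": round(res.p_time, 3),
                }
            )
    return pd.DataFrame(rows)


def format_table(df: pd.DataFrame, fmt: str = "tsv") -> str:
    """Serialize a table as TSV or GitHub-style markdown."""
    if fmt == "tsv":
        return df.to_csv(sep="\t", index=False)
    if fmt == "markdown":
        cols = list(df.columns)
        lines = [
            "| " + " | ".join(str(c) for c in cols) + " |",
            "| " + " | ".join("---" for _ in cols) + " |",
        ]
        for _, row in df.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row) + " |")
        return "\n".join(lines) + "\n"
    raise ValidationError(f"unknown table format {fmt!r}")


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

_COHORT_HEADER = ["id", "condition", "dropout"] + [
    f"{_CSV_STEM[o]}_{t}" for o in OUTCOMES for t in ("base", "post")
]


def read_cohort_csv(path: str | Path) -> TrialDataset:
    """Read the cohort CSV dialect (empty field = missing value)."""
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_COHORT_HEADER) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"{path}: missing CSV columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            outcomes = {}
            for out in OUTCOMES:
                stem = _CSV_STEM[out]
                base = row[f"{stem}_base"].strip()
                post = row[f"{stem}_post"].strip()
                outcomes[out] = (
                    float(base) if base else None,
                    float(post) if post else None,
                )
            dropout_raw = row["dropout"].strip().lower()
            if dropout_raw not in ("0", "1", "true", "false"):
                raise ValidationError(f"{path}:{i}: bad dropout flag {row['dropout']!r}")
            records.append(
                ParticipantRecord(
                    id=row["id"].strip(),
                    condition=row["condition"].strip(),
                    dropout=dropout_raw in ("1", "true"),
                    outcomes=outcomes,
                )
            )
    return TrialDataset(records=tuple(records))


def write_cohort_csv(dataset: TrialDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COHORT_HEADER)
        for r in dataset.records:
            row: list = [r.id, r.condition, int(r.dropout)]
            for out in OUTCOMES:
                base, post = r.outcomes.get(out, (None, None))
                row.append("" if base is None else f"{base:g}")
                row.append("" if post is None else f"{post:g}")
            writer.writerow(row)
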