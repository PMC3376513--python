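"""Computer-tailored step-advice engine.

The engine mimics individual counseling: a diagnostic questionnaire plus a
pedometer-derived step level are translated, through if-then decision rules
over a message library, into a personalized advice document built around the
10,000 steps/day goal.

Theoretical backbone:

* **Transtheoretical model** -- a participant is classified into one of five
  stages of change (precontemplation, contemplation, preparation, action,
  maintenance) from their goal status, their intention to take more steps,
  and how long they have already maintained the goal. The stage selects both
  *what* is said (content) and *how* the reader is addressed (impersonal /
  personal / decisive / supportive).
* **Theory of planned behavior** -- psychosocial scores (attitude,
  self-efficacy, social support, knowledge, perceived benefits and barriers)
  gate optional information blocks, e.g. barrier-coping content only for
  participants reporting high barriers.

Document structure, in fixed order: introduction, normative feedback (step
level vs. the goal), progress feedback (second and later requests only), a
goal schedule of weekly targets (below-goal stages only), tips per life
domain, and thematic information blocks. Every emitted message carries a
trace back to its library entry and the predicates that admitted it.
"""
from __future__ import annotations

import html as _html
import json
import math
import re
import string
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import yaml

from .config import RunConfig
from .errors import ConfigurationError, RenderError, ValidationError
from .steplog import StepSummary, meets_step_goal

__all__ = [
    "Intention",
    "StageOfChange",
    "AddressMode",
    "QuestionnaireResponse",
    "GoalSchedule",
    "Message",
    "AdviceDocument",
    "MessageLibrary",
    "classify_stage",
    "address_mode",
    "normative_feedback",
    "build_schedule",
    "progress_category",
    "progress_feedback",
    "select_tips",
    "compose_advice",
    "render_advice",
    "read_questionnaire_json",
    "default_library",
    "TIP_DOMAINS",
]

TIP_DOMAINS = ("work", "household", "gardening", "leisure", "transport")

SECTION_ORDER = (
    "introduction",
    "normative_feedback",
    "progress_feedback",
    "schedule",
    "tips",
    "info_blocks",
)


class Intention(str, Enum):
    """Intention to take more steps, as asked in the diagnostic questionnaire."""

    WITHIN_1_MONTH = "within_1_month"
    WITHIN_6_MONTHS = "within_6_months"
    NONE = "none"


class StageOfChange(str, Enum):
    PRECONTEMPLATION = "precontemplation"
    CONTEMPLATION = "contemplation"
    PREPARATION = "preparation"
    ACTION = "action"
    MAINTENANCE = "maintenance"


class AddressMode(str, Enum):
    IMPERSONAL = "impersonal"  # "people could ..."
    PERSONAL = "personal"      # "you could ..."
    DECISIVE = "decisive"      # "you should ..."
    SUPPORTIVE = "supportive"  # "you do ..."


#: stages whose advice still pushes toward the goal (and gets a schedule)
BELOW_GOAL_STAGES = (
    StageOfChange.PRECONTEMPLATION,
    StageOfChange.CONTEMPLATION,
    StageOfChange.PREPARATION,
)

_ADDRESS_BY_STAGE = {
    StageOfChange.PRECONTEMPLATION: AddressMode.IMPERSONAL,
    StageOfChange.CONTEMPLATION: AddressMode.PERSONAL,
    StageOfChange.PREPARATION: AddressMode.DECISIVE,
    StageOfChange.ACTION: AddressMode.SUPPORTIVE,
    StageOfChange.MAINTENANCE: AddressMode.SUPPORTIVE,
}


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Diagnostic-questionnaire answers used by the decision rules.

    Psychosocial scores are 1-5 ordinals. ``previous_step_level`` must be
    present exactly when ``request_number >= 2`` (progress feedback compares
    the current level with it).
    """

    age: float
    gender: str
    height_cm: float
    weight_kg: float
    baseline_step_level: float
    intention: Optional[Intention]
    goal_maintenance_months: float = 0.0
    attitude: int = 3
    self_efficacy: int = 3
    social_support: int = 3
    knowledge: int = 3
    perceived_benefits: int = 3
    perceived_barriers: int = 3
    request_number: int = 1
    previous_step_level: Optional[float] = None

    def __post_init__(self):
        if self.request_number < 1:
            raise ValidationError("request_number must be >= 1")
        if self.request_number >= 2 and self.previous_step_level is None:
            raise ValidationError(
                "previous_step_level required when request_number >= 2"
            )
        if self.request_number == 1 and self.previous_step_level is not None:
            raise ValidationError(
                "previous_step_level only meaningful from the second request on"
            )
        if self.goal_maintenance_months < 0:
            raise ValidationError("goal_maintenance_months must be >= 0")
        for name in (
            "attitude",
            "self_efficacy",
            "social_support",
            "knowledge",
            "perceived_benefits",
            "perceived_barriers",
        ):
            score = getattr(self, name)
            if not 1 <= score <= 5:
                raise ValidationError(f"{name} must be on the 1-5 scale, got {score}")


@dataclass(frozen=True)
class GoalSchedule:
    """Weekly steps/day targets from the current level up to the goal."""

    increment: int
    weekly_targets: tuple[float, ...]
    weeks_to_goal: int


@dataclass(frozen=True)
class Message:
    """A rendered message plus the audit trail of how it was selected."""

    text: str
    section: str
    entry_id: str
    predicates: tuple[str, ...] = ()
    domain: Optional[str] = None
    block: Optional[str] = None


@dataclass(frozen=True)
class AdviceDocument:
    """Ordered, stage-tailored advice; sections appear in a fixed order."""

    participant_stage: StageOfChange
    mode: AddressMode
    introduction: tuple[Message, ...]
    normative: tuple[Message, ...]
    progress: tuple[Message, ...]            # empty before the second request
    schedules: tuple[GoalSchedule, ...]      # empty for action/maintenance
    schedule_messages: tuple[Message, ...]
    tips: Mapping[str, tuple[Message, ...]]  # keyed by life domain
    info_blocks: Mapping[str, tuple[Message, ...]]

    def all_messages(self) -> tuple[Message, ...]:
        out: list[Message] = []
        out += self.introduction + self.normative + self.progress
        out += self.schedule_messages
        for domain in self.tips:
            out += self.tips[domain]
        for block in self.info_blocks:
            out += self.info_blocks[block]
        return tuple(out)


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------

def classify_stage(
    resp: QuestionnaireResponse,
    summary: StepSummary,
    goal: float = 10_000,
    maintenance_months: float = 6,
) -> StageOfChange:
    """Stage a participant from goal status, intention and goal tenure.

    At or above the goal, the split between action and maintenance is how
    long the goal has been held (default 6 months). Below the goal the
    intention question decides: no intention -> precontemplation, within 6
    months -> contemplation, within 1 month -> preparation.
    """
    if meets_step_goal(summary, goal):
        if resp.goal_maintenance_months >= maintenance_months:
            return StageOfChange.MAINTENANCE
        return StageOfChange.ACTION
    if resp.intention is None:
        raise ValidationError(
            "intention is required to stage a participant below the step goal"
        )
    return {
        Intention.NONE: StageOfChange.PRECONTEMPLATION,
        Intention.WITHIN_6_MONTHS: StageOfChange.CONTEMPLATION,
        Intention.WITHIN_1_MONTH: StageOfChange.PREPARATION,
    }[resp.intention]


def address_mode(stage: StageOfChange) -> AddressMode:
    """How the reader is addressed; a fixed function of the stage."""
    return _ADDRESS_BY_STAGE[stage]


def build_schedule(
    baseline: float, increment: int, goal: float = 10_000
) -> GoalSchedule:
    """Weekly targets ``baseline + k*increment`` with the last one capped at goal.

    Empty when the baseline already reaches the goal. For a below-goal
    baseline the number of weeks is ``ceil((goal - baseline) / increment)``.
    """
    if increment <= 0:
        raise ValidationError("increment must be positive")
    if baseline < 0:
        raise ValidationError("baseline must be >= 0")
    if baseline >= goal:
        return GoalSchedule(increment=increment, weekly_targets=(), weeks_to_goal=0)
    targets: list[float] = []
    level = baseline
    while level + increment < goal:
        level += increment
        targets.append(level)
    targets.append(goal)
    return GoalSchedule(
        increment=increment,
        weekly_targets=tuple(targets),
        weeks_to_goal=len(targets),
    )


def progress_category(
    previous: float, current: float, stable_band: float = 500
) -> str:
    """Classify evolution since the previous request.

    ``positive`` / ``negative`` when the change exceeds the stable band in
    either direction, ``stable`` otherwise; the three categories partition
    all pairs.
    """
    if previous < 0 or current < 0:
        raise ValidationError("step levels must be >= 0")
    if current - previous > stable_band:
        return "positive"
    if previous - current > stable_band:
        return "negative"
    return "stable"


# ---------------------------------------------------------------------------
# Message library
# ---------------------------------------------------------------------------

_PREDICATE_RE = re.compile(
    r"^\s*(not\s+)?([A-Za-z_][A-Za-z0-9_]*)\s*"
    r"(?:(==|!=|<=|>=|<|>)\s*('(?:[^']*)'|-?\d+(?:\.\d+)?|[A-Za-z_][A-Za-z0-9_]*))?\s*$"
)


def _eval_predicate(expr: str, context: Mapping[str, Any]) -> bool:
    """Evaluate one predicate over the tailoring context.

    Grammar: ``[not] field [op literal-or-field]`` with ops ``== != < <= > >=``;
    string literals are single-quoted. A bare field tests truthiness.
    """
    m = _PREDICATE_RE.match(expr)
    if not m:
        raise ConfigurationError(f"unparseable predicate {expr!r}")
    negate, lhs_name, op, rhs_raw = m.groups()
    if lhs_name not in context:
        raise ConfigurationError(f"predicate {expr!r}: unknown field {lhs_name!r}")
    lhs = context[lhs_name]
    if op is None:
        result = bool(lhs)
    else:
        if rhs_raw.startswith("'"):
            rhs: Any = rhs_raw[1:-1]
        elif re.fullmatch(r"-?\d+(\.\d+)?", rhs_raw):
            rhs = float(rhs_raw) if "." in rhs_raw else int(rhs_raw)
        else:
            if rhs_raw not in context:
                raise ConfigurationError(
                    f"predicate {expr!r}: unknown field {rhs_raw!r}"
                )
            rhs = context[rhs_raw]
        result = {
            "==": lambda a, b: a == b,
            "!=": lambda a, b: a != b,
            "<": lambda a, b: a < b,
            "<=": lambda a, b: a <= b,
            ">": lambda a, b: a > b,
            ">=": lambda a, b: a >= b,
        }[op](lhs, rhs)
    return (not result) if negate else result


class _StrictFormatter(string.Formatter):
    def get_value(self, key, args, kwargs):
        if isinstance(key, str) and key not in kwargs:
            raise RenderError(f"unresolved template placeholder {{{key}}}")
        return super().get_value(key, args, kwargs)


_FORMATTER = _StrictFormatter()


@dataclass(frozen=True)
class LibraryEntry:
    entry_id: str
    section: str
    template: str
    stages: tuple[str, ...]        # empty = any stage
    when: tuple[str, ...] = ()
    domain: Optional[str] = None
    block: Optional[str] = None
    canonical: bool = False

    def applies(self, stage: StageOfChange, context: Mapping[str, Any]) -> bool:
        if self.stages and stage.value not in self.stages:
            return False
        return all(_eval_predicate(p, context) for p in self.when)

    def render(self, context: Mapping[str, Any]) -> Message:
        try:
            text = _FORMATTER.vformat(self.template, (), dict(context))
        except (KeyError, IndexError) as exc:  # pragma: no cover - formatter raises
            raise RenderError(str(exc)) from exc
        return Message(
            text=text,
            section=self.section,
            entry_id=self.entry_id,
            predicates=self.when,
            domain=self.domain,
            block=self.block,
        )


class MessageLibrary:
    """The editable corpus of intervention messages plus their decision rules.

    Loaded from a YAML list; each entry carries ``section``, an optional
    ``stage`` (string or list, omitted = any), optional ``when`` predicates,
    optional ``domain`` (tips) or ``block`` (info blocks), and a ``template``
    with named placeholders.
    """

    def __init__(self, entries: Sequence[LibraryEntry]):
        self.entries = tuple(entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MessageLibrary":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls._from_raw(raw, source=str(path))

    @classmethod
    def _from_raw(cls, raw: Any, source: str) -> "MessageLibrary":
        if not isinstance(raw, list):
            raise ConfigurationError(f"{source}: message library must be a list")
        entries = []
        for i, item in enumerate(raw):
            if not isinstance(item, dict) or "section" not in item or "template" not in item:
                raise ConfigurationError(
                    f"{source}: entry {i} needs at least 'section' and 'template'"
                )
            stage_raw = item.get("stage")
            if stage_raw is None:
                stages: tuple[str, ...] = ()
            elif isinstance(stage_raw, str):
                stages = (stage_raw,)
            else:
                stages = tuple(stage_raw)
            for s in stages:
                if s not in StageOfChange._value2member_map_:
                    raise ConfigurationError(f"{source}: entry {i}: unknown stage {s!r}")
            entries.append(
                LibraryEntry(
                    entry_id=item.get("id", f"{item['section']}[{i}]"),
                    section=item["section"],
                    template=item["template"],
                    stages=stages,
                    when=tuple(item.get("when", ())),
                    domain=item.get("domain"),
                    block=item.get("block"),
                    canonical=bool(item.get("canonical", False)),
                )
            )
        return cls(entries)

    def select(
        self,
        section: str,
        stage: StageOfChange,
        context: Mapping[str, Any],
        required: bool = False,
    ) -> tuple[Message, ...]:
        """All applicable, rendered messages of a section, in library order."""
        picked = [
            e.render(context)
            for e in self.entries
            if e.section == section and e.applies(stage, context)
        ]
        if required and not picked:
            raise ConfigurationError(
                f"message library has no applicable entry for section "
                f"'{section}', stage '{stage.value}'"
            )
        return tuple(picked)


def default_library() -> MessageLibrary:
    """The library shipped with the package (stage introductions + rule-gated
    feedback, tip and info-block texts)."""
    ref = resources.files("stepadvice").joinpath("data/message_library.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return MessageLibrary._from_raw(raw, source="stepadvice/data/message_library.yaml")


# ---------------------------------------------------------------------------
# Section builders
# ---------------------------------------------------------------------------

def _base_context(
    resp: QuestionnaireResponse,
    summary: StepSummary,
    stage: StageOfChange,
    config: RunConfig,
) -> dict[str, Any]:
    mean = summary.mean_steps_per_day
    gap = max(0, int(round(config.goal - mean)))
    ctx: dict[str, Any] = {
        "goal": config.goal,
        "mean_steps": mean,
        "mean_steps_rounded": int(round(mean)),
        "n_valid_days": summary.n_valid_days,
        "gap": gap,
        "at_goal": mean >= config.goal,
        "stage": stage.value,
        "mode": address_mode(stage).value,
        "request_number": resp.request_number,
        "goal_maintenance_months": resp.goal_maintenance_months,
        "barriers_high_threshold": config.barriers_high_threshold,
        "self_efficacy_low_threshold": config.self_efficacy_low_threshold,
    }
    for name in (
        "age",
        "gender",
        "attitude",
        "self_efficacy",
        "social_support",
        "knowledge",
        "perceived_benefits",
        "perceived_barriers",
    ):
        ctx[name] = getattr(resp, name)
    if resp.previous_step_level is not None:
        prev = resp.previous_step_level
        ctx["previous_steps_rounded"] = int(round(prev))
        ctx["change"] = int(round(mean - prev))
        ctx["change_abs"] = abs(int(round(mean - prev)))
        ctx["evolution"] = progress_category(prev, mean, config.stable_band)
    return ctx


def normative_feedback(
    summary: StepSummary,
    goal: float = 10_000,
    library: Optional[MessageLibrary] = None,
    context: Optional[Mapping[str, Any]] = None,
    stage: StageOfChange = StageOfChange.PRECONTEMPLATION,
) -> tuple[bool, int, tuple[Message, ...]]:
    """Relate the measured step level to the goal.

    Returns ``(at_goal, gap, messages)``; the gap is the rounded shortfall
    (0 at or above goal). With a library, the below-goal / at-goal variant is
    selected and the mean and gap are filled into its template.
    """
    at_goal = meets_step_goal(summary, goal)
    gap = max(0, int(round(goal - summary.mean_steps_per_day)))
    messages: tuple[Message, ...] = ()
    if library is not None:
        ctx = dict(context) if context is not None else {
            "goal": int(goal),
            "mean_steps": summary.mean_steps_per_day,
            "mean_steps_rounded": int(round(summary.mean_steps_per_day)),
            "gap": gap,
            "at_goal": at_goal,
        }
        messages = library.select("normative_feedback", stage, ctx, required=True)
    return at_goal, gap, messages


def progress_feedback(
    previous: float,
    current: float,
    stable_band: float = 500,
    library: Optional[MessageLibrary] = None,
    context: Optional[Mapping[str, Any]] = None,
    stage: StageOfChange = StageOfChange.PRECONTEMPLATION,
) -> tuple[str, tuple[Message, ...]]:
    """Compare the current step level with the previous request's level."""
    category = progress_category(previous, current, stable_band)
    messages: tuple[Message, ...] = ()
    if library is not None:
        ctx = dict(context) if context is not None else {}
        ctx.setdefault("evolution", category)
        ctx.setdefault("previous_steps_rounded", int(round(previous)))
        ctx.setdefault("change", int(round(current - previous)))
        ctx.setdefault("change_abs", abs(int(round(current - previous))))
        ctx.setdefault("mean_steps_rounded", int(round(current)))
        messages = library.select("progress_feedback", stage, ctx, required=True)
    return category, messages


def select_tips(
    stage: StageOfChange,
    resp: QuestionnaireResponse,
    library: MessageLibrary,
    context: Mapping[str, Any],
    domains: Sequence[str] = TIP_DOMAINS,
) -> dict[str, tuple[Message, ...]]:
    """Tips per life domain, filtered by stage and psychosocial predicates.

    Below-goal stages get step-increase tips in their stage's address mode;
    action/maintenance get relapse-prevention framing instead.
    """
    all_tips = library.select("tips", stage, context, required=True)
    grouped: dict[str, tuple[Message, ...]] = {}
    for domain in domains:
        domain_msgs = tuple(m for m in all_tips if m.domain == domain)
        if domain_msgs:
            grouped[domain] = domain_msgs
    if not grouped:
        raise ConfigurationError(
            f"message library has tips for stage '{stage.value}' "
            f"but none in the configured domains {tuple(domains)}"
        )
    return grouped


def compose_advice(
    resp: QuestionnaireResponse,
    summary: StepSummary,
    library: Optional[MessageLibrary] = None,
    config: Optional[RunConfig] = None,
) -> AdviceDocument:
    """Assemble the full, ordered advice document for one participant."""
    config = config or RunConfig()
    library = library or default_library()
    stage = classify_stage(resp, summary, config.goal, config.maintenance_months)
    ctx = _base_context(resp, summary, stage, config)

    introduction = library.select("introduction", stage, ctx, required=True)
    _, _, normative = normative_feedback(
        summary, config.goal, library, ctx, stage
    )

    progress: tuple[Message, ...] = ()
    if resp.request_number >= 2:
        _, progress = progress_feedback(
            resp.previous_step_level,
            summary.mean_steps_per_day,
            config.stable_band,
            library,
            ctx,
            stage,
        )

    schedules: tuple[GoalSchedule, ...] = ()
    schedule_messages: tuple[Message, ...] = ()
    if stage in BELOW_GOAL_STAGES:
        schedules = tuple(
            build_schedule(summary.mean_steps_per_day, inc, config.goal)
            for inc in config.increments
        )
        schedule_messages = library.select("schedule", stage, ctx)

    tips = select_tips(stage, resp, library, ctx)
    blocks_raw = library.select("info_blocks", stage, ctx)
    info_blocks: dict[str, tuple[Message, ...]] = {}
    for msg in blocks_raw:
        key = msg.block or "general"
        info_blocks[key] = info_blocks.get(key, ()) + (msg,)

    return AdviceDocument(
        participant_stage=stage,
        mode=address_mode(stage),
        introduction=introduction,
        normative=normative,
        progress=progress,
        schedules=schedules,
        schedule_messages=schedule_messages,
        tips=tips,
        info_blocks=info_blocks,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_SECTION_TITLES = {
    "introduction": "Introduction",
    "normative_feedback": "Your step level and the 10,000 steps goal",
    "progress_feedback": "Your progress since your previous advice",
    "schedule": "A schedule toward the goal",
    "tips": "Tips to take more steps",
    "info_blocks": "More information",
}


def _schedule_lines(schedule: GoalSchedule) -> list[str]:
    lines = [
        f"Increasing by {schedule.increment} steps per week "
        f"({schedule.weeks_to_goal} week(s)):"
    ]
    for week, target in enumerate(schedule.weekly_targets, start=1):
        lines.append(f"  week {week}: {int(round(target))} steps/day")
    return lines


def _document_blocks(doc: AdviceDocument) -> list[tuple[str, list[str]]]:
    """(section title, paragraphs) pairs in render order, empties dropped."""
    blocks: list[tuple[str, list[str]]] = []
    if doc.introduction:
        blocks.append((_SECTION_TITLES["introduction"], [m.text for m in doc.introduction]))
    if doc.normative:
        blocks.append((_SECTION_TITLES["normative_feedback"], [m.text for m in doc.normative]))
    if doc.progress:
        blocks.append((_SECTION_TITLES["progress_feedback"], [m.text for m in doc.progress]))
    if doc.schedules:
        paras = [m.text for m in doc.schedule_messages]
        for schedule in doc.schedules:
            if schedule.weekly_targets:
                paras.append("\n".join(_schedule_lines(schedule)))
        if paras:
            blocks.append((_SECTION_TITLES["schedule"], paras))
    if doc.tips:
        paras = []
        for domain, msgs in doc.tips.items():
            for m in msgs:
                paras.append(f"{domain.capitalize()}: {m.text}")
        blocks.append((_SECTION_TITLES["tips"], paras))
    if doc.info_blocks:
        paras = [m.text for msgs in doc.info_blocks.values() for m in msgs]
        blocks.append((_SECTION_TITLES["info_blocks"], paras))
    return blocks


def render_advice(doc: AdviceDocument, format: str = "text") -> str:
    """Render an advice document; identical input yields identical output."""
    blocks = _document_blocks(doc)
    if format == "text":
        parts = []
        for title, paras in blocks:
            parts.append(title)
            parts.append("-" * len(title))
            parts.extend(paras)
            parts.append("")
        return "\n".join(parts).rstrip() + "\n"
    if format == "markdown":
        parts = []
        for title, paras in blocks:
            parts.append(f"## {title}")
            parts.append("")
            for p in paras:
                parts.append(p)
                parts.append("")
        return "\n".join(parts).rstrip() + "\n"
    if format == "html":
        parts = ["<!DOCTYPE html>", "<html><body>"]
        for title, paras in blocks:
            parts.append(f"<h2>{_html.escape(title)}</h2>")
            for p in paras:
                escaped = _html.escape(p).replace("\n", "<br/>")
                parts.append(f"<p>{escaped}</p>")
        parts.append("</body></html>")
        return "\n".join(parts) + "\n"
    raise ValidationError(f"unknown render format {format!r}")


# ---------------------------------------------------------------------------
# Questionnaire I/O
# ---------------------------------------------------------------------------

def read_questionnaire_json(path: str | Path) -> QuestionnaireResponse:
    """Read a flat snake_case JSON object into a QuestionnaireResponse."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: questionnaire JSON must be an object")
    intention_raw = raw.get("intention")
    intention = None
    if intention_raw is not None:
        try:
            intention = Intention(intention_raw)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: unknown intention {intention_raw!r}; expected one of "
                f"{[i.value for i in Intention]}"
            ) from exc
    known = set(QuestionnaireResponse.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown questionnaire fields {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k != "intention"}
    try:
        return QuestionnaireResponse(intention=intention, **kwargs)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
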