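"""Run configuration.

All defaults are the protocol constants of the intervention: a goal of
10,000 steps/day, weekly increments of 500 or 1000 steps, daily totals
capped at 20,000 steps, at least 5 valid registration days, and a credit
of 150 steps per minute of biking or swimming.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from .errors import ValidationError

#: steps/day target the advice is tailored toward
DEFAULT_GOAL = 10_000
#: allowed weekly step increments participants can choose from
DEFAULT_INCREMENTS = (500, 1000)
#: daily totals above this are truncated (limits unrealistically high averages)
DEFAULT_CAP = 20_000
#: minimum number of valid registration days for a usable step log
DEFAULT_MIN_VALID_DAYS = 5
#: steps credited per minute of a convertible non-ambulatory activity
DEFAULT_CONVERSION_RATE = 150
#: activity kinds credited as steps
DEFAULT_CONVERTIBLE_ACTIVITIES = ("biking", "swimming")
#: |current - previous| within this band counts as a stable evolution
DEFAULT_STABLE_BAND = 500
#: months at goal separating the action and maintenance stages
DEFAULT_MAINTENANCE_MONTHS = 6
#: psychosocial scores are 1-5 ordinals; these split "high" / "low"
DEFAULT_BARRIERS_HIGH = 4
DEFAULT_SELF_EFFICACY_LOW = 2


@dataclass(frozen=True)
class RunConfig:
    """Tunable constants wired through every pipeline stage."""

    goal: int = DEFAULT_GOAL
    increments: tuple[int, ...] = DEFAULT_INCREMENTS
    cap: int = DEFAULT_CAP
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS
    conversion_rate: float = DEFAULT_CONVERSION_RATE
    convertible_activities: tuple[str, ...] = DEFAULT_CONVERTIBLE_ACTIVITIES
    stable_band: float = DEFAULT_STABLE_BAND
    maintenance_months: int = DEFAULT_MAINTENANCE_MONTHS
    barriers_high_threshold: int = DEFAULT_BARRIERS_HIGH
    self_efficacy_low_threshold: int = DEFAULT_SELF_EFFICACY_LOW
    library_path: Optional[str] = None
    seed: Optional[int] = None
    output_format: str = "text"

    def __post_init__(self):
        if self.goal <= 0:
            raise ValidationError("goal must be positive")
        if self.cap <= 0:
            raise ValidationError("cap must be positive")
        if self.min_valid_days < 1:
            raise ValidationError("min_valid_days must be >= 1")
        if self.conversion_rate < 0:
            raise ValidationError("conversion_rate must be >= 0")
        if any(i <= 0 for i in self.increments):
            raise ValidationError("increments must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must be a mapping")
        for key in ("increments", "convertible_activities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        raw.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **overrides) -> "RunConfig":
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return replace(self, **overrides)
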