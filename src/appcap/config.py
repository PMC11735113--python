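"""Scenario configuration: parameters for every stage of the model.

The scenario file is YAML, validated strictly (unknown keys are rejected)
so that a scenario file is a complete reproducibility record. Every unset
field falls back to the published parameterization: 40% mental-health
prevalence among adults, 70% of those in the mild-to-moderate band, 33% of
GP appointments involving mental health, a 37.5-hour / 45-week working
year, 12-participant group cycles of 8 group-work weeks plus 4 well-being
weeks, 45-minute brief-intervention and 30-minute triage appointments, a
10% self-referral fraction, and 41 primary care networks.
"""

from __future__ import annotations

import copy
import logging
import warnings
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

ActivityCategory = Literal[
    "community_engagement",
    "other_supervision",
    "group_work",
    "brief_intervention",
    "triage",
]

#: Categories whose blocks are appointment streams and carry a duration.
APPOINTMENT_CATEGORIES = ("brief_intervention", "triage")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CascadeParams(_StrictModel):
    """Prevalence-and-severity cascade: adults -> MH-prevalent -> mild/moderate.

    ``min_age`` defaults to 15 because the register extracts are banded at
    15+ even though the role targets 16+; both are legitimate choices and
    the field is configurable rather than guessing intent.
    """

    min_age: int = Field(default=15, ge=0)
    mh_prevalence: float = Field(default=0.40, ge=0.0, le=1.0)
    severity_share: float = Field(default=0.70, ge=0.0, le=1.0)


class ApportionmentParams(_StrictModel):
    """How commissioning-area appointment totals map down to one PCN."""

    # 0.33 exactly, not 1/3: the stated parameter is the printed 33%.
    mh_share_of_gp_appts: float = Field(default=0.33, ge=0.0, le=1.0)
    staff_type_in_scope: Literal["gp_only", "all_staff"] = "gp_only"


class AnnualizationParams(_StrictModel):
    """Working-time assumptions used to annualize weekly activity."""

    weeks_per_year: int = Field(default=45, ge=0)
    hours_per_week: float = Field(default=37.5, gt=0.0)
    hours_per_day: float = Field(default=7.5, gt=0.0)

    @model_validator(mode="after")
    def _warn_week_day_mismatch(self) -> "AnnualizationParams":
        # A 5-day week is assumed when converting day-denominated blocks;
        # a mismatch is legal (compressed weeks) but worth flagging.
        if abs(self.hours_per_week - 5.0 * self.hours_per_day) > 1e-9:
            warnings.warn(
                f"hours_per_week ({self.hours_per_week}) != 5 x hours_per_day "
                f"({self.hours_per_day}); day-denominated blocks use "
                "hours_per_day, the remainder uses hours_per_week",
                stacklevel=2,
            )
        return self


class ActivityBlock(_StrictModel):
    """One activity stream within a working week.

    Time is given either in days (``weekly_time_days``, converted via
    ``hours_per_day``) or directly in hours; a ``remainder`` block takes
    whatever the fixed blocks leave of the working week. Appointment-stream
    blocks (brief interventions, triage) carry a per-appointment duration.
    """

    name: str
    category: ActivityCategory
    weekly_time_days: Optional[float] = Field(default=None, ge=0.0)
    weekly_time_hours: Optional[float] = Field(default=None, ge=0.0)
    appointment_duration_minutes: Optional[float] = Field(default=None, gt=0.0)
    allocation: Literal["fixed", "remainder"] = "fixed"

    @model_validator(mode="after")
    def _check_time_and_duration(self) -> "ActivityBlock":
        n_times = (self.weekly_time_days is not None) + (
            self.weekly_time_hours is not None
        )
        if self.allocation == "remainder":
            if n_times:
                raise ValueError(
                    f"block {self.name!r}: a remainder block must not state a "
                    "weekly time"
                )
        elif n_times != 1:
            raise ValueError(
                f"block {self.name!r}: give exactly one of weekly_time_days or "
                "weekly_time_hours"
            )
        if self.category in APPOINTMENT_CATEGORIES:
            if self.appointment_duration_minutes is None:
                raise ValueError(
                    f"block {self.name!r}: {self.category} requires "
                    "appointment_duration_minutes"
                )
        elif self.appointment_duration_minutes is not None:
            raise ValueError(
                f"block {self.name!r}: appointment_duration_minutes only "
                "applies to brief_intervention/triage blocks"
            )
        return self


class WeekTemplate(_StrictModel):
    """An ordered set of activity blocks making up one APP working week."""

    name: str = ""
    blocks: list[ActivityBlock] = Field(min_length=1)

    @model_validator(mode="after")
    def _at_most_one_remainder(self) -> "WeekTemplate":
        n_rem = sum(b.allocation == "remainder" for b in self.blocks)
        if n_rem > 1:
            raise ValueError(
                f"template {self.name!r}: at most one remainder block allowed"
            )
        return self


class GroupCycleSpec(_StrictModel):
    """Group-work cycle: weekly half-day sessions for ``group_weeks`` weeks,
    then community well-being sessions for ``wellbeing_weeks`` weeks, with up
    to ``participants_per_cycle`` people enrolled per cycle."""

    group_weeks: int = Field(default=8, ge=1)
    wellbeing_weeks: int = Field(default=4, ge=1)
    sessions_per_week: int = Field(default=1, ge=1)
    participants_per_cycle: int = Field(default=12, ge=1)


class DiversionScenario(_StrictModel):
    """Referral-pathway scenario: patients who would have seen the GP
    ``baseline_gp_visits_per_patient`` times instead see them
    ``future_gp_visits_per_patient`` time(s) and receive APP care."""

    baseline_gp_visits_per_patient: int = Field(default=3, ge=0)
    future_gp_visits_per_patient: int = Field(default=1, ge=0)
    app_sessions_per_patient: int = Field(default=4, ge=1)
    self_referral_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    triage_duration_minutes: float = Field(default=30.0, gt=0.0)

    @model_validator(mode="after")
    def _baseline_at_least_future(self) -> "DiversionScenario":
        if self.baseline_gp_visits_per_patient < self.future_gp_visits_per_patient:
            raise ValueError(
                "baseline_gp_visits_per_patient must be >= "
                "future_gp_visits_per_patient"
            )
        return self


def _default_templates() -> dict[str, WeekTemplate]:
    """The shipped week templates.

    ``standard`` is calibrated so that its annual brief-intervention output
    is exactly 1,665 appointments (37 x 45): half a day of community
    engagement, a quarter-day of other/supervision, half a day of group
    work, remaining time as 45-minute appointments. ``standard_no_group``
    is the three-activity variant without group work. The alternative weeks
    add a triage stream and are calibrations, not published facts: their
    exact published compositions are not available.
    """

    def block(name, category, days=None, minutes=None, remainder=False):
        return ActivityBlock(
            name=name,
            category=category,
            weekly_time_days=days,
            appointment_duration_minutes=minutes,
            allocation="remainder" if remainder else "fixed",
        )

    community = block("community_engagement", "community_engagement", days=0.5)
    other = block("other_supervision", "other_supervision", days=0.25)
    group = block("group_work", "group_work", days=0.5)
    brief = block("brief_interventions", "brief_intervention", minutes=45, remainder=True)

    return {
        "standard": WeekTemplate(
            name="standard", blocks=[community, other, group, brief]
        ),
        "standard_no_group": WeekTemplate(
            name="standard_no_group", blocks=[community, other, brief]
        ),
        "alternative_1": WeekTemplate(
            name="alternative_1",
            blocks=[
                community,
                other,
                group,
                block("triage", "triage", days=0.875, minutes=30),
                brief,
            ],
        ),
        "alternative_2": WeekTemplate(
            name="alternative_2",
            blocks=[
                community,
                other,
                group,
                block("triage", "triage", days=0.8, minutes=30),
                brief,
            ],
        ),
    }


class ScenarioConfig(_StrictModel):
    """The complete parameter set for one model run."""

    schema_version: int = SCHEMA_VERSION
    cascade: CascadeParams = Field(default_factory=CascadeParams)
    apportionment: ApportionmentParams = Field(default_factory=ApportionmentParams)
    annualization: AnnualizationParams = Field(default_factory=AnnualizationParams)
    week_templates: dict[str, WeekTemplate] = Field(default_factory=_default_templates)
    active_template: str = "standard"
    group_cycle: GroupCycleSpec = Field(default_factory=GroupCycleSpec)
    diversion: DiversionScenario = Field(default_factory=DiversionScenario)
    n_pcns: int = Field(default=41, ge=1)
    reduction_band: tuple[float, float] = (0.25, 1.0 / 3.0)
    #: Commissioning-area population used for the PCN share; when unset the
    #: summed register population stands in for the area.
    area_population: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _cross_checks(self) -> "ScenarioConfig":
        low, high = self.reduction_band
        if not (0.0 <= low <= high <= 1.0):
            raise ValueError(
                f"reduction_band must satisfy 0 <= low <= high <= 1, got "
                f"({low}, {high})"
            )
        if self.active_template not in self.week_templates:
            raise ValueError(
                f"active_template {self.active_template!r} not among templates "
                f"{sorted(self.week_templates)}"
            )
        for key, template in self.week_templates.items():
            if not template.name:
                template.name = key
        return self


def default_scenario() -> ScenarioConfig:
    """The published parameterization, as a validated config."""
    return ScenarioConfig()


def _deep_merge(base: dict, update: dict) -> dict:
    """Recursively merge ``update`` into ``base`` (dicts merge, others replace)."""
    merged = copy.deepcopy(base)
    for key, value in update.items():
        if (
            key in merged
            and isinstance(merged[key], dict)
            and isinstance(value, dict)
        ):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def _apply_dotted(data: dict, dotted: str, value: object) -> None:
    parts = dotted.split(".")
    node = data
    for part in parts[:-1]:
        node = node.setdefault(part, {})
        if not isinstance(node, dict):
            raise ConfigError(f"override path {dotted!r} crosses a scalar field")
    node[parts[-1]] = value


def load_scenario(
    path: str | Path, overrides: Optional[dict[str, object]] = None
) -> ScenarioConfig:
    """Load, default-fill and validate a scenario file.

    ``overrides`` maps dotted field paths (e.g. ``"cascade.mh_prevalence"``)
    to values applied after the file. An empty file yields
    :func:`default_scenario`. Unknown keys are rejected.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: scenario file must be a mapping")

    defaults = default_scenario().model_dump(mode="json", exclude_none=True)
    merged = _deep_merge(defaults, raw)
    for dotted, value in (overrides or {}).items():
        _apply_dotted(merged, dotted, value)

    config = ScenarioConfig(**merged)
    logger.info("effective scenario config:\n%s", dump_scenario(config))
    return config


def dump_scenario(config: ScenarioConfig) -> str:
    """Serialize a config to the YAML dialect :func:`load_scenario` reads."""
    return yaml.safe_dump(
        config.model_dump(mode="json", exclude_none=True), sort_keys=False
    )


def save_scenario(config: ScenarioConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(dump_scenario(config))
    return path
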