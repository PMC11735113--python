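"""Annual clinical capacity of one whole-time-equivalent practitioner.

A working week is a set of activity blocks (community engagement,
other/supervision, group work, and the appointment streams: 45-minute
brief interventions and 30-minute triage). Fixed blocks take their stated
time; one block may be marked ``remainder`` and receives whatever is left
of the working week. Appointment streams yield whole appointments per week
(floored weekly, then multiplied by the working weeks of the year — this
ordering is what the published per-practitioner figure implies: 28.125 h /
0.75 h = 37.5 -> 37 slots/week -> 37 x 45 = 1,665/year, where annual
flooring would give 1,687).

Group work runs in cycles of ``group_weeks`` weekly sessions followed by
``wellbeing_weeks`` community well-being weeks; a 45-week year packs three
full cycles plus one trailing group-only cycle. Participant-session counts
cover the group-work weeks only: enrolled participants attend the group
sessions of their cycle, so 4 cycles x 8 sessions x 12 participants = 384.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import (
    ActivityBlock,
    ActivityCategory,
    AnnualizationParams,
    GroupCycleSpec,
    WeekTemplate,
)
from .errors import InfeasibleWeekError

_EPS = 1e-9


@dataclass
class CycleSchedule:
    """How group/well-being cycles pack into the working year."""

    full_cycles: int
    group_only_cycles: int
    weeks_used: int


@dataclass
class AnnualCapacity:
    """Annualized outputs of one WTE practitioner on one week template."""

    brief_appointments: int
    triage_appointments: int
    group_participants: int
    group_person_sessions: int
    community_engagement_hours: float


def block_hours(block: ActivityBlock, annualization: AnnualizationParams) -> float:
    """Weekly hours of a fixed block (day-denominated times use hours_per_day)."""
    if block.allocation == "remainder":
        raise ValueError(f"block {block.name!r} is remainder-allocated")
    if block.weekly_time_hours is not None:
        return block.weekly_time_hours
    return block.weekly_time_days * annualization.hours_per_day


def resolve_week(
    template: WeekTemplate, annualization: AnnualizationParams
) -> dict[str, float]:
    """Effective weekly hours per block after remainder resolution.

    Raises :class:`InfeasibleWeekError` if fixed blocks exceed the working
    week. When a remainder block exists the resolved hours sum exactly to
    ``hours_per_week``.
    """
    hours: dict[str, float] = {}
    remainder_name = None
    fixed_total = 0.0
    for block in template.blocks:
        if block.allocation == "remainder":
            remainder_name = block.name
        else:
            hours[block.name] = block_hours(block, annualization)
            fixed_total += hours[block.name]
    spare = annualization.hours_per_week - fixed_total
    if spare < -_EPS:
        listing = ", ".join(f"{name}={h}h" for name, h in hours.items())
        raise InfeasibleWeekError(
            f"template {template.name!r}: fixed blocks ({listing}) total "
            f"{fixed_total} h, exceeding the {annualization.hours_per_week} h week"
        )
    if remainder_name is not None:
        hours[remainder_name] = max(spare, 0.0)
    return hours


def _category_block(template: WeekTemplate, category: ActivityCategory):
    for block in template.blocks:
        if block.category == category:
            return block
    return None


def weekly_slots(
    template: WeekTemplate,
    category: ActivityCategory,
    annualization: AnnualizationParams,
) -> int:
    """Whole appointments per week for an appointment-stream category.

    Returns 0 when the template carries no block of that category.
    """
    block = _category_block(template, category)
    if block is None:
        return 0
    hours = resolve_week(template, annualization)[block.name]
    per_appointment = block.appointment_duration_minutes / 60.0
    return int(math.floor(hours / per_appointment + _EPS))


def annualize(weekly: int, annualization: AnnualizationParams) -> int:
    """Weekly appointments x working weeks per year."""
    if weekly < 0:
        raise ValueError("weekly slot count must be >= 0")
    return weekly * annualization.weeks_per_year


def schedule_group_cycles(weeks_per_year: int, spec: GroupCycleSpec) -> CycleSchedule:
    """Pack group/well-being cycles into the year.

    Full cycles (group + well-being weeks) are packed first; at most one
    trailing group-only cycle is added if its group weeks still fit. A
    truncated trailing cycle is never well-being-only.
    """
    if weeks_per_year < 0:
        raise ValueError("weeks_per_year must be >= 0")
    cycle_len = spec.group_weeks + spec.wellbeing_weeks
    full = weeks_per_year // cycle_len
    remaining = weeks_per_year - full * cycle_len
    group_only = 1 if remaining >= spec.group_weeks else 0
    weeks_used = full * cycle_len + group_only * spec.group_weeks
    return CycleSchedule(full_cycles=full, group_only_cycles=group_only, weeks_used=weeks_used)


def group_reach(schedule: CycleSchedule, spec: GroupCycleSpec) -> int:
    """People enrolled across all cycles in the year."""
    return (schedule.full_cycles + schedule.group_only_cycles) * spec.participants_per_cycle


def group_person_sessions(schedule: CycleSchedule, spec: GroupCycleSpec) -> int:
    """Participant-attendances at group-work sessions (well-being weeks excluded)."""
    cycles = schedule.full_cycles + schedule.group_only_cycles
    return (
        cycles
        * spec.group_weeks
        * spec.sessions_per_week
        * spec.participants_per_cycle
    )


def annual_capacity(
    template: WeekTemplate,
    annualization: AnnualizationParams,
    spec: GroupCycleSpec,
) -> AnnualCapacity:
    """Aggregate annual outputs of one WTE on the given week template."""
    resolved = resolve_week(template, annualization)  # validates feasibility
    brief = annualize(weekly_slots(template, "brief_intervention", annualization), annualization)
    triage = annualize(weekly_slots(template, "triage", annualization), annualization)

    if _category_block(template, "group_work") is not None:
        schedule = schedule_group_cycles(annualization.weeks_per_year, spec)
        participants = group_reach(schedule, spec)
        person_sessions = group_person_sessions(schedule, spec)
    else:
        participants = 0
        person_sessions = 0

    community_hours = sum(
        resolved[block.name]
        for block in template.blocks
        if block.category == "community_engagement"
    ) * annualization.weeks_per_year

    return AnnualCapacity(
        brief_appointments=brief,
        triage_appointments=triage,
        group_participants=participants,
        group_person_sessions=person_sessions,
        community_engagement_hours=float(community_hours),
    )
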