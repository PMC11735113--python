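"""Week templates -> annual capacity: slots, cycles, reach, sessions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from appcap.capacity import (
    annual_capacity,
    annualize,
    group_person_sessions,
    group_reach,
    resolve_week,
    schedule_group_cycles,
    weekly_slots,
)
from appcap.config import (
    ActivityBlock,
    AnnualizationParams,
    GroupCycleSpec,
    WeekTemplate,
)
from appcap.errors import InfeasibleWeekError

ANN = AnnualizationParams()
SPEC = GroupCycleSpec()


def template(*blocks, name="t"):
    return WeekTemplate(name=name, blocks=list(blocks))


def brief(days=None, remainder=False, minutes=45):
    return ActivityBlock(
        name="brief",
        category="brief_intervention",
        weekly_time_days=days,
        appointment_duration_minutes=minutes,
        allocation="remainder" if remainder else "fixed",
    )


def fixed(name, category, days):
    return ActivityBlock(name=name, category=category, weekly_time_days=days)


STANDARD = template(
    fixed("community", "community_engagement", 0.5),
    fixed("other", "other_supervision", 0.25),
    fixed("group", "group_work", 0.5),
    brief(remainder=True),
    name="standard",
)


class TestWeeklySlots:
    def test_standard_week_brief_slots(self):
        """28.125 remaining hours / 0.75 h per appointment -> 37 whole slots."""
        assert weekly_slots(STANDARD, "brief_intervention", ANN) == 37

    def test_absent_category_gives_zero(self):
        assert weekly_slots(STANDARD, "triage", ANN) == 0

    def test_fixed_three_days_brief(self):
        t = template(brief(days=3.0))
        assert weekly_slots(t, "brief_intervention", ANN) == 30

    def test_triage_slots(self):
        t = template(
            ActivityBlock(
                name="triage",
                category="triage",
                weekly_time_days=0.875,
                appointment_duration_minutes=30,
            )
        )
        assert weekly_slots(t, "triage", ANN) == 13

    def test_overcommitted_week_raises(self):
        t = template(
            fixed("community", "community_engagement", 4.0),
            fixed("group", "group_work", 2.0),
            brief(remainder=True),
        )
        with pytest.raises(InfeasibleWeekError, match="community"):
            weekly_slots(t, "brief_intervention", ANN)

    def test_remainder_conserves_week(self):
        hours = resolve_week(STANDARD, ANN)
        assert sum(hours.values()) == pytest.approx(ANN.hours_per_week)

    @given(extra=st.floats(0, 3.0))
    @settings(derandomize=True, max_examples=40)
    def test_brief_slots_non_increasing_in_fixed_time(self, extra):
        base = weekly_slots(STANDARD, "brief_intervention", ANN)
        padded = template(
            fixed("community", "community_engagement", 0.5 + extra),
            fixed("other", "other_supervision", 0.25),
            fixed("group", "group_work", 0.5),
            brief(remainder=True),
        )
        assert weekly_slots(padded, "brief_intervention", ANN) <= base


class TestAnnualize:
    @pytest.mark.parametrize("weekly,expected", [(37, 1665), (0, 0), (30, 1350)])
    def test_times_working_weeks(self, weekly, expected):
        assert annualize(weekly, ANN) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            annualize(-1, ANN)


def brute_force_schedule(weeks, spec):
    """Enumerate all feasible (full, group_only) packings; prefer more full
    cycles, then a trailing group-only cycle."""
    best = (0, 0)
    cycle = spec.group_weeks + spec.wellbeing_weeks
    for full in range(weeks // cycle + 1):
        for group_only in (0, 1):
            used = full * cycle + group_only * spec.group_weeks
            if used <= weeks and (full, group_only) > best:
                best = (full, group_only)
    return best


class TestCycleScheduling:
    def test_45_week_year(self):
        sched = schedule_group_cycles(45, SPEC)
        assert (sched.full_cycles, sched.group_only_cycles) == (3, 1)
        assert sched.weeks_used == 44

    @pytest.mark.parametrize("weeks,expected", [(7, (0, 0)), (12, (1, 0)), (8, (0, 1))])
    def test_small_years(self, weeks, expected):
        sched = schedule_group_cycles(weeks, SPEC)
        assert (sched.full_cycles, sched.group_only_cycles) == expected

    @pytest.mark.parametrize("weeks", range(0, 61))
    def test_matches_brute_force(self, weeks):
        sched = schedule_group_cycles(weeks, SPEC)
        assert (sched.full_cycles, sched.group_only_cycles) == brute_force_schedule(
            weeks, SPEC
        )
        assert sched.weeks_used <= weeks

    def test_reach_and_sessions(self):
        sched = schedule_group_cycles(45, SPEC)
        assert group_reach(sched, SPEC) == 48
        assert group_person_sessions(sched, SPEC) == 384

    def test_reach_two_full_cycles(self):
        sched = schedule_group_cycles(24, SPEC)
        assert group_reach(sched, SPEC) == 24
        assert group_person_sessions(sched, SPEC) == 192

    def test_zero_weeks_all_zero(self):
        sched = schedule_group_cycles(0, SPEC)
        assert group_reach(sched, SPEC) == 0
        assert group_person_sessions(sched, SPEC) == 0


class TestAnnualCapacity:
    def test_standard_week_headline(self):
        cap = annual_capacity(STANDARD, ANN, SPEC)
        assert cap.brief_appointments == 1665
        assert cap.group_participants == 48
        assert cap.group_person_sessions == 384
        assert cap.triage_appointments == 0
        assert cap.community_engagement_hours == pytest.approx(0.5 * 7.5 * 45)

    def test_no_group_block_means_no_group_outputs(self):
        t = template(
            fixed("community", "community_engagement", 0.5),
            brief(remainder=True),
        )
        cap = annual_capacity(t, ANN, SPEC)
        assert cap.group_participants == 0
        assert cap.group_person_sessions == 0

    def test_triage_week_annualizes(self):
        t = template(
            ActivityBlock(
                name="triage",
                category="triage",
                weekly_time_days=0.875,
                appointment_duration_minutes=30,
            )
        )
        assert annual_capacity(t, ANN, SPEC).triage_appointments == 585

    @pytest.mark.parametrize("weeks", [40, 45, 52])
    def test_brief_capacity_monotone_in_weeks(self, weeks):
        ann = AnnualizationParams(weeks_per_year=weeks)
        base = annual_capacity(STANDARD, AnnualizationParams(weeks_per_year=weeks - 1), SPEC)
        more = annual_capacity(STANDARD, ann, SPEC)
        assert more.brief_appointments >= base.brief_appointments
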