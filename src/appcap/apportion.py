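"""Apportion commissioning-area appointment volumes down to one PCN.

Published appointment statistics are reported at commissioning-area (CCG)
level, split into GP and other-staff appointments, for all ages. The PCN's
share of that activity is taken as its share of the area's registered
population, and a fixed fraction of the resulting GP appointments (33% by
default) is attributed to mental health. Volumes spanning an arbitrary
period are scaled to a 365.25-day year before apportionment.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable

import pandas as pd

from .config import ApportionmentParams
from .errors import SchemaError

DAYS_PER_YEAR = 365.25

APPOINTMENT_COLUMNS = [
    "area_id",
    "period_start",
    "period_end",
    "staff_type",
    "appointments",
]

_STAFF_KEYS = {"GP": "gp", "OTHER": "other_staff"}


@dataclass
class AppointmentVolume:
    """Appointment counts for one commissioning area over one period."""

    area_id: str
    period_start: date
    period_end: date
    appointments_by_staff_type: dict[str, float]

    def __post_init__(self) -> None:
        if self.period_end < self.period_start:
            raise ValueError(
                f"area {self.area_id}: period end before start "
                f"({self.period_start}..{self.period_end})"
            )
        for staff, count in self.appointments_by_staff_type.items():
            if count < 0:
                raise ValueError(f"area {self.area_id}: negative count for {staff}")

    @property
    def period_days(self) -> int:
        # inclusive of both endpoints: Oct 1 2021 .. Sep 30 2022 is 365 days
        return (self.period_end - self.period_start).days + 1


@dataclass
class ApportionedVolume:
    """One PCN's slice of the area's annual GP activity."""

    pcn_id: str
    population_share: float
    pcn_gp_appointments: float
    pcn_mh_appointments: float


def population_share(pcn_population: float, area_population: float) -> float:
    """The PCN population as a proportion of the whole area population."""
    if area_population <= 0:
        raise ValueError(f"area population must be > 0, got {area_population}")
    if pcn_population > area_population:
        raise ValueError(
            f"PCN population ({pcn_population}) exceeds area population "
            f"({area_population})"
        )
    return pcn_population / area_population


def annualize_volume(volume: AppointmentVolume) -> dict[str, float]:
    """Scale period counts to a 365.25-day year, keyed by staff type."""
    factor = DAYS_PER_YEAR / volume.period_days
    return {
        staff: count * factor
        for staff, count in volume.appointments_by_staff_type.items()
    }


def apportion(
    volume: AppointmentVolume,
    share: float,
    params: ApportionmentParams,
    pcn_id: str = "",
) -> ApportionedVolume:
    """Slice the area volume by population share and apply the MH fraction.

    ``volume`` counts are used as given (annualize first if the period is
    not a year). With ``staff_type_in_scope = gp_only`` only GP appointments
    count; ``all_staff`` pools GP and other-staff appointments.
    """
    if not 0.0 <= share <= 1.0:
        raise ValueError(f"population share must be in [0, 1], got {share}")
    counts = volume.appointments_by_staff_type
    if "gp" not in counts:
        raise SchemaError(f"area {volume.area_id}: missing 'gp' staff-type count")
    if params.staff_type_in_scope == "all_staff":
        if "other_staff" not in counts:
            raise SchemaError(
                f"area {volume.area_id}: missing 'other_staff' staff-type count"
            )
        in_scope_total = counts["gp"] + counts["other_staff"]
    else:
        in_scope_total = counts["gp"]
    pcn_gp = in_scope_total * share
    pcn_mh = pcn_gp * params.mh_share_of_gp_appts
    return ApportionedVolume(
        pcn_id=pcn_id,
        population_share=share,
        pcn_gp_appointments=pcn_gp,
        pcn_mh_appointments=pcn_mh,
    )


def read_appointments(path: str | Path) -> list[AppointmentVolume]:
    """Read an appointments CSV (area_id, period_start, period_end, staff_type,
    appointments) with staff_type in {GP, OTHER}, one volume per area+period."""
    frame = pd.read_csv(path, dtype={"area_id": str, "staff_type": str})
    missing = set(APPOINTMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"appointments {path}: missing columns {sorted(missing)}")
    bad = set(frame["staff_type"]) - set(_STAFF_KEYS)
    if bad:
        raise SchemaError(
            f"appointments {path}: unknown staff_type values {sorted(bad)} "
            f"(expected {sorted(_STAFF_KEYS)})"
        )
    volumes = []
    grouped = frame.groupby(["area_id", "period_start", "period_end"], sort=True)
    for (area_id, start, end), rows in grouped:
        volumes.append(
            AppointmentVolume(
                area_id=str(area_id),
                period_start=date.fromisoformat(str(start)),
                period_end=date.fromisoformat(str(end)),
                appointments_by_staff_type={
                    _STAFF_KEYS[row.staff_type]: float(row.appointments)
                    for row in rows.itertuples()
                },
            )
        )
    return volumes


def write_appointments(volumes: Iterable[AppointmentVolume], path: str | Path) -> Path:
    path = Path(path)
    labels = {v: k for k, v in _STAFF_KEYS.items()}
    rows = [
        {
            "area_id": volume.area_id,
            "period_start": volume.period_start.isoformat(),
            "period_end": volume.period_end.isoformat(),
            "staff_type": labels[staff],
            "appointments": int(count),
        }
        for volume in volumes
        for staff, count in sorted(volume.appointments_by_staff_type.items())
    ]
    pd.DataFrame(rows, columns=APPOINTMENT_COLUMNS).to_csv(path, index=False)
    return path
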