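"""GP appointments diverted or freed, and the staffing that implies.

Two complementary readings of the pathway change are modelled:

* **Pathway accounting** — patients in scope currently average ``k``
  (3 or 4) GP visits and in the future state see the GP once before
  referral, so a fraction (k - 1)/k of the PCN's annual mental-health GP
  appointments is freed. This reproduces the published 13,650-15,280
  spread as k ranges over {3, 4} on a single appointment pool.
* **Band accounting** — an aggregate reduction of a quarter to a third of
  mental-health GP appointments, anchored on the 28% demand reduction
  observed for social prescribing.

One practitioner's brief-intervention appointments divert GP appointments
one-for-one; dividing freed appointments by that per-practitioner capacity
gives the whole-time-equivalent (WTE) requirement, reported half-up to one
decimal place (13,650 / 1,665 = 8.198 -> 8.2). A self-referral route sends
a fraction of the mental-health appointment pool straight to 30-minute
triage appointments, absorbed up to the practitioner's triage capacity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .capacity import AnnualCapacity
from .config import DiversionScenario
from .rounding import report_int, round_half_up, two_sig_figs


@dataclass
class DiversionResult:
    """Freed-capacity outputs for one PCN under one scenario."""

    diverted_appointments_per_app: int
    freed_gp_appointments_low: float
    freed_gp_appointments_high: float
    wte_required_low: float
    wte_required_high: float
    freed_band_low: float
    freed_band_high: float
    self_referral_demand: float
    absorbed_triage: float
    unmet_triage: float
    patients_served_per_app: int


def diverted_per_app(capacity: AnnualCapacity) -> int:
    """GP appointments diverted by one practitioner: one per brief appointment."""
    return capacity.brief_appointments


def patients_served(capacity: AnnualCapacity, scenario: DiversionScenario) -> int:
    """Patients completing a brief intervention (sessions-per-patient each)."""
    return capacity.brief_appointments // scenario.app_sessions_per_patient


def freed_by_pathway(
    pcn_mh_appointments: float, scenario: DiversionScenario
) -> float:
    """Appointments freed when baseline GP visits collapse to the future count.

    freed = M x (baseline - future) / baseline, rounded for report.
    """
    baseline = scenario.baseline_gp_visits_per_patient
    future = scenario.future_gp_visits_per_patient
    if baseline <= 0:
        raise ValueError("baseline_gp_visits_per_patient must be > 0")
    freed = pcn_mh_appointments * (baseline - future) / baseline
    return float(report_int(freed))


def freed_by_band(
    pcn_mh_appointments: float, band: tuple[float, float]
) -> tuple[float, float]:
    """Appointments freed under an aggregate reduction band (low, high)."""
    low, high = band
    if not 0.0 <= low <= high:
        raise ValueError(f"invalid reduction band ({low}, {high})")
    return (
        float(report_int(pcn_mh_appointments * low)),
        float(report_int(pcn_mh_appointments * high)),
    )


def wte_required(freed_appointments: float, per_app_capacity: float) -> float:
    """Whole-time equivalents needed to supply the freed appointments."""
    if per_app_capacity <= 0:
        raise ValueError("per-practitioner capacity must be > 0")
    return round_half_up(freed_appointments / per_app_capacity, 1)


def self_referral_demand(
    pcn_mh_appointments: float, scenario: DiversionScenario
) -> float:
    """Triage appointments generated by the self-referral route."""
    return float(report_int(pcn_mh_appointments * scenario.self_referral_fraction))


def absorb_triage(demand: float, capacity: AnnualCapacity) -> tuple[float, float]:
    """Split self-referral demand into (absorbed, unmet) against triage capacity."""
    if demand < 0:
        raise ValueError("triage demand must be >= 0")
    absorbed = min(demand, float(capacity.triage_appointments))
    return absorbed, demand - absorbed


def scale_pcns(
    per_pcn_value: float, n_pcns: int, rounding: str = "none"
) -> float:
    """Scale a per-PCN quantity to ``n_pcns`` networks.

    ``rounding="two_sig_figs"`` applies the presentation rounding used for
    multi-PCN headline figures (53,013 -> 53,000); raw values are the
    ``"none"`` mode.
    """
    if n_pcns < 1:
        raise ValueError("n_pcns must be >= 1")
    total = per_pcn_value * n_pcns
    if rounding == "none":
        return float(total)
    if rounding == "two_sig_figs":
        return two_sig_figs(total)
    raise ValueError(f"unknown rounding mode {rounding!r}")


def run_diversion(
    pcn_mh_appointments: float,
    capacity: AnnualCapacity,
    scenario: DiversionScenario,
    reduction_band: tuple[float, float],
) -> DiversionResult:
    """All diversion outputs for one PCN.

    The freed range spans baseline visit counts {3, 4} (or the scenario's
    configured baseline and baseline + 1 when it differs from 3), matching
    the published presentation of a low/high pair.
    """
    baselines = sorted({scenario.baseline_gp_visits_per_patient,
                        scenario.baseline_gp_visits_per_patient + 1})
    freed = [
        freed_by_pathway(
            pcn_mh_appointments,
            scenario.model_copy(update={"baseline_gp_visits_per_patient": k}),
        )
        for k in baselines
    ]
    band_low, band_high = freed_by_band(pcn_mh_appointments, reduction_band)
    per_app = diverted_per_app(capacity)
    demand = self_referral_demand(pcn_mh_appointments, scenario)
    absorbed, unmet = absorb_triage(demand, capacity)
    if per_app > 0:
        wte_low, wte_high = (wte_required(f, per_app) for f in (freed[0], freed[-1]))
    else:
        wte_low = wte_high = float("nan")
    return DiversionResult(
        diverted_appointments_per_app=per_app,
        freed_gp_appointments_low=freed[0],
        freed_gp_appointments_high=freed[-1],
        wte_required_low=wte_low,
        wte_required_high=wte_high,
        freed_band_low=band_low,
        freed_band_high=band_high,
        self_referral_demand=demand,
        absorbed_triage=absorbed,
        unmet_triage=unmet,
        patients_served_per_app=patients_served(capacity, scenario),
    )
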