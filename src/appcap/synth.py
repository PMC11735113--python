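"""Synthetic practice registers and appointment tables.

Emulates the structure of national practice-level register extracts and
commissioning-area appointment counts so every pipeline stage can run
without any download. List sizes are administrative counts drawn from a
log-normal (registers carry no event noise); appointment totals are
Poisson, since appointments are events accumulating over a year.

Defaults mimic the modelled setting: 41 PCNs of ~5 practices each
(~200 practices), log-normal list sizes with median 7,600 and log-sd 0.5
(area total ~1.77 million people), an 82% adult (15+) fraction, 5
appointments per person-year with half delivered by GPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import Field

from .apportion import AppointmentVolume, write_appointments
from .cascade import PCNRegister, PracticeRecord, write_register
from .config import _StrictModel

PERIOD_START = date(2021, 10, 1)
PERIOD_END = date(2022, 9, 30)

CHILD_BAND = "0-14"
ADULT_BAND = "15+"


class SynthSpec(_StrictModel):
    """Parameters of the synthetic world (per PCN unless noted)."""

    n_practices: int = Field(default=5, ge=1)
    list_size_median: float = Field(default=7600.0, gt=0.0)
    list_size_dispersion: float = Field(default=0.5, gt=0.0)  # sigma of log list size
    adult_fraction: float = Field(default=0.82, ge=0.0, le=1.0)
    per_capita_gp_appointment_rate: float = Field(default=5.0, ge=0.0)
    gp_share_of_all_appointments: float = Field(default=0.5, ge=0.0, le=1.0)
    mh_share_target: float = Field(default=0.33, ge=0.0, le=1.0)
    random_seed: int = 0

    def list_size_mean(self) -> float:
        """Analytic mean of the log-normal list-size distribution."""
        return self.list_size_median * float(
            np.exp(self.list_size_dispersion**2 / 2.0)
        )


def synth_register(
    spec: SynthSpec,
    pcn_id: str = "PCN-001",
    rng: Optional[np.random.Generator] = None,
) -> PCNRegister:
    """One PCN's practices with list sizes split into 0-14 / 15+ bands.

    Identical (spec, seed) gives identical output; pass ``rng`` to draw
    several PCNs from one stream.
    """
    if rng is None:
        rng = np.random.default_rng(spec.random_seed)
    sizes = rng.lognormal(
        mean=float(np.log(spec.list_size_median)),
        sigma=spec.list_size_dispersion,
        size=spec.n_practices,
    )
    practices = []
    for i, size in enumerate(np.rint(sizes).astype(int), start=1):
        adults = int(round(size * spec.adult_fraction))
        practices.append(
            PracticeRecord(
                practice_id=f"{pcn_id}-P{i:03d}",
                pcn_id=pcn_id,
                list_size_by_age_band={
                    CHILD_BAND: size - adults,
                    ADULT_BAND: adults,
                },
            )
        )
    return PCNRegister(pcn_id=pcn_id, practices=practices)


def synth_appointments(
    spec: SynthSpec,
    register: PCNRegister,
    area_multiplier: float,
    rng: Optional[np.random.Generator] = None,
    area_id: str = "AREA-001",
) -> AppointmentVolume:
    """Area-level appointment counts for an area ``area_multiplier`` times the
    PCN's population (so the true population share is 1/area_multiplier)."""
    if area_multiplier < 1:
        raise ValueError("area_multiplier must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.random_seed)
    area_population = register.total_population * area_multiplier
    total_rate = area_population * spec.per_capita_gp_appointment_rate
    gp_mean = total_rate * spec.gp_share_of_all_appointments
    other_mean = total_rate * (1.0 - spec.gp_share_of_all_appointments)
    return AppointmentVolume(
        area_id=area_id,
        period_start=PERIOD_START,
        period_end=PERIOD_END,
        appointments_by_staff_type={
            "gp": float(rng.poisson(gp_mean)),
            "other_staff": float(rng.poisson(other_mean)),
        },
    )


@dataclass
class SynthBundle:
    """A full synthetic area: registers, appointment volume, file paths."""

    registers: list[PCNRegister]
    appointments: AppointmentVolume
    register_path: Optional[Path] = None
    appointments_path: Optional[Path] = None
    manifest_path: Optional[Path] = None


def synth_bundle(
    spec: SynthSpec,
    n_pcns: int = 41,
    seed: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
) -> SynthBundle:
    """Generate a whole commissioning area: ``n_pcns`` registers plus one
    area appointment volume whose mean matches the pooled population.

    With ``out_dir`` set, writes ``register.csv``, ``appointments.csv`` and a
    ``manifest.json`` recording the spec and seed.
    """
    if seed is not None:
        spec = spec.model_copy(update={"random_seed": int(seed)})
    rng = np.random.default_rng(spec.random_seed)
    registers = [
        synth_register(spec, pcn_id=f"PCN-{i:03d}", rng=rng)
        for i in range(1, n_pcns + 1)
    ]
    area_population = sum(r.total_population for r in registers)
    total_rate = area_population * spec.per_capita_gp_appointment_rate
    gp_mean = total_rate * spec.gp_share_of_all_appointments
    other_mean = total_rate * (1.0 - spec.gp_share_of_all_appointments)
    appointments = AppointmentVolume(
        area_id="AREA-001",
        period_start=PERIOD_START,
        period_end=PERIOD_END,
        appointments_by_staff_type={
            "gp": float(rng.poisson(gp_mean)),
            "other_staff": float(rng.poisson(other_mean)),
        },
    )
    bundle = SynthBundle(registers=registers, appointments=appointments)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bundle.register_path = write_register(registers, out_dir / "register.csv")
        bundle.appointments_path = write_appointments(
            [appointments], out_dir / "appointments.csv"
        )
        manifest = {
            "spec": spec.model_dump(mode="json"),
            "n_pcns": n_pcns,
            "seed": spec.random_seed,
        }
        bundle.manifest_path = out_dir / "manifest.json"
        bundle.manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return bundle
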